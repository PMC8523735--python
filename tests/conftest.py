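import numpy as np
import pytest

from osteomap import cohort


@pytest.fixture(scope="session")
def big_cohort():
    """One large two-group draw shared by the moment-recovery checks."""
    return cohort.generate_cohort(n_frac=10_000, n_nonfrac=10_000, seed=424242)


@pytest.fixture(scope="session")
def vm_oracle():
    """Independent von Mises strain oracle via principal strains.

    Builds the full 3D strain tensor (out-of-plane strain from the
    plane-stress condition), diagonalizes it and evaluates
    sqrt(2/3 * dev:dev) on the principal values — a different code path
    from the closed-form component expression under test.
    """

    def oracle(ex: float, ey: float, gxy: float, nu: float) -> float:
        ez = -nu * (ex + ey) / (1.0 - nu)
        T = np.array([[ex, gxy / 2, 0.0], [gxy / 2, ey, 0.0], [0.0, 0.0, ez]])
        p = np.linalg.eigvalsh(T)
        dev = p - p.mean()
        return float(np.sqrt(2.0 / 3.0 * np.sum(dev**2)))

    return oracle


def planted_classification(seed: int, n: int = 400, k_noise: int = 6, sep: float = 2.0):
    """Balanced binary data with two informative and k_noise pure-noise columns."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.standard_normal((n, 2 + k_noise))
    X[:, 0] += sep * y
    X[:, 1] -= sep * y
    return X, y
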