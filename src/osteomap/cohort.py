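"""Synthetic cohorts of postmenopausal women for fracture-prediction experiments.

The reference study population is a cohort of 174 postmenopausal women
(69 of whom developed an incident vertebral fracture during follow-up,
105 of whom did not) described by 13 baseline clinical and densitometric
variables: age at menopause, body weight, age, BMI, and — for the lumbar
spine, femoral neck and total femur — bone mineral content (BMC, g), areal
bone mineral density (BMD, g/cm²) and the Bone Strain Index (BSI,
dimensionless).  Only group means, standard deviations and whole-population
ranges are published, so the generator draws from a Gaussian copula whose
marginals are truncated normals *moment-matched* to the published group
mean/SD inside the published range.  Sampling a truncated normal naively
(truncate after drawing) would bias the group mean wherever a range bound
sits close to it; solving for the parent (mu, sigma) such that the truncated
law has exactly the target moments removes that bias while keeping every
value inside the printed range.

Two generation modes exist:

* :func:`generate_cohort` — fractured and non-fractured records are drawn
  from their own group parameters (the way the published table is laid out);
* :func:`assign_outcomes` — a single-population draw gets outcomes from a
  logistic model on standardized variables, for planted-signal recovery
  experiments where the analyst controls which variable carries the signal.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GroupSpec",
    "VARIABLES",
    "FRACTURED_SPECS",
    "NONFRACTURED_SPECS",
    "WHOLE_POPULATION_SPECS",
    "default_correlation",
    "generate_cohort",
    "generate_population",
    "assign_outcomes",
    "sample_followup_years",
    "read_cohort_csv",
    "write_cohort_csv",
]

#: Canonical order of the 13 baseline variables.
VARIABLES = [
    "menopause_age",
    "weight",
    "age",
    "BMI",
    "L_BMC",
    "L_BMD",
    "L_BSI",
    "Neck_BMC",
    "Neck_BMD",
    "Neck_BSI",
    "Ftot_BMC",
    "Ftot_BMD",
    "Ftot_BSI",
]

#: Follow-up duration (years): published mean and SD of the inter-exam interval.
FOLLOWUP_MEAN = 3.34
FOLLOWUP_SD = 1.91


@dataclass(frozen=True)
class GroupSpec:
    """Marginal specification of one variable within one outcome group.

    Parameters
    ----------
    name : str
        Canonical variable name (one of :data:`VARIABLES`).
    mean, sd : float
        Target mean and standard deviation in native units; ``sd >= 0``.
    range_low, range_high : float
        Hard truncation bounds (the published whole-population range).
    """

    name: str
    mean: float
    sd: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0, got {self.sd}")
        if not self.range_low < self.range_high:
            raise ValueError(
                f"{self.name}: range_low must be < range_high "
                f"({self.range_low} vs {self.range_high})"
            )
        if not self.range_low <= self.mean <= self.range_high:
            raise ValueError(
                f"{self.name}: mean {self.mean} outside truncation range "
                f"[{self.range_low}, {self.range_high}]"
            )


def _specs(rows: list[tuple[str, float, float, float, float]]) -> list[GroupSpec]:
    return [GroupSpec(*row) for row in rows]


# (name, mean, sd, range_low, range_high); ranges are whole-population.
_RANGES = {
    "menopause_age": (38.0, 60.0),
    "weight": (37.0, 98.0),
    "age": (41.0, 88.0),
    "BMI": (14.82, 34.89),
    "L_BMC": (14.96, 81.01),
    "L_BMD": (0.525, 1.281),
    "L_BSI": (1.076, 4.299),
    "Neck_BMC": (2.11, 4.74),
    "Neck_BMD": (0.365, 0.879),
    "Neck_BSI": (0.772, 3.991),
    "Ftot_BMC": (14.84, 38.58),
    "Ftot_BMD": (0.427, 1.111),
    "Ftot_BSI": (0.992, 3.332),
}

_FRACTURED = {
    "menopause_age": (48.1, 5.4),
    "weight": (58.5, 7.9),
    "age": (66.6, 10.6),
    "BMI": (24.4, 3.7),
    "L_BMC": (37.25, 8.10),
    "L_BMD": (0.774, 0.090),
    "L_BSI": (2.467, 0.54),
    "Neck_BMC": (2.96, 0.37),
    "Neck_BMD": (0.603, 0.073),
    "Neck_BSI": (2.085, 0.614),
    "Ftot_BMC": (23.71, 3.75),
    "Ftot_BMD": (0.752, 0.101),
    "Ftot_BSI": (1.751, 0.482),
}

_NONFRACTURED = {
    "menopause_age": (48.6, 4.8),
    "weight": (60.9, 10.5),
    "age": (66.1, 9.3),
    "BMI": (24.1, 3.7),
    "L_BMC": (44.03, 10.11),
    "L_BMD": (0.867, 0.142),
    "L_BSI": (2.031, 0.581),
    "Neck_BMC": (3.29, 0.53),
    "Neck_BMD": (0.698, 0.102),
    "Neck_BSI": (1.821, 0.450),
    "Ftot_BMC": (25.66, 4.73),
    "Ftot_BMD": (0.801, 0.115),
    "Ftot_BSI": (1.606, 0.325),
}

_WHOLE = {
    "menopause_age": (48.4, 5.1),
    "weight": (60.0, 9.6),
    "age": (66.3, 9.8),
    "BMI": (24.2, 3.7),
    "L_BMC": (41.32, 9.92),
    "L_BMD": (0.813, 0.131),
    "L_BSI": (2.298, 0.586),
    "Neck_BMC": (3.12, 0.50),
    "Neck_BMD": (0.667, 0.091),
    "Neck_BSI": (1.929, 0.521),
    "Ftot_BMC": (24.81, 4.46),
    "Ftot_BMD": (0.773, 0.11),
    "Ftot_BSI": (1.638, 0.402),
}


def _build(group: dict[str, tuple[float, float]]) -> list[GroupSpec]:
    return [GroupSpec(v, *group[v], *_RANGES[v]) for v in VARIABLES]


FRACTURED_SPECS: list[GroupSpec] = _build(_FRACTURED)
NONFRACTURED_SPECS: list[GroupSpec] = _build(_NONFRACTURED)
WHOLE_POPULATION_SPECS: list[GroupSpec] = _build(_WHOLE)

#: Published group sizes.
N_FRACTURED = 69
N_NONFRACTURED = 105


def default_correlation() -> np.ndarray:
    """Default 13x13 inter-variable correlation matrix.

    The published table gives no covariances, so the default encodes the
    qualitative structure a densitometrist would expect, via a low-rank
    factor model (which guarantees positive semi-definiteness): a body-size
    factor (weight, BMI, BMC), a global bone-mass factor loading positively
    on BMC/BMD and negatively on BSI (a mechanically weaker bone strains
    more at the same load), and one factor per skeletal site giving
    within-site |r| around 0.6 between BMC/BMD and BSI, BSI opposing BMD.
    """
    k = len(VARIABLES)
    idx = {v: i for i, v in enumerate(VARIABLES)}
    # columns: body size, global bone mass, lumbar, neck, total femur, age
    load = np.zeros((k, 6))

    def put(var: str, col: int, value: float) -> None:
        load[idx[var], col] = value

    put("weight", 0, 0.70)
    put("BMI", 0, 0.80)
    for site, col in (("L", 2), ("Neck", 3), ("Ftot", 4)):
        put(f"{site}_BMC", 0, 0.25)
        put(f"{site}_BMC", 1, 0.40)
        put(f"{site}_BMD", 1, 0.40)
        put(f"{site}_BSI", 1, -0.30)
        put(f"{site}_BMC", col, 0.62)
        put(f"{site}_BMD", col, 0.70)
        put(f"{site}_BSI", col, -0.70)
    put("age", 5, 0.70)
    put("menopause_age", 5, -0.25)

    corr = load @ load.T
    np.fill_diagonal(corr, 1.0)
    return corr


def _check_correlation(corr: np.ndarray, k: int) -> np.ndarray:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (k, k):
        raise ValueError(f"correlation must be {k}x{k}, got {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    return corr


@functools.lru_cache(maxsize=256)
def _matched_parent(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo, hi]-truncated normal has moments (mean, sd)."""
    max_sd = (hi - lo) / np.sqrt(12.0)  # uniform limit on the interval
    if sd >= max_sd:
        raise ValueError(
            f"sd {sd} unattainable for a truncated normal on [{lo}, {hi}]"
        )

    def residual(p: np.ndarray) -> np.ndarray:
        mu, sig = p
        a, b = (lo - mu) / sig, (hi - mu) / sig
        d = stats.truncnorm(a, b, loc=mu, scale=sig)
        return np.array([d.mean() - mean, d.std() - sd])

    sol = optimize.least_squares(
        residual,
        x0=np.array([mean, sd]),
        bounds=([lo - 10 * (hi - lo), sd / 10], [hi + 10 * (hi - lo), 10 * (hi - lo)]),
        xtol=1e-14,
        ftol=1e-14,
    )
    if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(sd, 1e-12):
        raise RuntimeError(f"moment matching failed for ({mean}, {sd}, {lo}, {hi})")
    return float(sol.x[0]), float(sol.x[1])


def _sample_group(
    specs: list[GroupSpec], n: int, corr: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-copula draw with moment-matched truncated-normal marginals."""
    k = len(specs)
    if n == 0:
        return np.empty((0, k))
    # eigh-based root: deterministic, tolerant of PSD-with-zero-eigenvalue inputs
    w, v = np.linalg.eigh(corr)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((n, k)) @ root.T
    u = stats.norm.cdf(z)
    out = np.empty((n, k))
    for j, spec in enumerate(specs):
        if spec.sd == 0.0:
            out[:, j] = spec.mean
            continue
        mu, sig = _matched_parent(spec.mean, spec.sd, spec.range_low, spec.range_high)
        a, b = (spec.range_low - mu) / sig, (spec.range_high - mu) / sig
        out[:, j] = stats.truncnorm.ppf(u[:, j], a, b, loc=mu, scale=sig)
        # ppf at u -> {0,1} can touch the bounds; keep strictly finite values
        np.clip(out[:, j], spec.range_low, spec.range_high, out=out[:, j])
    return out


def sample_followup_years(n: int, rng: np.random.Generator) -> np.ndarray:
    """Log-normal follow-up durations matched to the published mean/SD (years)."""
    sigma2 = np.log1p((FOLLOWUP_SD / FOLLOWUP_MEAN) ** 2)
    mu = np.log(FOLLOWUP_MEAN) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def _assemble(
    values: np.ndarray,
    fracture: np.ndarray,
    specs: list[GroupSpec],
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = values.shape[0]
    table = pd.DataFrame(values, columns=[s.name for s in specs])
    table.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(n)])
    table["fracture"] = fracture.astype(int)
    table["followup_years"] = sample_followup_years(n, rng)
    return table


def generate_cohort(
    specs_fractured: list[GroupSpec] | None = None,
    specs_nonfractured: list[GroupSpec] | None = None,
    n_frac: int = N_FRACTURED,
    n_nonfrac: int = N_NONFRACTURED,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a two-group cohort with per-group published moments.

    Returns a DataFrame with ``patient_id``, the 13 variables, binary
    ``fracture`` (fractured records first) and ``followup_years``.
    Reproducible: equal seeds give bit-identical tables.
    """
    specs_fractured = specs_fractured or FRACTURED_SPECS
    specs_nonfractured = specs_nonfractured or NONFRACTURED_SPECS
    if n_frac < 0 or n_nonfrac < 0:
        raise ValueError("group sizes must be >= 0")
    if len(specs_fractured) != len(specs_nonfractured):
        raise ValueError("both groups must specify the same variables")
    k = len(specs_fractured)
    corr = (
        _check_correlation(correlation, k)
        if correlation is not None
        else (default_correlation() if k == len(VARIABLES) else np.eye(k))
    )
    rng = np.random.default_rng(seed)
    vals_f = _sample_group(specs_fractured, n_frac, corr, rng)
    vals_n = _sample_group(specs_nonfractured, n_nonfrac, corr, rng)
    values = np.vstack([vals_f, vals_n])
    fracture = np.concatenate([np.ones(n_frac), np.zeros(n_nonfrac)])
    return _assemble(values, fracture, specs_fractured, rng)


def generate_population(
    specs: list[GroupSpec] | None = None,
    n: int = N_FRACTURED + N_NONFRACTURED,
    correlation: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-population draw (no outcome column); see :func:`assign_outcomes`."""
    specs = specs or WHOLE_POPULATION_SPECS
    k = len(specs)
    corr = (
        _check_correlation(correlation, k)
        if correlation is not None
        else (default_correlation() if k == len(VARIABLES) else np.eye(k))
    )
    rng = np.random.default_rng(seed)
    values = _sample_group(specs, n, corr, rng)
    table = pd.DataFrame(values, columns=[s.name for s in specs])
    table.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(n)])
    table["followup_years"] = sample_followup_years(n, rng)
    return table


def assign_outcomes(
    table: pd.DataFrame,
    coefficients: dict[str, float],
    prevalence: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach a binary ``fracture`` outcome via a logistic model.

    The linear predictor is ``sum_j beta_j * z_j`` on per-variable z-scores;
    the intercept is calibrated by root-finding so the *expected* fracture
    fraction equals ``prevalence``.  Used to plant a known signal (e.g. a
    large positive coefficient on total-femur BSI makes high strain drive
    fracture, hence low strain drive non-fracture).
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    if "fracture" in table.columns:
        raise ValueError("table already carries a fracture outcome")
    unknown = set(coefficients) - set(table.columns)
    if unknown:
        raise ValueError(f"coefficients refer to unknown variables: {sorted(unknown)}")

    n = len(table)
    eta = np.zeros(n)
    for name, beta in coefficients.items():
        x = table[name].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd > 0:
            eta += beta * (x - x.mean()) / sd

    def excess(intercept: float) -> float:
        return float(np.mean(stats.logistic.cdf(intercept + eta))) - prevalence

    if prevalence in (0.0, 1.0):
        p = np.full(n, prevalence)
    else:
        intercept = optimize.brentq(excess, -40.0, 40.0, xtol=1e-12)
        p = stats.logistic.cdf(intercept + eta)
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["fracture"] = (rng.random(n) < p).astype(int)
    if "followup_years" not in out.columns:
        out["followup_years"] = sample_followup_years(n, rng)
    return out


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "fracture" in table.columns:
        bad = ~table["fracture"].isin([0, 1])
        if bad.any():
            raise ValueError("fracture column must be coded 0/1")
    if table.isna().any().any():
        raise ValueError("cohort table contains missing values")
    return table
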