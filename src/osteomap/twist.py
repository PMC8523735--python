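"""TWIST-style evolutionary selection of a record split and a variable subset.

A genetic algorithm jointly optimizes (a) an assignment of every record to
subset A or B and (b) a boolean mask over the input variables.  A
candidate's fitness is the mean overall accuracy of a fast probe classifier
trained on A and tested on B and vice versa, using only the masked
variables — so the surviving split is one on which a model generalizes both
ways, and the surviving variables are those that carry transferable signal.
The best split/mask pair is then handed to the full classifier protocols.

The genome is the concatenated bit-string (records, then variables) with
uniform crossover, per-bit mutation probability 1/length, tournament
selection of size 3 and single-candidate elitism.  Candidates whose split
is degenerate (an empty half, a half missing an outcome class, or a
class-prevalence imbalance beyond ``balance_tol``) score zero.  Fitness
ties break toward fewer selected variables, then lexicographic mask order,
for parsimony and determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import TrainConfig, evaluate, train_mlp
from .preprocessing import minmax_scale

__all__ = ["TwistConfig", "Candidate", "TwistResults", "TwistSelector", "fitness"]


@dataclass(frozen=True)
class TwistConfig:
    """Genetic-algorithm and probe settings."""

    pop_size: int = 24
    generations: int = 15
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # None -> 1 / genome length
    elitism: int = 1
    tournament: int = 3
    balance_tol: float = 0.1
    probe: str = "mlp"  # or "centroid"
    probe_epochs: int = 60
    probe_hidden: int = 4
    seed: int = 0


@dataclass
class Candidate:
    """One genome: per-record A/B assignment and per-variable mask."""

    split: np.ndarray  # bool, True -> subset B
    mask: np.ndarray  # bool, True -> variable selected
    fitness: float = 0.0
    flag: str = ""

    def key(self) -> tuple:
        """Sort key: higher fitness, then fewer variables, then lexicographic."""
        return (-self.fitness, int(self.mask.sum()), tuple(self.mask.astype(int)))


def _split_validity(split: np.ndarray, y: np.ndarray, balance_tol: float) -> str:
    a, b = ~split, split
    if a.sum() == 0 or b.sum() == 0:
        return "empty split half"
    for half, name in ((a, "A"), (b, "B")):
        if len(np.unique(y[half])) < 2 or min(np.bincount(y[half])) < 2:
            return f"subset {name} lacks both outcome classes"
    if abs(y[a].mean() - y[b].mean()) > balance_tol:
        return "class prevalence imbalance between halves"
    return ""


def _probe_accuracy(
    Xtr, ytr, Xte, yte, config: TwistConfig
) -> float:
    if config.probe == "centroid":
        mu1 = Xtr[ytr == 1].mean(axis=0)
        mu0 = Xtr[ytr == 0].mean(axis=0)
        d1 = np.linalg.norm(Xte - mu1, axis=1)
        d0 = np.linalg.norm(Xte - mu0, axis=1)
        return float(np.mean((d1 < d0).astype(int) == yte))
    if config.probe == "mlp":
        model = train_mlp(
            Xtr,
            ytr,
            TrainConfig(
                hidden=config.probe_hidden,
                epochs=config.probe_epochs,
                learning_rate=0.02,
                seed=0,  # fixed: a candidate's fitness must be reproducible
            ),
        )
        return evaluate(model, Xte, yte).accuracy / 100.0
    raise ValueError(f"unknown probe {config.probe!r}")


def fitness(candidate: Candidate, X, y, config: TwistConfig | None = None) -> Candidate:
    """Two-way cross-testing accuracy of the probe on the masked variables.

    Returns the candidate with ``fitness`` in [0, 1] filled in (zero, with a
    flag, for degenerate splits or an empty mask).
    """
    config = config or TwistConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if candidate.mask.sum() == 0:
        candidate.fitness, candidate.flag = 0.0, "no variable selected"
        return candidate
    problem = _split_validity(candidate.split, y, config.balance_tol)
    if problem:
        candidate.fitness, candidate.flag = 0.0, problem
        return candidate
    sel = X[:, candidate.mask]
    a, b = ~candidate.split, candidate.split
    acc_ab = _probe_accuracy(sel[a], y[a], sel[b], y[b], config)
    acc_ba = _probe_accuracy(sel[b], y[b], sel[a], y[a], config)
    candidate.fitness, candidate.flag = (acc_ab + acc_ba) / 2.0, ""
    return candidate


@dataclass
class TwistResults:
    """Outcome of one evolutionary run."""

    best: Candidate
    trace: list[float]  # best-ever fitness per generation (non-decreasing)
    selected: list[str]
    variables: list[str]
    config: TwistConfig

    @property
    def subset_a(self) -> np.ndarray:
        return np.nonzero(~self.best.split)[0]

    @property
    def subset_b(self) -> np.ndarray:
        return np.nonzero(self.best.split)[0]

    def summary(self) -> str:
        lines = [
            "TWIST variable/split selection",
            "==============================",
            f"fitness (two-way probe accuracy): {self.best.fitness:.4f}",
            f"selected variables ({len(self.selected)}/{len(self.variables)}): "
            + ", ".join(self.selected),
            f"subset sizes: A = {len(self.subset_a)}, B = {len(self.subset_b)}",
            f"generations: {len(self.trace) - 1}, population: {self.config.pop_size}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "fitness": self.best.fitness,
            "selected": self.selected,
            "mask": self.best.mask.astype(int).tolist(),
            "split_b": self.best.split.astype(int).tolist(),
            "trace": self.trace,
        }

    def plot_trace(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.trace)), self.trace, marker="o")
        ax.set_xlabel("generation")
        ax.set_ylabel("best two-way accuracy")
        ax.set_title("TWIST fitness trace")
        return ax


class TwistSelector:
    """Evolutionary split/variable selector over a cohort matrix.

    Parameters
    ----------
    X : (n, k) array or DataFrame
        Input variables; min-max scaled internally to [0, 1] column-wise.
    y : (n,) binary outcome.
    variables : list of str, optional
        Column names (taken from the DataFrame if given).
    """

    def __init__(self, X, y, variables: list[str] | None = None,
                 config: TwistConfig | None = None):
        if hasattr(X, "columns"):
            variables = variables or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if min(np.bincount(y, minlength=2)) < 2:
            raise ValueError("need at least 2 records per outcome class")
        self.variables = variables or [f"x{j}" for j in range(X.shape[1])]
        cols = []
        for j in range(X.shape[1]):
            lo, hi = X[:, j].min(), X[:, j].max()
            cols.append(
                minmax_scale(X[:, j], lo, hi) if lo < hi else np.zeros(len(X))
            )
        self.X = np.column_stack(cols)
        self.y = y
        self.config = config or TwistConfig()

    # -- GA machinery -------------------------------------------------

    def _random_candidate(self, rng: np.random.Generator) -> Candidate:
        n, k = self.X.shape
        split = rng.random(n) < 0.5
        mask = rng.random(k) < 0.5
        if not mask.any():
            mask[rng.integers(k)] = True
        return Candidate(split=split, mask=mask)

    def _tournament(self, pop: list[Candidate], rng) -> Candidate:
        picks = rng.integers(len(pop), size=self.config.tournament)
        return min((pop[i] for i in picks), key=Candidate.key)

    def fit(self, seed: int | None = None) -> TwistResults:
        """Run the GA; deterministic for a fixed seed; returns best-ever."""
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        rng = np.random.default_rng(seed)
        n, k = self.X.shape
        genome_len = n + k
        p_mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / genome_len

        pop = [self._random_candidate(rng) for _ in range(cfg.pop_size)]
        pop = [fitness(c, self.X, self.y, cfg) for c in pop]
        best = min(pop, key=Candidate.key)
        trace = [best.fitness]

        for _ in range(cfg.generations):
            nxt: list[Candidate] = [
                Candidate(best.split.copy(), best.mask.copy(), best.fitness, best.flag)
            ][: cfg.elitism]
            while len(nxt) < cfg.pop_size:
                p1, p2 = self._tournament(pop, rng), self._tournament(pop, rng)
                g1 = np.concatenate([p1.split, p1.mask])
                g2 = np.concatenate([p2.split, p2.mask])
                if rng.random() < cfg.crossover_rate:
                    swap = rng.random(genome_len) < 0.5
                    child = np.where(swap, g2, g1)
                else:
                    child = g1.copy()
                child ^= rng.random(genome_len) < p_mut
                cand = Candidate(split=child[:n].copy(), mask=child[n:].copy())
                if not cand.mask.any():
                    cand.mask[rng.integers(k)] = True
                nxt.append(fitness(cand, self.X, self.y, cfg))
            pop = nxt
            gen_best = min(pop, key=Candidate.key)
            if gen_best.key() < best.key():
                best = gen_best
            trace.append(best.fitness)

        selected = [v for v, m in zip(self.variables, best.mask) if m]
        return TwistResults(
            best=best,
            trace=trace,
            selected=selected,
            variables=list(self.variables),
            config=cfg,
        )
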