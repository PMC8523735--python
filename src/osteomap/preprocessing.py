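"""Scaling, complement ("high"/"low") expansion and descriptive statistics.

Before semantic mapping, each of the k baseline variables is min-max scaled
to [0, 1] and paired with its complement: ``x_high = (x - lo) / (hi - lo)``
and ``x_low = 1 - x_high``.  The doubled (2k-column) representation lets an
association network express links that involve *low* values of a variable
(e.g. "low total-femur strain goes with no incident fracture") just as
directly as links involving high values.

Group descriptives follow the usual clinical-table layout: per-group mean,
SD and range with a Welch two-sample t-test per variable, plus plain
Pearson correlations for the variable-versus-outcome panel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaledTable",
    "minmax_scale",
    "minmax_unscale",
    "complement_expand",
    "group_stats",
    "pearson_corr",
    "outcome_correlations",
]


def minmax_scale(
    x, lo: float, hi: float, clip: bool = True
):
    """Scale ``x`` linearly so ``lo -> 0`` and ``hi -> 1``.

    Out-of-range inputs are clipped into [0, 1] with a warning (they arise
    when stored bounds from a reference cohort are applied to new records).
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    arr = np.asarray(x, dtype=float)
    out = (arr - lo) / (hi - lo)
    if clip:
        oob = (out < 0) | (out > 1)
        if np.any(oob):
            warnings.warn(
                f"{int(np.sum(oob))} value(s) outside [{lo}, {hi}] clipped",
                stacklevel=2,
            )
            out = np.clip(out, 0.0, 1.0)
    return float(out) if arr.ndim == 0 else out


def minmax_unscale(x, lo: float, hi: float):
    """Inverse of :func:`minmax_scale` (no clipping)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    arr = np.asarray(x, dtype=float)
    out = lo + arr * (hi - lo)
    return float(out) if arr.ndim == 0 else out


@dataclass
class ScaledTable:
    """2k-column [0, 1] matrix with paired ``_high``/``_low`` variables."""

    data: pd.DataFrame
    bounds: dict[str, tuple[float, float]]

    @property
    def variables(self) -> list[str]:
        return list(self.bounds)

    def to_csv(self, path) -> None:
        """Write the matrix as CSV with a JSON sidecar of scaling bounds."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(".bounds.json")
        sidecar.write_text(
            json.dumps({k: list(v) for k, v in self.bounds.items()}, indent=2)
        )

    @classmethod
    def from_csv(cls, path) -> "ScaledTable":
        path = Path(path)
        data = pd.read_csv(path)
        bounds = json.loads(path.with_suffix(".bounds.json").read_text())
        return cls(data=data, bounds={k: tuple(v) for k, v in bounds.items()})


def complement_expand(
    table: pd.DataFrame,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> ScaledTable:
    """Min-max scale every column and append its 1-x complement.

    ``bounds`` may supply (lo, hi) per variable (defaults to the column's
    observed range).  A constant column, or a table that already carries
    ``_high``/``_low`` columns, is rejected.
    """
    already = [c for c in table.columns if c.endswith(("_high", "_low"))]
    if already:
        raise ValueError(
            f"table appears already complement-expanded (columns {already[:3]}...)"
        )
    bounds = dict(bounds) if bounds else {}
    cols: dict[str, np.ndarray] = {}
    used: dict[str, tuple[float, float]] = {}
    for name in table.columns:
        x = table[name].to_numpy(dtype=float)
        lo, hi = bounds.get(name, (float(np.min(x)), float(np.max(x))))
        if not lo < hi:
            raise ValueError(f"variable {name!r} is constant (lo == hi == {lo})")
        high = minmax_scale(x, lo, hi)
        cols[f"{name}_high"] = high
        cols[f"{name}_low"] = 1.0 - high
        used[name] = (lo, hi)
    return ScaledTable(data=pd.DataFrame(cols, index=table.index), bounds=used)


def group_stats(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    outcome: str = "fracture",
) -> pd.DataFrame:
    """Per-variable group mean/SD/range plus a Welch two-sided t-test.

    Returns one row per variable with columns ``mean_1/sd_1`` (outcome = 1,
    the fractured group), ``mean_0/sd_0``, whole-sample ``range_low/high``,
    ``p_value`` and a ``flag`` marking variables where a group has n < 2
    (SD and p undefined there).
    """
    if variables is None:
        drop = {outcome, "patient_id", "followup_years"}
        variables = [c for c in cohort.columns if c not in drop]
    g1 = cohort[cohort[outcome] == 1]
    g0 = cohort[cohort[outcome] == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both outcome groups must be nonempty")
    rows = []
    for v in variables:
        x1 = g1[v].to_numpy(dtype=float)
        x0 = g0[v].to_numpy(dtype=float)
        small = len(x1) < 2 or len(x0) < 2
        if small:
            p = np.nan
        else:
            p = float(stats.ttest_ind(x1, x0, equal_var=False).pvalue)
        rows.append(
            {
                "variable": v,
                "mean_1": float(np.mean(x1)),
                "sd_1": float(np.std(x1, ddof=1)) if len(x1) >= 2 else np.nan,
                "mean_0": float(np.mean(x0)),
                "sd_0": float(np.std(x0, ddof=1)) if len(x0) >= 2 else np.nan,
                "range_low": float(cohort[v].min()),
                "range_high": float(cohort[v].max()),
                "p_value": p,
                "flag": "group n < 2" if small else "",
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def pearson_corr(x, y) -> float:
    """Product-moment correlation with explicit degenerate-input guards."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    return float(stats.pearsonr(x, y).statistic)


def outcome_correlations(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    outcome: str = "fracture",
) -> pd.Series:
    """Pearson r of each variable against the binary outcome (point-biserial)."""
    if variables is None:
        drop = {outcome, "patient_id", "followup_years"}
        variables = [c for c in cohort.columns if c not in drop]
    y = cohort[outcome].to_numpy(dtype=float)
    return pd.Series(
        {v: pearson_corr(cohort[v].to_numpy(dtype=float), y) for v in variables},
        name="pearson_r",
    )
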