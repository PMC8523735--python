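"""End-to-end orchestration: simulate -> BSI -> preprocess -> TWIST -> ANN -> map.

Each stage persists its outputs under the run directory and consumes only
the persisted outputs of its predecessors, so stages can be re-run
individually (the CLI exposes one subcommand per stage).  A single global
seed is expanded into per-stage seeds by a counter scheme
``stage_seed = (seed * 1000003 + counter) mod 2^31``; the mapping is logged
in the run report.  Reports contain no timestamps, so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .autocm import AutoContractiveMap, adjacency_report, semantic_input
from .bsi import BSIConfig, calibrate_scale, compute_bsi
from .classifier import TrainConfig, ab_ba_protocol, tripartite_protocol
from .cohort import (
    VARIABLES,
    assign_outcomes,
    generate_cohort,
    generate_population,
    read_cohort_csv,
)
from .phantom import generate_phantom
from .preprocessing import ScaledTable, complement_expand, group_stats, outcome_correlations
from .twist import TwistConfig, TwistSelector

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline", "stage_seed"]

_STAGE_COUNTERS = {"cohort": 1, "bsi": 2, "twist": 3, "ann": 4, "autocm": 5}


def stage_seed(seed: int, stage: str) -> int:
    """Counter-based per-stage seed derived from the global seed."""
    return (seed * 1000003 + _STAGE_COUNTERS[stage]) % (2**31)


class CohortStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_frac: int = Field(default=69, ge=0)
    n_nonfrac: int = Field(default=105, ge=0)
    mode: str = Field(default="groups", pattern="^(groups|logistic)$")
    #: logistic mode only: planted standardized coefficients and prevalence
    coefficients: dict[str, float] = Field(default_factory=dict)
    prevalence: float = Field(default=69 / 174, ge=0.0, le=1.0)


class BSIStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    refinement: int = Field(default=1, ge=1)
    noise_sd: float = Field(default=0.03, ge=0.0)
    poisson: float = Field(default=0.3, gt=0.0, lt=0.5)


class TwistStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = True
    pop_size: int = Field(default=24, ge=2)
    generations: int = Field(default=15, ge=0)
    probe: str = Field(default="mlp", pattern="^(mlp|centroid)$")
    probe_epochs: int = Field(default=60, ge=1)


class AnnStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int = Field(default=500, ge=1)
    learning_rate: float = Field(default=0.01, gt=0.0)
    hidden: int | None = Field(default=None)


class AutoCMStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_epochs: int = Field(default=1000, ge=1)
    tol: float = Field(default=1e-6, gt=0.0)
    contraction: float | None = Field(default=None, gt=0.0)


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    cohort: CohortStage = Field(default_factory=CohortStage)
    bsi: BSIStage = Field(default_factory=BSIStage)
    twist: TwistStage = Field(default_factory=TwistStage)
    ann: AnnStage = Field(default_factory=AnnStage)
    autocm: AutoCMStage = Field(default_factory=AutoCMStage)

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def validate_config(path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse a JSON config; returns (config, errors) with *all* errors listed.

    Error entries carry JSON-pointer-style paths, e.g.
    ``/cohort/n_frac: Input should be greater than or equal to 0``.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        return None, [f"/: unreadable config ({exc})"]
    try:
        return PipelineConfig.model_validate(raw), []
    except ValidationError as exc:
        errors = [
            "/" + "/".join(str(p) for p in err["loc"]) + f": {err['msg']}"
            for err in exc.errors()
        ]
        return None, errors


@dataclass
class RunReport:
    """Aggregated, regenerable summary of one pipeline run."""

    payload: dict

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.payload, indent=2, sort_keys=True))

    @property
    def pooled_accuracy(self) -> float:
        return self.payload["ann"]["pooled"]["accuracy_pct"]


# --------------------------------------------------------------------------
# stages


def run_stage_cohort(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    seed = stage_seed(config.seed, "cohort")
    c = config.cohort
    if c.mode == "groups":
        table = generate_cohort(n_frac=c.n_frac, n_nonfrac=c.n_nonfrac, seed=seed)
    else:
        table = generate_population(n=c.n_frac + c.n_nonfrac, seed=seed)
        table = assign_outcomes(table, c.coefficients, c.prevalence, seed=seed + 1)
    table.to_csv(outdir / "cohort.csv", index=False)
    return table


def run_stage_bsi(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    """Recompute lumbar and total-femur BSI per patient via the FEM.

    Each patient gets one vertebral and one femoral phantom whose mask-mean
    BMD equals their L_BMD / Ftot_BMD; the FEM BSI (calibrated per site to
    the population means) replaces the generator's L_BSI and Ftot_BSI
    columns.  Neck BSI has no dedicated load case and is retained.
    """
    table = read_cohort_csv(outdir / "cohort.csv")
    seed = stage_seed(config.seed, "bsi")
    base = BSIConfig(refinement=config.bsi.refinement, poisson=config.bsi.poisson)
    cfg = {site: calibrate_scale(base, site=site) for site in ("vertebra", "femur")}
    rows = []
    for i, rec in table.iterrows():
        out = {}
        for site, bmd_col in (("vertebra", "L_BMD"), ("femur", "Ftot_BMD")):
            ph = generate_phantom(
                site=site,
                target_bmd=float(rec[bmd_col]),
                noise_sd=config.bsi.noise_sd,
                weight=float(rec["weight"]),
                seed=(seed + 7 * i) % (2**31),
            )
            res = compute_bsi(ph, cfg[site])
            out[site] = res.values[1]
        rows.append(out)
    table = table.copy()
    table["L_BSI"] = [r["vertebra"] for r in rows]
    table["Ftot_BSI"] = [r["femur"] for r in rows]
    table.to_csv(outdir / "cohort_bsi.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": table["patient_id"],
            "lumbar_bsi": table["L_BSI"],
            "total_femur_bsi": table["Ftot_BSI"],
        }
    ).to_csv(outdir / "bsi_table.csv", index=False)
    return table


def _load_cohort(outdir: Path) -> pd.DataFrame:
    path = outdir / "cohort_bsi.csv"
    if not path.exists():
        path = outdir / "cohort.csv"
    return read_cohort_csv(path)


def run_stage_preprocess(config: PipelineConfig, outdir: Path) -> ScaledTable:
    table = _load_cohort(outdir)
    stats = group_stats(table, variables=VARIABLES)
    stats.to_csv(outdir / "table1_stats.csv")
    outcome_correlations(table, variables=VARIABLES).to_csv(
        outdir / "fig3_corr.csv", header=True
    )
    scaled = complement_expand(table[VARIABLES])
    scaled.to_csv(outdir / "scaled.csv")
    return scaled


def run_stage_twist(config: PipelineConfig, outdir: Path) -> dict:
    table = _load_cohort(outdir)
    tw = config.twist
    selector = TwistSelector(
        table[VARIABLES],
        table["fracture"],
        config=TwistConfig(
            pop_size=tw.pop_size,
            generations=tw.generations,
            probe=tw.probe,
            probe_epochs=tw.probe_epochs,
        ),
    )
    results = selector.fit(seed=stage_seed(config.seed, "twist"))
    payload = results.to_dict()
    (outdir / "twist.json").write_text(json.dumps(payload, indent=2))
    pd.DataFrame(
        {"generation": range(len(results.trace)), "best_fitness": results.trace}
    ).to_csv(outdir / "twist_trace.csv", index=False)
    return payload


def _selected_matrix(outdir: Path) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    table = _load_cohort(outdir)
    twist_path = outdir / "twist.json"
    if twist_path.exists():
        tw = json.loads(twist_path.read_text())
        selected = tw["selected"]
        split_b = np.asarray(tw["split_b"], dtype=bool)
    else:  # no TWIST stage: use all variables, alternating split
        selected = list(VARIABLES)
        split_b = np.arange(len(table)) % 2 == 1
        tw = {"selected": selected, "split_b": split_b.astype(int).tolist()}
    scaled = ScaledTable.from_csv(outdir / "scaled.csv")
    X = scaled.data[[f"{v}_high" for v in selected]].to_numpy()
    y = table["fracture"].to_numpy(dtype=int)
    return X, y, selected, {"split_b": split_b}


def run_stage_ann(config: PipelineConfig, outdir: Path) -> dict:
    X, y, selected, extra = _selected_matrix(outdir)
    split_b = extra["split_b"]
    cfg = TrainConfig(
        hidden=config.ann.hidden,
        epochs=config.ann.epochs,
        learning_rate=config.ann.learning_rate,
        seed=stage_seed(config.seed, "ann"),
    )
    a, b = ~split_b, split_b
    arm_ab, arm_ba, pooled = ab_ba_protocol(X[a], y[a], X[b], y[b], cfg)
    table2 = pd.DataFrame(
        {
            "sequence AB": arm_ab.to_dict(),
            "sequence BA": arm_ba.to_dict(),
            "Sum/mean": pooled.to_dict(),
        }
    ).T
    table2.to_csv(outdir / "table2_metrics.csv")

    # tripartite 64/60/50 split, scaled proportionally to the cohort size
    n = len(y)
    rng = np.random.default_rng(stage_seed(config.seed, "ann") + 1)
    order = rng.permutation(n)
    n1 = max(int(round(n * 64 / 174)), 4)
    n2 = max(int(round(n * 60 / 174)), 4)
    split = {
        "train": order[:n1],
        "test": order[n1 : n1 + n2],
        "validation": order[n1 + n2 :],
    }
    table3 = tripartite_protocol(X, y, split, cfg)
    table3.to_csv(outdir / "table3_metrics.csv")

    payload = {
        "selected_variables": selected,
        "arm_ab": arm_ab.to_dict(),
        "arm_ba": arm_ba.to_dict(),
        "pooled": pooled.to_dict(),
        "tripartite": {k: row.to_dict() for k, row in table3.iterrows()},
    }
    (outdir / "ann_metrics.json").write_text(json.dumps(payload, indent=2))
    return payload


def run_stage_autocm(config: PipelineConfig, outdir: Path) -> dict:
    table = _load_cohort(outdir)
    scaled = ScaledTable.from_csv(outdir / "scaled.csv")
    data = semantic_input(scaled.data, table["fracture"])
    model = AutoContractiveMap(data, C=config.autocm.contraction)
    results = model.fit(max_epochs=config.autocm.max_epochs, tol=config.autocm.tol)
    graph = results.mst()
    graph.write_edgelist_csv(outdir / "semantic_edges.csv")
    graph.write_graphml(outdir / "semantic_map.graphml")
    report = adjacency_report(graph, "new_fracture_no")
    report.to_csv(outdir / "adjacency_new_fracture_no.csv", index=False)
    return {
        "converged": results.weights.converged,
        "epochs": results.weights.epochs,
        "new_fracture_no_neighbors": report.to_dict(orient="records"),
        "edges": graph.edges().to_dict(orient="records"),
    }


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Run all enabled stages and write ``report.json``.

    If the BSI stage is disabled the cohort's generated BSI columns are used
    as-is (stage bypass).  Any stage failure propagates with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload: dict = {
        "provenance": {
            "package": "osteomap",
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_COUNTERS},
            "config_hash": config.content_hash(),
            "config": config.model_dump(),
        }
    }
    stages = [
        ("cohort", run_stage_cohort, True),
        ("bsi", run_stage_bsi, config.bsi.enabled),
        ("preprocess", run_stage_preprocess, True),
        ("twist", run_stage_twist, config.twist.enabled),
        ("ann", run_stage_ann, True),
        ("autocm", run_stage_autocm, True),
    ]
    for name, fn, enabled in stages:
        if not enabled:
            payload[name] = {"skipped": True}
            continue
        try:
            result = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if name == "cohort":
            payload[name] = {"records": len(result), "fracture_yes": int(result["fracture"].sum())}
        elif name == "bsi":
            payload[name] = {
                "lumbar_bsi_mean": float(result["L_BSI"].mean()),
                "total_femur_bsi_mean": float(result["Ftot_BSI"].mean()),
            }
        elif name == "preprocess":
            payload[name] = {"columns": len(result.data.columns)}
        else:
            payload[name] = result
    report = RunReport(payload=payload)
    report.to_json(outdir / "report.json")
    return report
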