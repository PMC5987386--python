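"""Readers/writers, pipeline configuration and the end-to-end pipeline.

The tabular interchange format is CSV throughout (no domain standard exists
for BALF/cytokine dose-response tables); structured reports are JSON with
floats at full precision — display rounding happens only in rendered
tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import bmd, comparison, loael, pooling, reference, synth
from .bmd import BmdResult, ResponseTable
from .dose_metrics import (
    DoseQuantity,
    ExposureContext,
    METRICS,
    convert,
    default_contexts,
)

logger = logging.getLogger("nanobmd")

RESPONSE_COLUMNS = (
    "material_id", "context_id", "endpoint",
    "dose_value", "dose_metric", "replicate_id", "response",
)


@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on, in one serialisable object."""

    seed: int = 20180604
    ces: float = 0.20
    confidence: float = 0.90
    alpha: float = 0.05
    selection: str = "lr"
    ssa_basis: str = "agglomerate"
    nd_policy: str = "exclude"
    metric: str = "ug_per_cm2"
    sigma: float = 0.25
    noise: str = "lognormal"
    input_csv: str | None = None
    context_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.ces:
            raise ValueError("ces must be > 0")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(self.input_csv)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)


def read_response_csv(path: str | Path) -> list[ResponseTable]:
    """Read and validate a replicate-level response CSV.

    Schema: material_id, context_id, endpoint, dose_value, dose_metric,
    replicate_id, response (response_units optional).  Row-level problems
    are reported with their CSV line numbers.
    """
    frame = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(
            f"{path}: schema mismatch, missing columns {sorted(missing)}"
        )
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    errors = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        dose = row["dose_value"]
        resp = row["response"]
        if not (isinstance(dose, (int, float)) and math.isfinite(dose)) or dose < 0:
            errors.append(f"line {line}: invalid dose_value {dose!r}")
        if not (isinstance(resp, (int, float)) and math.isfinite(resp)) or resp <= 0:
            errors.append(f"line {line}: response must be > 0, got {resp!r}")
        if row["dose_metric"] not in METRICS:
            errors.append(f"line {line}: unknown metric {row['dose_metric']!r}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))

    tables = []
    for (material, cid, endpoint), group in frame.groupby(
        ["material_id", "context_id", "endpoint"], sort=True
    ):
        metrics = group["dose_metric"].unique()
        if len(metrics) > 1:
            raise ValueError(
                f"{path}: {material}/{cid}/{endpoint} mixes dose metrics "
                f"{sorted(metrics)}"
            )
        tables.append(
            ResponseTable(
                material_id=str(material),
                context_id=str(cid),
                endpoint=str(endpoint),
                metric=str(metrics[0]),
                doses=group["dose_value"].to_numpy(float),
                responses=group["response"].to_numpy(float),
                replicate_ids=group["replicate_id"].to_numpy(),
            )
        )
    return tables


def write_response_csv(tables: Sequence[ResponseTable], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


def table_in_metric(
    table: ResponseTable,
    target_metric: str,
    ctx: ExposureContext,
    **convert_kwargs,
) -> ResponseTable:
    """Re-express a table's doses in another metric (responses untouched)."""
    if table.metric == target_metric:
        return table
    factor = convert(
        DoseQuantity(1.0, table.metric, table.context_id),
        target_metric, ctx, **convert_kwargs,
    ).value
    return dataclasses.replace(
        table, doses=table.doses * factor, metric=target_metric
    )


def bmd_results_frame(results: Sequence[BmdResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        model = r.selected_model
        rows.append(
            {
                "material_id": r.material_id,
                "context_id": r.context_id,
                "endpoint": r.endpoint,
                "metric": r.metric,
                "ces": r.ces,
                "confidence": r.confidence,
                "status": r.status,
                "ced": r.ced,
                "bmdl": r.bmdl,
                "bmdu": r.bmdu,
                "model_id": model.model_id if model else None,
                "sigma": model.sigma if model else None,
            }
        )
    return pd.DataFrame(rows)


def pooled_frame(pooled: Sequence[pooling.PooledInterval]) -> pd.DataFrame:
    rows = [
        {
            "material_id": p.material_id,
            "context_id": p.context_id,
            "metric": p.metric,
            "bmdl_median": p.bmdl_median,
            "bmdu_median": p.bmdu_median,
            "n_defined": p.n_defined,
            "display": p.display(),
        }
        for p in pooled
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate or ingest -> fit BMD -> pool -> LOAEL -> compare.

    Returns the report bundle as a dict of DataFrames plus a JSON-ready
    summary; fully deterministic for a given config (and seed, when
    simulating).
    """
    contexts = default_contexts(config.context_overrides or None)
    materials = reference.reference_materials()

    if config.input_csv:
        logger.info("reading responses from %s", config.input_csv)
        tables = read_response_csv(config.input_csv)
        truth_ledger = None
    else:
        logger.info("simulating default study (seed=%d)", config.seed)
        design = synth.default_study_design(
            sigma=config.sigma, ces=config.ces, noise=config.noise
        )
        table_map, truth_ledger = synth.generate_study(design, config.seed)
        tables = list(table_map.values())

    # fit every endpoint table in the common comparison metric
    results: list[BmdResult] = []
    for table in tables:
        ctx = contexts[table.context_id]
        harmonised = table_in_metric(table, config.metric, ctx)
        results.append(
            bmd.fit_bmd(
                harmonised,
                ces=config.ces,
                confidence=config.confidence,
                selection=config.selection,
                alpha=config.alpha,
                seed=config.seed,
            )
        )

    interval_grid = pooling.build_interval_table(
        results, config.metric, nd_policy=config.nd_policy
    )
    pooled = [cell for cell in interval_grid.to_numpy().ravel() if cell is not None]

    loael_results = []
    grouped: dict[tuple[str, str], dict[str, ResponseTable]] = {}
    for table in tables:
        ctx = contexts[table.context_id]
        harmonised = table_in_metric(table, config.metric, ctx)
        grouped.setdefault(
            (harmonised.material_id, harmonised.context_id), {}
        )[harmonised.endpoint] = harmonised
    for (_, _), endpoint_tables in sorted(grouped.items()):
        loael_results.append(
            loael.determine_loael(endpoint_tables, alpha=config.alpha)
        )

    rankings = {}
    for cid in contexts:
        cell_intervals = [p for p in pooled if p.context_id == cid]
        if len(cell_intervals) >= 2:
            rankings[cid] = comparison.rank_materials(cell_intervals)

    views = comparison.apply_metric_views(pooled, materials, contexts)

    report = {
        "config": dataclasses.asdict(config),
        "bmd_results": bmd_results_frame(results),
        "pooled_intervals": pooled_frame(pooled),
        "loaels": pd.DataFrame(
            [
                {
                    "material_id": r.material_id,
                    "context_id": r.context_id,
                    "metric": r.metric,
                    "loael": r.loael,
                }
                for r in loael_results
            ]
        ),
        "rankings": {
            cid: {"order": rk.order, "tie_groups": rk.tie_groups,
                  "nd": rk.nd_materials}
            for cid, rk in rankings.items()
        },
        "metric_views": views,
    }
    if truth_ledger is not None:
        # express the true CEDs in the fitting metric before scoring
        harmonised_ledger = truth_ledger.copy()
        for idx, row in harmonised_ledger.iterrows():
            if row["metric"] != config.metric:
                ctx = contexts[row["context_id"]]
                factor = convert(
                    DoseQuantity(1.0, row["metric"], row["context_id"]),
                    config.metric, ctx,
                ).value
                harmonised_ledger.loc[idx, "true_ced"] = row["true_ced"] * factor
                harmonised_ledger.loc[idx, "metric"] = config.metric
        report["truth_ledger"] = harmonised_ledger
        report["recovery"] = synth.score_recovery(results, harmonised_ledger)
    return report


def write_report(report: Mapping, out_dir: str | Path) -> None:
    """Write the pipeline report bundle: CSV per table, JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for name, payload in report.items():
        if isinstance(payload, pd.DataFrame):
            payload.to_csv(out / f"{name}.csv", index=False)
            summary[name] = f"{name}.csv"
        else:
            summary[name] = payload
    with open(out / "report.json", "w") as handle:
        json.dump(summary, handle, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")
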