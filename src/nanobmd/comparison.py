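"""Cross-method comparison: fold-differences, metric views and rankings.

The in vivo instillation result is the reference; each in vitro method is
characterised by the fold-difference of its LOAEL (or interval bound) to the
in vivo one, in a shared dose metric.  Materials within one method are
ranked by the pooled BMDL (the conservative lower interval bound), with
materials whose pooled intervals overlap placed in a single tie group and
materials without a determinable interval (ND) listed last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .dose_metrics import DoseQuantity, ExposureContext, convert
from .materials import MaterialRecord
from .pooling import PooledInterval

__all__ = [
    "MaterialRanking",
    "fold_difference",
    "rank_materials",
    "apply_metric_views",
    "loael_fold_table",
]

#: Fig.-5-style views of the pooled intervals
METRIC_VIEWS = (
    "ug_per_cm2",
    "ug_per_1e6_macrophages",
    "cm2_per_1e6_macrophages_primary",
    "cm2_per_1e6_macrophages_agglomerate",
)


@dataclass
class MaterialRanking:
    """Materials of one context x metric ordered from most to least potent."""

    context_id: str
    metric: str
    order: list[str]  # every material exactly once, ND last
    tie_groups: list[list[str]] = field(default_factory=list)
    nd_materials: list[str] = field(default_factory=list)


def fold_difference(loael_a: DoseQuantity, loael_b: DoseQuantity) -> float:
    """Ratio a / b of two effect doses expressed in the same metric."""
    if loael_a.metric != loael_b.metric:
        raise ValueError(
            f"metric mismatch: {loael_a.metric!r} vs {loael_b.metric!r}"
        )
    if loael_b.value == 0:
        raise ZeroDivisionError("reference effect dose is zero")
    return loael_a.value / loael_b.value


def loael_fold_table(
    loaels: Mapping[str, float | None],
    metric: str,
    reference_context: str = "in_vivo_instillation",
) -> pd.DataFrame:
    """Fold-difference of each method's LOAEL to the reference method.

    ``loaels`` maps context_id to a LOAEL value in ``metric`` (None = no
    significant effect).  Undefined operands give a NaN fold with a flag.
    """
    reference = loaels.get(reference_context)
    rows = []
    for context_id, value in loaels.items():
        if value is None or reference is None:
            fold, defined = math.nan, False
        else:
            fold = fold_difference(
                DoseQuantity(value, metric, context_id),
                DoseQuantity(reference, metric, reference_context),
            )
            defined = True
        rows.append(
            {"context_id": context_id, "loael": value, "fold_vs_reference": fold,
             "defined": defined}
        )
    return pd.DataFrame(rows)


def _overlap(a: PooledInterval, b: PooledInterval) -> bool:
    """Closed-interval intersection, unbounded uppers treated as +inf."""
    a_hi = a.bmdu_median if a.bmdu_median is not None else math.inf
    b_hi = b.bmdu_median if b.bmdu_median is not None else math.inf
    return a.bmdl_median <= b_hi and b.bmdl_median <= a_hi


def rank_materials(pooled: Sequence[PooledInterval]) -> MaterialRanking:
    """Rank materials of one context x metric by pooled BMDL (ascending).

    A lower interval means potency at lower dose.  Materials whose closed
    intervals overlap (transitively) form one tie group; ND materials are
    appended last, never interleaved.
    """
    if len(pooled) < 2:
        raise ValueError("ranking needs at least two materials")
    keys = {(p.context_id, p.metric) for p in pooled}
    if len(keys) > 1:
        raise ValueError(f"intervals mix context/metric: {sorted(keys)}")
    context_id, metric = next(iter(keys))

    defined = sorted((p for p in pooled if p.defined), key=lambda p: p.bmdl_median)
    nd = sorted(p.material_id for p in pooled if not p.defined)

    tie_groups: list[list[PooledInterval]] = []
    for interval in defined:
        if tie_groups and any(_overlap(interval, o) for o in tie_groups[-1]):
            tie_groups[-1].append(interval)
        else:
            tie_groups.append([interval])
    groups = [[p.material_id for p in g] for g in tie_groups]
    order = [m for g in groups for m in g] + nd
    return MaterialRanking(
        context_id=context_id,
        metric=metric,
        order=order,
        tie_groups=groups,
        nd_materials=nd,
    )


def apply_metric_views(
    pooled: Sequence[PooledInterval],
    materials: Mapping[str, MaterialRecord],
    contexts: Mapping[str, ExposureContext],
) -> pd.DataFrame:
    """Express pooled ug/cm^2 intervals in all four comparison views.

    Views: mass per (alveolar or cell-layer) surface, mass per million
    macrophages, and surface area per million macrophages under the
    primary-BET and the agglomerate SSA basis.  The agglomerate view uses
    the medium actually reaching the cells: aerosol at the ALI, suspension
    for instillation and submerged exposures.  Cells whose material lacks
    the needed medium are flagged rather than silently dropped.
    """
    rows = []
    for interval in pooled:
        if interval.metric != "ug_per_cm2":
            raise ValueError("metric views start from ug/cm^2 intervals")
        ctx = contexts[interval.context_id]
        material = materials.get(interval.material_id)
        for view in METRIC_VIEWS:
            row = {
                "material_id": interval.material_id,
                "context_id": interval.context_id,
                "view": view,
                "bmdl": None,
                "bmdu": None,
                "flag": "",
            }
            if not interval.defined:
                row["flag"] = "ND"
                rows.append(row)
                continue
            basis = None
            if view == "cm2_per_1e6_macrophages_primary":
                target, basis = "cm2_per_1e6_macrophages", "primary-BET"
            elif view == "cm2_per_1e6_macrophages_agglomerate":
                target, basis = "cm2_per_1e6_macrophages", "agglomerate"
            else:
                target = view
            try:
                row["bmdl"], row["bmdu"] = (
                    convert(
                        DoseQuantity(v, "ug_per_cm2", interval.context_id),
                        target,
                        ctx,
                        material=material,
                        ssa_basis=basis or "agglomerate",
                    ).value
                    if v is not None and math.isfinite(v)
                    else v
                    for v in (interval.bmdl_median, interval.bmdu_median)
                )
            except (KeyError, ValueError) as err:
                row["flag"] = f"missing_conversion: {err}"
            rows.append(row)
    return pd.DataFrame(rows)
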