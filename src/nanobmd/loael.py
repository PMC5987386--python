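"""LOAEL determination by rank-based multiple comparison to control.

Replicate responses at each dose are compared with the unexposed control
using the Kruskal-Wallis omnibus test followed by Dunn's post-hoc z tests
on the pooled mid-ranks (with the standard tie correction).  Dunn p-values
are adjusted over the treated-versus-control family (Bonferroni by default,
Holm or none selectable).  The LOAEL of a material under one exposure
method is the smallest tested dose whose adjusted p-value falls below
alpha on any included endpoint; if no dose is significant on any endpoint
there is no LOAEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .bmd import ResponseTable

__all__ = ["LoaelResult", "kruskal_wallis", "dunn_vs_control", "determine_loael"]

ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass
class LoaelResult:
    material_id: str
    context_id: str
    metric: str
    alpha: float
    loael: float | None  # smallest significant tested dose, any endpoint
    per_endpoint_loael: dict[str, float | None] = field(default_factory=dict)
    adjusted_p: dict[str, dict[float, float]] = field(default_factory=dict)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate all-identical data return (0.0, 1.0) instead of an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_vs_control(
    groups: Sequence[np.ndarray],
    control_index: int = 0,
    adjust: str = "bonferroni",
) -> np.ndarray:
    """Dunn's post-hoc test of each treated group against the control.

    Returns the adjusted two-sided p-value for every non-control group, in
    group order.  The z statistic for groups i, j uses pooled mid-ranks:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    with tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tied sets.
    """
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"unknown adjustment {adjust!r}; expected {ADJUSTMENTS}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [g.size for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i]: offsets[i + 1]])) for i in range(len(groups))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1))
    variance = n_total * (n_total + 1) / 12.0 - tie_term

    raw = []
    for i in range(len(groups)):
        if i == control_index:
            continue
        se2 = variance * (1.0 / sizes[i] + 1.0 / sizes[control_index])
        if se2 <= 0:  # fully tied data: no evidence against equality
            raw.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[control_index]) / np.sqrt(se2)
        raw.append(float(min(1.0, 2.0 * stats.norm.sf(abs(z)))))
    return _adjust(np.array(raw), adjust)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none" or p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    # Holm step-down
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, p[idx] * (p.size - rank))
        adjusted[idx] = min(running, 1.0)
    return adjusted


def determine_loael(
    tables: Mapping[str, ResponseTable] | Sequence[ResponseTable],
    alpha: float = 0.05,
    adjust: str = "bonferroni",
    gate_on_kruskal: bool = True,
) -> LoaelResult:
    """LOAEL for one material x context from its per-endpoint tables.

    Each endpoint table is split into dose groups; Dunn's comparisons to
    control run only when the Kruskal-Wallis omnibus test is significant
    (``gate_on_kruskal``).  The overall LOAEL is the smallest tested dose
    with adjusted p < alpha on any endpoint; per-endpoint LOAELs and all
    adjusted p-values are reported alongside.
    """
    if not isinstance(tables, Mapping):
        tables = {t.endpoint: t for t in tables}
    if not tables:
        raise ValueError("no response tables supplied")
    keys = {(t.material_id, t.context_id, t.metric) for t in tables.values()}
    if len(keys) > 1:
        raise ValueError(f"tables mix material/context/metric cells: {sorted(keys)}")
    material_id, context_id, metric = next(iter(keys))

    per_endpoint: dict[str, float | None] = {}
    all_p: dict[str, dict[float, float]] = {}
    for endpoint, table in tables.items():
        levels = table.dose_levels
        if levels.size < 3:
            raise ValueError(f"{endpoint}: need >= 2 dose levels plus control")
        groups = [table.responses[table.doses == lvl] for lvl in levels]
        _, omnibus_p = kruskal_wallis(groups)
        if gate_on_kruskal and omnibus_p >= alpha:
            adj = np.ones(levels.size - 1)
        else:
            adj = dunn_vs_control(groups, control_index=0, adjust=adjust)
        all_p[endpoint] = dict(zip(levels[1:], adj))
        significant = levels[1:][adj < alpha]
        per_endpoint[endpoint] = float(significant.min()) if significant.size else None

    defined = [v for v in per_endpoint.values() if v is not None]
    return LoaelResult(
        material_id=material_id,
        context_id=context_id,
        metric=metric,
        alpha=alpha,
        loael=min(defined) if defined else None,
        per_endpoint_loael=per_endpoint,
        adjusted_p=all_p,
    )
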