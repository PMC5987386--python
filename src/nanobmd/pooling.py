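"""Median pooling of per-cytokine BMD intervals.

A material x exposure-method cell yields one BMDL/BMDU interval per
pro-inflammatory mediator.  The general pro-inflammatory interval is the
median of the defined BMDLs and the median of the defined BMDUs across the
endpoints; endpoints with no determinable benchmark response (ND) are
excluded by default (an alternative policy treating ND as an infinitely
high dose is available).  With an even number of defined endpoints the
median is the midpoint of the two central values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .bmd import BmdResult
from .materials import round_sig

__all__ = ["PooledInterval", "pool_intervals", "pool_endpoints",
           "build_interval_table", "check_published_medians"]

ND_POLICIES = ("exclude", "infinite")


@dataclass
class PooledInterval:
    """Median BMDL/BMDU across endpoints for one material x method x metric."""

    material_id: str
    context_id: str
    metric: str
    bmdl_median: float | None
    bmdu_median: float | None
    endpoints_used: list[str]
    n_defined: int

    @property
    def defined(self) -> bool:
        return self.n_defined >= 1 and self.bmdl_median is not None

    def display(self, sig_figs: int = 2) -> str:
        if not self.defined:
            return "ND"
        hi = ("inf" if not math.isfinite(self.bmdu_median)
              else f"{round_sig(self.bmdu_median, sig_figs):g}")
        return f"{round_sig(self.bmdl_median, sig_figs):g}-{hi}"


def _median(values: Sequence[float]) -> float | None:
    if not values:
        return None
    return float(np.median(np.asarray(values, dtype=float)))


def pool_intervals(
    intervals: Iterable[tuple[float | None, float | None]],
    nd_policy: str = "exclude",
) -> tuple[float | None, float | None, int]:
    """Median-pool raw (bmdl, bmdu) pairs; ``None`` bounds mark ND endpoints.

    Returns (median BMDL, median BMDU, number of defined endpoints).  Under
    ``nd_policy='infinite'`` ND endpoints enter both medians as +inf instead
    of being dropped.
    """
    if nd_policy not in ND_POLICIES:
        raise ValueError(f"unknown ND policy {nd_policy!r}; expected {ND_POLICIES}")
    lowers: list[float] = []
    uppers: list[float] = []
    n_defined = 0
    for bmdl, bmdu in intervals:
        if bmdl is None or bmdu is None:
            if nd_policy == "infinite":
                lowers.append(math.inf)
                uppers.append(math.inf)
            continue
        n_defined += 1
        lowers.append(float(bmdl))
        uppers.append(float(bmdu))
    return _median(lowers), _median(uppers), n_defined


def pool_endpoints(
    results: Sequence[BmdResult],
    nd_policy: str = "exclude",
) -> PooledInterval:
    """Pool per-cytokine :class:`BmdResult` objects into one interval.

    All results must share material, context and metric.  Endpoints with
    status ``no_response`` count as ND; an unbounded upper limit enters the
    BMDU median as +inf.
    """
    if not results:
        raise ValueError("no results to pool")
    keys = {(r.material_id, r.context_id, r.metric) for r in results}
    if len(keys) > 1:
        raise ValueError(f"results mix material/context/metric cells: {sorted(keys)}")
    pairs = []
    for r in results:
        if not r.defined:
            pairs.append((None, None))
        else:
            pairs.append((r.bmdl, r.bmdu if r.bmdu is not None else math.inf))
    bmdl, bmdu, n_defined = pool_intervals(pairs, nd_policy=nd_policy)
    material_id, context_id, metric = next(iter(keys))
    return PooledInterval(
        material_id=material_id,
        context_id=context_id,
        metric=metric,
        bmdl_median=bmdl,
        bmdu_median=bmdu,
        endpoints_used=[r.endpoint for r in results],
        n_defined=n_defined,
    )


def build_interval_table(
    results: Sequence[BmdResult],
    metric: str,
    nd_policy: str = "exclude",
) -> pd.DataFrame:
    """Pool all results of one metric into a material x context grid.

    Rows are materials, columns contexts, cells :class:`PooledInterval`
    objects (ND cells preserved); empty input gives an empty frame.
    """
    subset = [r for r in results if r.metric == metric]
    cells: dict[tuple[str, str], PooledInterval] = {}
    for (material_id, context_id), group in _group_cells(subset):
        cells[(material_id, context_id)] = pool_endpoints(group, nd_policy=nd_policy)
    if not cells:
        return pd.DataFrame()
    materials = sorted({k[0] for k in cells})
    contexts = sorted({k[1] for k in cells})
    return pd.DataFrame(
        [[cells.get((m, c)) for c in contexts] for m in materials],
        index=pd.Index(materials, name="material_id"),
        columns=pd.Index(contexts, name="context_id"),
    )


def _group_cells(results: Sequence[BmdResult]):
    grouped: dict[tuple[str, str], list[BmdResult]] = {}
    for r in results:
        grouped.setdefault((r.material_id, r.context_id), []).append(r)
    return sorted(grouped.items())


def check_published_medians(
    intervals: pd.DataFrame,
    medians: pd.DataFrame,
    nd_policy: str = "exclude",
) -> pd.DataFrame:
    """Re-derive printed pooled medians from printed per-cytokine intervals.

    ``intervals`` has columns (context_id, material_id, endpoint, bmdl, bmdu)
    with NaN for ND; ``medians`` the printed (bmdl_median, bmdu_median).
    Each cell is marked consistent when both recomputed medians agree with
    the printed values within one unit in the last printed digit (the
    printed table rounds to about two significant figures, and several cells
    sit exactly on a rounding half).  Inconsistent cells are reported, never
    overwritten with the printed number.
    """
    rows = []
    for _, printed in medians.iterrows():
        cell = intervals[
            (intervals["context_id"] == printed["context_id"])
            & (intervals["material_id"] == printed["material_id"])
        ]
        pairs = [
            (None, None) if pd.isna(r["bmdl"]) or pd.isna(r["bmdu"])
            else (float(r["bmdl"]), float(r["bmdu"]))
            for _, r in cell.iterrows()
        ]
        bmdl, bmdu, n_defined = pool_intervals(pairs, nd_policy=nd_policy)
        printed_l = printed["bmdl_median"]
        printed_u = printed["bmdu_median"]
        if pd.isna(printed_l):
            consistent = n_defined == 0
        elif n_defined == 0:
            consistent = False
        else:
            consistent = _close_to_printed(bmdl, printed_l) and _close_to_printed(
                bmdu, printed_u
            )
        rows.append(
            {
                "context_id": printed["context_id"],
                "material_id": printed["material_id"],
                "computed_bmdl": bmdl,
                "computed_bmdu": bmdu,
                "printed_bmdl": printed_l,
                "printed_bmdu": printed_u,
                "n_defined": n_defined,
                "consistent": consistent,
            }
        )
    return pd.DataFrame(rows)


def _last_digit_unit(printed: float) -> float:
    """Size of one unit in the last printed decimal place."""
    text = f"{printed}"
    if "e" in text or "E" in text:
        return abs(printed) * 1e-2
    if "." in text:
        return 10.0 ** -len(text.split(".")[1])
    return 1.0


def _close_to_printed(computed: float | None, printed: float) -> bool:
    # one unit in the last printed digit, or 0.5% relative for cells the
    # original table printed from unrounded inputs at many digits
    if computed is None:
        return False
    tol = max(_last_digit_unit(printed), 0.005 * abs(printed))
    return abs(computed - printed) <= tol * (1.0 + 1e-9)
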