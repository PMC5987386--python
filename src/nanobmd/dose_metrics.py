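"""Deposited-dose metric conversions across exposure methods.

To compare intratracheal instillation in rats with cell-culture exposures
(air-liquid interface or submerged), deposited doses are expressed in
metrics that exist in every context:

* ``ug_per_lungs``      — total deposited mass (in vivo only);
* ``ug_per_cm2``        — mass per alveolar surface (in vivo) or per cell-layer
                          surface (in vitro);
* ``ug_per_1e6_macrophages`` — mass per million alveolar (-like) macrophages;
* ``cm2_per_1e6_macrophages`` — particle surface area per million macrophages,
                          obtained from the mass metric via a specific surface
                          area (BET or spherical-agglomerate).

Anatomical and culture constants are data, not code: the defaults are a rat
alveolar surface of 4000 cm^2 with 25e6 alveolar macrophages, 4.67 cm^2
inserts at 60,000 macrophages/cm^2 and 2 cm^2 plates at 25,000
macrophages/cm^2, all overridable per :class:`ExposureContext`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import pandas as pd

from .materials import MaterialRecord, choose_ssa, mass_dose_to_surface_dose, round_sig

__all__ = [
    "METRICS",
    "CONTEXT_IDS",
    "ExposureContext",
    "DoseQuantity",
    "MetricContextError",
    "default_contexts",
    "lungs_to_areal",
    "lungs_to_per_macrophage",
    "areal_to_per_macrophage",
    "convert",
    "DEFAULT_DOSE_GRIDS",
    "footnote_dose_grids",
]

METRICS = (
    "ug_per_lungs",
    "ug_per_cm2",
    "ug_per_1e6_macrophages",
    "cm2_per_1e6_macrophages",
)

CONTEXT_IDS = (
    "in_vivo_instillation",
    "ali_insert_3h21h",
    "submerged_insert_3h21h",
    "submerged_plate_24h",
)


class MetricContextError(ValueError):
    """A dose metric was used in, or converted within, an invalid context."""


@dataclass(frozen=True)
class ExposureContext:
    """Anatomy/culture constants of one exposure method.

    Exactly one of ``total_macrophages`` (whole-organ count, in vivo) or
    ``macrophage_density_per_cm2`` (in vitro) must be set.
    ``dose_delivery_window_h`` is descriptive metadata: the time over which
    the final deposited dose is reached (~0 h for an instilled bolus, 3 h for
    aerosol/insert delivery, 24 h for continuous plate sedimentation).
    """

    context_id: str
    reference_surface_cm2: float
    total_macrophages: float | None = None
    macrophage_density_per_cm2: float | None = None
    dose_delivery_window_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.reference_surface_cm2 > 0:
            raise ValueError("reference surface must be > 0 cm^2")
        if (self.total_macrophages is None) == (self.macrophage_density_per_cm2 is None):
            raise ValueError(
                "set exactly one of total_macrophages (in vivo) or "
                "macrophage_density_per_cm2 (in vitro)"
            )
        count = self.total_macrophages or self.macrophage_density_per_cm2
        if not count > 0:
            raise ValueError("macrophage count/density must be > 0")

    @property
    def in_vivo(self) -> bool:
        return self.total_macrophages is not None


_DEFAULTS = {
    "in_vivo_instillation": dict(
        reference_surface_cm2=4000.0, total_macrophages=25e6, dose_delivery_window_h=0.0
    ),
    "ali_insert_3h21h": dict(
        reference_surface_cm2=4.67, macrophage_density_per_cm2=60000.0,
        dose_delivery_window_h=3.0,
    ),
    "submerged_insert_3h21h": dict(
        reference_surface_cm2=4.67, macrophage_density_per_cm2=60000.0,
        dose_delivery_window_h=3.0,
    ),
    "submerged_plate_24h": dict(
        reference_surface_cm2=2.0, macrophage_density_per_cm2=25000.0,
        dose_delivery_window_h=24.0,
    ),
}


def default_contexts(
    overrides: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, ExposureContext]:
    """Build the four study contexts, optionally overriding any constant."""
    contexts = {}
    for cid, kwargs in _DEFAULTS.items():
        merged = dict(kwargs)
        if overrides and cid in overrides:
            merged.update(overrides[cid])
        contexts[cid] = ExposureContext(context_id=cid, **merged)
    return contexts


@dataclass(frozen=True)
class DoseQuantity:
    """A dose value tagged with its metric and exposure context."""

    value: float
    metric: str
    context_id: str
    material_id: str | None = None
    medium: str | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("dose value must be >= 0")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")


def lungs_to_areal(dose: float, ctx: ExposureContext) -> float:
    """ug/lungs -> ug/cm^2, dividing by the total alveolar surface."""
    if not ctx.in_vivo:
        raise MetricContextError(
            f"ug_per_lungs is only defined in vivo, not in {ctx.context_id!r}"
        )
    return dose / ctx.reference_surface_cm2


def lungs_to_per_macrophage(dose: float, ctx: ExposureContext) -> float:
    """ug/lungs -> ug per 10^6 alveolar macrophages."""
    if not ctx.in_vivo:
        raise MetricContextError(
            f"ug_per_lungs is only defined in vivo, not in {ctx.context_id!r}"
        )
    return dose / (ctx.total_macrophages / 1e6)


def areal_to_per_macrophage(dose: float, ctx: ExposureContext) -> float:
    """ug/cm^2 -> ug per 10^6 macrophage-like cells (in vitro contexts)."""
    if ctx.macrophage_density_per_cm2 is None:
        raise MetricContextError(
            f"{ctx.context_id!r} has no macrophage density; "
            "areal_to_per_macrophage applies to in vitro contexts"
        )
    return dose / (ctx.macrophage_density_per_cm2 / 1e6)


def _areal_factor(
    metric: str,
    ctx: ExposureContext,
    ssa: float | None,
) -> float:
    """Multiplicative factor taking a value in ``metric`` to ug/cm^2."""
    if metric == "ug_per_cm2":
        return 1.0
    if metric == "ug_per_lungs":
        if not ctx.in_vivo:
            raise MetricContextError(
                f"ug_per_lungs is not defined in context {ctx.context_id!r}; "
                "valid metrics there: ug_per_cm2, ug_per_1e6_macrophages, "
                "cm2_per_1e6_macrophages"
            )
        return 1.0 / ctx.reference_surface_cm2
    if metric == "ug_per_1e6_macrophages":
        if ctx.in_vivo:
            # per-macrophage -> total mass -> areal
            return (ctx.total_macrophages / 1e6) / ctx.reference_surface_cm2
        return ctx.macrophage_density_per_cm2 / 1e6
    if metric == "cm2_per_1e6_macrophages":
        if ssa is None:
            raise MetricContextError(
                "surface-area metric requires a resolvable SSA "
                "(pass material plus ssa_basis/medium)"
            )
        # cm^2/10^6 mac -> ug/10^6 mac is division by (ssa * 0.01)
        return _areal_factor("ug_per_1e6_macrophages", ctx, None) / (ssa * 0.01)
    raise ValueError(f"unknown metric {metric!r}")


def convert(
    dose: DoseQuantity,
    target_metric: str,
    ctx: ExposureContext,
    material: MaterialRecord | None = None,
    ssa_basis: str = "agglomerate",
    medium: str | None = None,
) -> DoseQuantity:
    """Convert a :class:`DoseQuantity` to ``target_metric`` within ``ctx``.

    Surface-area conversions resolve the SSA from ``material`` under
    ``ssa_basis`` ('primary-BET' or 'agglomerate'); for the agglomerate basis
    ``medium`` defaults to the dose's tagged medium.  Converting to the source
    metric is the identity.
    """
    if target_metric not in METRICS:
        raise ValueError(f"unknown metric {target_metric!r}; expected one of {METRICS}")
    if dose.context_id != ctx.context_id:
        raise MetricContextError(
            f"dose is tagged with context {dose.context_id!r}, got {ctx.context_id!r}"
        )
    if target_metric == dose.metric:
        return dose

    ssa = None
    use_medium = medium or dose.medium
    if "cm2_per_1e6_macrophages" in (dose.metric, target_metric):
        if material is None:
            raise MetricContextError(
                "surface-area metric requires a material record to resolve the SSA"
            )
        if ssa_basis == "agglomerate" and use_medium is None:
            # aerosol reaches the cells at the ALI; suspensions elsewhere
            use_medium = "aerosol" if ctx.context_id == "ali_insert_3h21h" else "suspension"
        ssa = choose_ssa(material, ssa_basis, use_medium)

    areal = dose.value * _areal_factor(dose.metric, ctx, ssa)
    value = areal / _areal_factor(target_metric, ctx, ssa)
    return replace(
        dose,
        value=value,
        metric=target_metric,
        material_id=material.material_id if material is not None else dose.material_id,
        medium=use_medium if target_metric == "cm2_per_1e6_macrophages" else dose.medium,
    )


#: primary (as-administered) dose grids per context, excluding control 0
DEFAULT_DOSE_GRIDS: dict[str, tuple[str, tuple[float, ...]]] = {
    "in_vivo_instillation": ("ug_per_lungs", (4.0, 40.0, 400.0)),
    "ali_insert_3h21h": ("ug_per_cm2", (0.1, 1.0, 3.0)),
    "submerged_insert_3h21h": ("ug_per_cm2", (1.0, 3.0, 10.0)),
    "submerged_plate_24h": ("ug_per_cm2", (1.0, 3.0, 10.0, 20.0)),
}


def footnote_dose_grids(
    contexts: Mapping[str, ExposureContext] | None = None,
    sig_figs: int = 3,
) -> pd.DataFrame:
    """Regenerate every published dose grid in every mass metric.

    Returns a tidy frame (context_id, metric, doses as a tuple) with values
    rounded to ``sig_figs`` significant figures, the footnote display style.
    """
    contexts = contexts or default_contexts()
    rows = []
    for cid, (metric, doses) in DEFAULT_DOSE_GRIDS.items():
        ctx = contexts[cid]
        targets = ["ug_per_cm2", "ug_per_1e6_macrophages"]
        if ctx.in_vivo:
            targets.insert(0, "ug_per_lungs")
        for target in targets:
            converted = tuple(
                round_sig(
                    convert(DoseQuantity(d, metric, cid), target, ctx).value, sig_figs
                )
                for d in doses
            )
            rows.append({"context_id": cid, "metric": target, "doses": converted})
    return pd.DataFrame(rows)
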