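"""Nanomaterial physico-chemical records and surface-area dose conversions.

Poorly soluble metal-oxide nanomaterials (TiO2, CeO2) agglomerate in exposure
media (aqueous suspensions, aerosols).  For dose harmonisation the specific
surface area (SSA) of the material can be taken either from the dry-powder
BET measurement on primary particles, or estimated for the agglomerates
actually reaching the cells, treating them as ideal spheres of the measured
mean diameter and effective density:

    SSA [m^2/g] = 6000 / (rho [g/cm^3] * d [nm])

The effective density of an agglomerate includes trapped medium and voids and
is therefore bounded above by the primary material density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AgglomerateState",
    "MaterialRecord",
    "spherical_ssa",
    "mass_dose_to_surface_dose",
    "choose_ssa",
    "load_material_table",
    "ssa_consistency_report",
    "round_sig",
]

#: media in which agglomerate states are characterised
MEDIA = ("suspension", "aerosol")

#: SSA bases selectable for surface-area dose normalisation
SSA_BASES = ("primary-BET", "agglomerate")


def round_sig(x: float, n: int = 3) -> float:
    """Round ``x`` to ``n`` significant figures (0 passes through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, n - 1 - math.floor(math.log10(abs(x))))


def spherical_ssa(diameter_nm: float, density: float) -> float:
    """Specific surface area of a sphere, in m^2/g.

    Parameters
    ----------
    diameter_nm : float
        Sphere diameter in nanometres.
    density : float
        Mass density in g/cm^3 (effective density for agglomerates).
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter must be > 0 nm, got {diameter_nm!r}")
    if not density > 0:
        raise ValueError(f"density must be > 0 g/cm^3, got {density!r}")
    return 6000.0 / (density * diameter_nm)


def mass_dose_to_surface_dose(dose: float, ssa: float) -> float:
    """Convert a mass dose (ug per 10^6 macrophages) to a surface-area dose.

    1 ug * 1 m^2/g = 1e-6 g * 1e4 cm^2/g = 0.01 cm^2, hence the factor.
    Returns cm^2 per 10^6 macrophages.
    """
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose!r}")
    if not ssa > 0:
        raise ValueError(f"ssa must be > 0 m^2/g, got {ssa!r}")
    return dose * ssa * 0.01


@dataclass(frozen=True)
class AgglomerateState:
    """Mean agglomerate size and effective density in one exposure medium."""

    mean_diameter_nm: float
    effective_density: float

    def __post_init__(self) -> None:
        if not self.mean_diameter_nm > 0:
            raise ValueError("agglomerate mean diameter must be > 0 nm")
        if not self.effective_density > 0:
            raise ValueError("agglomerate effective density must be > 0")

    @property
    def derived_ssa(self) -> float:
        """Spherical-agglomerate SSA in m^2/g (computed, never stored)."""
        return spherical_ssa(self.mean_diameter_nm, self.effective_density)


@dataclass
class MaterialRecord:
    """One nanomaterial's primary and per-medium agglomerate properties."""

    material_id: str
    crystallinity: str
    coated: bool
    primary_diameter_nm: float
    primary_density: float
    bet_ssa: float
    media: dict[str, AgglomerateState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, value in (
            ("primary_diameter_nm", self.primary_diameter_nm),
            ("primary_density", self.primary_density),
            ("bet_ssa", self.bet_ssa),
        ):
            if not value > 0:
                raise ValueError(f"{self.material_id}: {name} must be > 0, got {value!r}")
        for medium, state in self.media.items():
            if medium not in MEDIA:
                raise ValueError(f"{self.material_id}: unknown medium {medium!r}")
            if state.effective_density > self.primary_density:
                raise ValueError(
                    f"{self.material_id}/{medium}: effective agglomerate density "
                    f"{state.effective_density} exceeds primary density "
                    f"{self.primary_density} (agglomerates contain medium/voids)"
                )


def choose_ssa(
    material: MaterialRecord,
    basis: str,
    medium: str | None = None,
) -> float:
    """Select the SSA (m^2/g) used to express doses in surface area.

    ``basis='primary-BET'`` returns the dry-powder BET value; the medium is
    ignored.  ``basis='agglomerate'`` returns the spherical-agglomerate SSA
    derived from the mean size and effective density measured in ``medium``.
    """
    if basis == "primary-BET":
        return material.bet_ssa
    if basis == "agglomerate":
        if medium is None:
            raise ValueError("agglomerate basis requires a medium")
        try:
            state = material.media[medium]
        except KeyError:
            raise KeyError(
                f"{material.material_id}: no agglomerate state for medium "
                f"{medium!r}; available: {sorted(material.media)}"
            ) from None
        return state.derived_ssa
    raise ValueError(f"unknown SSA basis {basis!r}; expected one of {SSA_BASES}")


def load_material_table(path: str | Path) -> dict[str, MaterialRecord]:
    """Read a material-property CSV into :class:`MaterialRecord` objects.

    Expected columns: material_id, crystallinity, coated,
    primary_diameter_nm, primary_density, bet_ssa, and per-medium pairs
    suspension_diameter_nm / suspension_density and
    aerosol_diameter_nm / aerosol_density (empty cells = medium missing).
    """
    frame = pd.read_csv(path)
    required = {
        "material_id", "crystallinity", "coated",
        "primary_diameter_nm", "primary_density", "bet_ssa",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"material table {path}: missing columns {sorted(missing)}")
    records: dict[str, MaterialRecord] = {}
    for _, row in frame.iterrows():
        media = {}
        for medium in MEDIA:
            d = row.get(f"{medium}_diameter_nm")
            rho = row.get(f"{medium}_density")
            if pd.notna(d) and pd.notna(rho):
                media[medium] = AgglomerateState(float(d), float(rho))
        rec = MaterialRecord(
            material_id=str(row["material_id"]),
            crystallinity=str(row["crystallinity"]),
            coated=bool(row["coated"]),
            primary_diameter_nm=float(row["primary_diameter_nm"]),
            primary_density=float(row["primary_density"]),
            bet_ssa=float(row["bet_ssa"]),
            media=media,
        )
        records[rec.material_id] = rec
    return records


def ssa_consistency_report(
    materials: Mapping[str, MaterialRecord],
    printed_ssa: Iterable[tuple[str, str, float]],
    rtol: float = 0.01,
) -> pd.DataFrame:
    """Check printed per-medium SSA values against the spherical formula.

    ``printed_ssa`` yields (material_id, medium, printed value in m^2/g)
    triples, typically from a published characterisation table.  A cell is
    ``consistent`` when the printed value agrees with
    ``spherical_ssa(mean size, effective density)`` within ``rtol`` after
    rounding the computed value to 3 significant figures.  Inconsistent cells
    are reported, never silently replaced by the printed number.
    """
    rows = []
    for material_id, medium, printed in printed_ssa:
        state = materials[material_id].media[medium]
        computed = round_sig(state.derived_ssa, 3)
        rows.append(
            {
                "material_id": material_id,
                "medium": medium,
                "printed_ssa": printed,
                "computed_ssa": computed,
                "rel_diff": abs(computed - printed) / printed,
                "consistent": abs(computed - printed) / printed <= rtol,
            }
        )
    return pd.DataFrame(rows)
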