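"""Packaged reference tables from the published rat / A549+THP-1 study.

These are the published desk inputs of the analysis: the material
characterisation table (primary and per-medium agglomerate properties with
the printed per-medium SSA values), the per-cytokine BMDL/BMDU intervals in
ug/cm^2 with the printed pooled medians, and the per-method LOAELs in
ug/cm^2.  They are used to validate the package's arithmetic (surface-area
formula, dose-grid regeneration, median pooling, fold-differences) against
the printed results.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .materials import MaterialRecord, load_material_table

_DATA = resources.files("nanobmd").joinpath("data")


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_DATA.joinpath(name)) as path:
        return pd.read_csv(path)


def reference_materials() -> dict[str, MaterialRecord]:
    """The four study nanomaterials (TiO2 NM105/NM101/NM100, CeO2 NM212)."""
    with resources.as_file(_DATA.joinpath("materials.csv")) as path:
        return load_material_table(path)


def printed_media_ssa() -> list[tuple[str, str, float]]:
    """Printed per-medium 'mean surface area in exposure media' values."""
    frame = _read("printed_media_ssa.csv")
    return list(frame.itertuples(index=False, name=None))


def published_dose_intervals() -> pd.DataFrame:
    """Per-cytokine BMDL/BMDU intervals (ug/cm^2); NaN marks ND cells."""
    return _read("published_dose_intervals.csv")


def published_pooled_medians() -> pd.DataFrame:
    """Printed pooled (median BMDL, median BMDU) intervals (ug/cm^2)."""
    return _read("published_pooled_medians.csv")


def published_loaels() -> dict[str, float]:
    """Per-method pro-inflammatory LOAELs in ug/cm^2."""
    frame = _read("published_loaels.csv")
    return dict(zip(frame["context_id"], frame["loael_ug_per_cm2"]))
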