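"""Per-cell scalar morphometry: ER density/area/compactness, mitochondrial
density and size, and contact-site counts and lengths.

Units: areas in µm², densities per µm², compactness in nm⁻¹, contact
lengths in nm.  The cytoplasmic area excludes the nucleus hole.  Metrics
that are undefined for a cell (mean length with zero contacts, compactness
with zero ER) propagate as NaN and are excluded pairwise from group
statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import pandas as pd

from .contacts import ContactParams, ContactSet, detect_contacts, mam_per_mito
from .errors import GeometryError
from .geometry import CellGeometry, validate_geometry

log = logging.getLogger(__name__)

NM2_PER_UM2 = 1e6


@dataclass
class MorphometryRecord:
    """One row of the per-cell metrics table (Figs 6-9 style quantities)."""

    cell_id: str
    group: str
    cytoplasm_area_um2: float
    n_er: int
    er_density_per_um2: float
    er_area_fraction: float
    er_compactness_per_nm: float       # pooled: total perimeter / total area
    er_compactness_mean_per_nm: float  # secondary: mean of per-cisterna ratios
    n_mito: int
    mito_density_per_um2: float
    mito_mean_area_um2: float
    mam_count: int
    mam_per_mito: float
    mam_mean_length_nm: float
    pam_count: int
    pam_mean_length_nm: float
    mito_pm_count: int
    mito_mito_contacts: int


def er_metrics(cell: CellGeometry) -> tuple[int, float, float, float, float]:
    """ER cisterna count, density (/µm²), area fraction, and pooled plus
    per-cisterna-mean perimeter-to-area compactness (nm⁻¹).

    Compactness is pooled per cell (Σ perimeter / Σ area) as the primary
    definition, robust to many tiny cisternae; the per-cisterna mean is the
    secondary column.  Cells without ER yield zero counts and NaN
    compactness (logged)."""
    s = cell.pixel_size_nm
    cyto_um2 = cell.cytoplasm.area * s**2 / NM2_PER_UM2
    if cyto_um2 <= 0:
        raise GeometryError(f"{cell.cell_id}: non-positive cytoplasm area")
    n_er = len(cell.er)
    if n_er == 0:
        log.info("%s: no ER cisternae; compactness undefined", cell.cell_id)
        return 0, 0.0, 0.0, math.nan, math.nan
    areas_nm2 = [p.area * s**2 for p in cell.er]
    perims_nm = [p.exterior.length * s for p in cell.er]
    density = n_er / cyto_um2
    area_fraction = sum(areas_nm2) / (cell.cytoplasm.area * s**2)
    pooled = sum(perims_nm) / sum(areas_nm2)
    per_cisterna = sum(p / a for p, a in zip(perims_nm, areas_nm2)) / n_er
    return n_er, density, area_fraction, pooled, per_cisterna


def mito_metrics(cell: CellGeometry, contact_set: ContactSet) -> tuple[int, float, float, int]:
    """Mitochondrion count, density (/µm²), mean profile area (µm²), and
    the number of mitochondrion-mitochondrion contacts (counted per
    touching pair, so one mitochondrion with two neighbours contributes
    two contacts)."""
    s = cell.pixel_size_nm
    cyto_um2 = cell.cytoplasm.area * s**2 / NM2_PER_UM2
    n_mito = len(cell.mito)
    density = n_mito / cyto_um2
    if n_mito == 0:
        log.info("%s: no mitochondria; mean area undefined", cell.cell_id)
        mean_area = math.nan
    else:
        mean_area = sum(p.area * s**2 for p in cell.mito) / n_mito / NM2_PER_UM2
    return n_mito, density, mean_area, contact_set.count("MITO_MITO")


def _mean_length(contact_set: ContactSet, kind: str) -> float:
    segs = contact_set.of_kind(kind)
    if not segs:
        return math.nan
    return sum(s.length_nm for s in segs) / len(segs)


def cell_record(cell: CellGeometry, params: ContactParams | None = None) -> MorphometryRecord:
    """Full deterministic per-cell record: validates, detects contacts, and
    aggregates all metrics.  Raises on invalid geometry; no partial record."""
    violations = validate_geometry(cell)
    if violations:
        raise GeometryError(
            f"{cell.cell_id}: invalid geometry: " + "; ".join(map(str, violations))
        )
    contact_set = detect_contacts(cell, params)
    n_er, er_density, er_frac, er_comp, er_comp_mean = er_metrics(cell)
    n_mito, mito_density, mito_mean_area, n_mm = mito_metrics(cell, contact_set)
    if n_mito > 0:
        mpm, _ = mam_per_mito(contact_set, cell)
    else:
        mpm = math.nan
    s = cell.pixel_size_nm
    return MorphometryRecord(
        cell_id=cell.cell_id,
        group=cell.group,
        cytoplasm_area_um2=cell.cytoplasm.area * s**2 / NM2_PER_UM2,
        n_er=n_er,
        er_density_per_um2=er_density,
        er_area_fraction=er_frac,
        er_compactness_per_nm=er_comp,
        er_compactness_mean_per_nm=er_comp_mean,
        n_mito=n_mito,
        mito_density_per_um2=mito_density,
        mito_mean_area_um2=mito_mean_area,
        mam_count=contact_set.count("MAM"),
        mam_per_mito=mpm,
        mam_mean_length_nm=_mean_length(contact_set, "MAM"),
        pam_count=contact_set.count("PAM"),
        pam_mean_length_nm=_mean_length(contact_set, "PAM"),
        mito_pm_count=contact_set.count("MITO_PM"),
        mito_mito_contacts=n_mm,
    )


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    """Tidy per-cell table, one row per cell."""
    cols = [f.name for f in fields(MorphometryRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)
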