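"""Membrane apposition detection and contact-site classification.

A contact site is a maximal stretch of one organelle boundary (the
*reference* membrane) whose points lie strictly closer than ``d_max_nm``
(default 20 nm) to another membrane.  The reference boundary is resampled
at ``sample_step_nm`` arc spacing, apposed samples are grouped into runs,
runs on the same organelle pair separated by an arc gap below
``merge_gap_nm`` are merged, and runs shorter than ``min_len_nm`` are
dropped.  Contacts are classified by the membrane pair:

* ``MAM``       ER vs mitochondrion (reference: ER)
* ``PAM``       ER vs plasma membrane (reference: ER)
* ``MITO_PM``   mitochondrion vs plasma membrane (reference: mito)
* ``MITO_MITO`` mitochondrion pair (reference: lower-index member),
  recorded once per unordered pair.

All distances and lengths are in nm after calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LinearRing, LineString, Polygon

from .errors import GeometryError, UndefinedMetricError
from .geometry import CellGeometry, validate_geometry

KINDS = ("MAM", "PAM", "MITO_PM", "MITO_MITO")


@dataclass(frozen=True)
class ContactParams:
    """Detection parameters.

    d_max_nm : apposition threshold (strict ``<``), nm.
    sample_step_nm : reference-boundary resampling step, nm.
    merge_gap_nm : arc gap below which runs on one pair merge, nm.
    min_len_nm : shortest reportable apposition, nm.
    """

    d_max_nm: float = 20.0
    sample_step_nm: float = 2.0
    merge_gap_nm: float = 30.0
    min_len_nm: float = 5.0

    def __post_init__(self) -> None:
        for name in ("d_max_nm", "sample_step_nm", "merge_gap_nm", "min_len_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_len_nm < self.sample_step_nm:
            raise ValueError("min_len_nm must be >= sample_step_nm")


@dataclass
class ContactSegment:
    """One detected membrane apposition.

    ``arc_start_nm``/``arc_end_nm`` are positions along the reference
    boundary (``arc_end`` may exceed the ring perimeter when the run wraps
    around the ring origin)."""

    kind: str | None
    ref_id: str
    other_id: str
    arc_start_nm: float
    arc_end_nm: float
    length_nm: float
    min_distance_nm: float
    mean_distance_nm: float


@dataclass
class ContactSet:
    """All contacts detected in one cell, with per-mitochondrion MAM counts
    and per-pair multiplicities."""

    cell_id: str
    segments: list[ContactSegment] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[ContactSegment]:
        return [s for s in self.segments if s.kind == kind]

    def count(self, kind: str) -> int:
        return len(self.of_kind(kind))

    def mam_counts_per_mito(self, n_mito: int) -> np.ndarray:
        counts = np.zeros(n_mito, dtype=int)
        for seg in self.of_kind("MAM"):
            counts[int(seg.other_id.split("_")[1])] += 1
        return counts

    def pair_multiplicity(self) -> dict[tuple[str, str], int]:
        mult: dict[tuple[str, str], int] = {}
        for seg in self.segments:
            key = (seg.ref_id, seg.other_id)
            mult[key] = mult.get(key, 0) + 1
        return mult


def _as_coords(curve) -> tuple[np.ndarray, bool]:
    """Vertex array of a curve plus whether it is closed."""
    if isinstance(curve, Polygon):
        return np.asarray(curve.exterior.coords), True
    if isinstance(curve, LinearRing):
        return np.asarray(curve.coords), True
    if isinstance(curve, LineString):
        coords = np.asarray(curve.coords)
        closed = bool(np.allclose(coords[0], coords[-1]))
        return coords, closed
    coords = np.asarray(curve, dtype=float)
    closed = bool(np.allclose(coords[0], coords[-1]))
    return coords, closed


def resample_curve(curve, step: float) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Resample a polyline/ring at uniform arc spacing ``<= step``.

    Returns ``(points, arc_positions, total_length, closed)``.  For closed
    curves the duplicate endpoint is dropped, so samples tile the ring.
    """
    coords, closed = _as_coords(curve)
    seg = np.diff(coords, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = float(cum[-1])
    if total == 0:
        raise GeometryError("degenerate zero-length curve")
    n = max(int(np.ceil(total / step)), 2)
    if closed:
        arcs = np.arange(n) * (total / n)
    else:
        arcs = np.linspace(0.0, total, n + 1)
    xs = np.interp(arcs, cum, coords[:, 0])
    ys = np.interp(arcs, cum, coords[:, 1])
    return np.column_stack([xs, ys]), arcs, total, closed


def _runs_from_mask(mask: np.ndarray, closed: bool) -> list[np.ndarray]:
    """Index arrays of maximal True runs, with ring wrap-around."""
    n = mask.size
    if not mask.any():
        return []
    if mask.all():
        return [np.arange(n)]
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    if closed and len(runs) > 1 and mask[0] and mask[-1]:
        runs[0] = np.concatenate([runs[-1], runs[0] + 0])  # wrap join
        runs = runs[:-1]
    return runs


def apposition_segments(ref_curve, other_curve, params: ContactParams) -> list[ContactSegment]:
    """Detect apposed stretches of ``ref_curve`` against ``other_curve``.

    Both curves are in nm coordinates.  A resampled reference point is
    apposed iff its minimum Euclidean distance to ``other_curve`` is
    strictly below ``params.d_max_nm``.  Curves must not intersect: a
    crossing means an invalid segmentation, not a zero-distance contact.
    """
    ref_coords, _ = _as_coords(ref_curve)
    other_coords, other_closed = _as_coords(other_curve)
    ref_line = LineString(ref_coords)
    other_line = (
        LinearRing(other_coords) if other_closed and len(other_coords) >= 4
        else LineString(other_coords)
    )
    if ref_line.intersects(other_line):
        raise GeometryError("reference and partner curves intersect")

    pts, arcs, total, closed = resample_curve(ref_curve, params.sample_step_nm)
    dists = shapely.distance(shapely.points(pts), other_line)
    apposed = dists < params.d_max_nm
    runs = _runs_from_mask(apposed, closed)
    if not runs:
        return []

    spacing = total / pts.shape[0] if closed else arcs[1] - arcs[0]

    def run_bounds(run: np.ndarray) -> tuple[float, float]:
        start = arcs[run[0]]
        # wrapped runs are stored with original indices; unwrap arc end
        end = start + (run.size - 1) * spacing
        return start, end

    # merge runs separated by a small arc gap (same pair by construction)
    runs = sorted(runs, key=lambda r: arcs[r[0]])
    merged: list[list[np.ndarray]] = [[runs[0]]]
    for run in runs[1:]:
        prev = merged[-1][-1]
        _, prev_end = run_bounds(prev)
        gap = arcs[run[0]] - prev_end
        if gap < params.merge_gap_nm:
            merged[-1].append(run)
        else:
            merged.append([run])
    if closed and len(merged) > 1:
        # gap across the ring origin between last run end and first run start
        _, last_end = run_bounds(merged[-1][-1])
        first_start = arcs[merged[0][0][0]]
        if (first_start + total) - last_end < params.merge_gap_nm:
            merged[0] = merged.pop() + merged[0]

    segments: list[ContactSegment] = []
    for group in merged:
        idx = np.concatenate(group)
        start, _ = run_bounds(group[0])
        _, end = run_bounds(group[-1])
        if end < start:  # merged across the ring origin
            end += total
        length = end - start
        if length < params.min_len_nm:
            continue
        d = dists[idx]
        segments.append(
            ContactSegment(
                kind=None,
                ref_id="",
                other_id="",
                arc_start_nm=float(start),
                arc_end_nm=float(end),
                length_nm=float(length),
                min_distance_nm=float(d.min()),
                mean_distance_nm=float(d.mean()),
            )
        )
    return segments


def detect_contacts(cell: CellGeometry, params: ContactParams | None = None) -> ContactSet:
    """Detect and classify every contact site of one cell.

    Requires a cell that passes :func:`~mamsleep.geometry.validate_geometry`.
    Organelle pairs whose polygon distance is at least ``d_max_nm`` are
    pruned without resampling (the sampled minimum can only be larger).
    """
    params = params or ContactParams()
    violations = validate_geometry(cell)
    if violations:
        raise GeometryError(
            f"{cell.cell_id}: invalid geometry: " + "; ".join(map(str, violations))
        )

    er_nm = [cell.scaled_to_nm(p) for p in cell.er]
    mito_nm = [cell.scaled_to_nm(p) for p in cell.mito]
    pm_nm = cell.scaled_to_nm(cell.plasma_membrane)

    out = ContactSet(cell_id=cell.cell_id)

    def add(ref, other, kind: str, ref_id: str, other_id: str) -> None:
        ref_b = ref.exterior if isinstance(ref, Polygon) else ref
        other_b = other.exterior if isinstance(other, Polygon) else other
        if shapely.distance(ref_b, other_b) >= params.d_max_nm:
            return
        for seg in apposition_segments(ref_b, other_b, params):
            seg.kind, seg.ref_id, seg.other_id = kind, ref_id, other_id
            out.segments.append(seg)

    for i, er in enumerate(er_nm):
        for j, mito in enumerate(mito_nm):
            add(er, mito, "MAM", f"er_{i}", f"mito_{j}")
        add(er, pm_nm, "PAM", f"er_{i}", "pm")
    for j, mito in enumerate(mito_nm):
        add(mito, pm_nm, "MITO_PM", f"mito_{j}", "pm")
        for k in range(j + 1, len(mito_nm)):
            add(mito, mito_nm[k], "MITO_MITO", f"mito_{j}", f"mito_{k}")
    return out


def contacts_to_frame(contact_sets: list[ContactSet]):
    """Tidy export of contact segments, one row per segment:
    cell_id, kind, ref_id, other_id, length_nm, min/mean distance."""
    import pandas as pd

    rows = [
        {
            "cell_id": cs.cell_id, "kind": s.kind,
            "ref_id": s.ref_id, "other_id": s.other_id,
            "length_nm": s.length_nm,
            "min_distance_nm": s.min_distance_nm,
            "mean_distance_nm": s.mean_distance_nm,
        }
        for cs in contact_sets
        for s in cs.segments
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "kind", "ref_id", "other_id", "length_nm",
                       "min_distance_nm", "mean_distance_nm"],
    )


def mam_per_mito(contact_set: ContactSet, cell: CellGeometry) -> tuple[float, np.ndarray]:
    """MAM segments per mitochondrion plus the per-mitochondrion histogram.

    Raises :class:`UndefinedMetricError` for cells without mitochondria
    (the record is excluded upstream, not imputed)."""
    n_mito = len(cell.mito)
    if n_mito == 0:
        raise UndefinedMetricError(f"{cell.cell_id}: no mitochondria; MAM/mito undefined")
    hist = contact_set.mam_counts_per_mito(n_mito)
    return float(hist.sum()) / n_mito, hist
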