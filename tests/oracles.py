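"""Independent brute-force references used by the test suite.

These deliberately re-derive results with the simplest possible method
(dense 1-nm boundary sampling, explicit Python run-grouping) so they stay
independent of the implementation they check.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry import LinearRing, LineString, Polygon


def dense_boundary(curve, step: float = 1.0) -> tuple[np.ndarray, float, bool]:
    """Points at uniform ~``step`` arc spacing along a curve, naively."""
    if isinstance(curve, Polygon):
        coords = np.asarray(curve.exterior.coords)
        closed = True
    else:
        coords = np.asarray(LineString(curve).coords if not hasattr(curve, "coords") else curve.coords)
        closed = bool(np.allclose(coords[0], coords[-1]))
    seg = np.diff(coords, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = float(cum[-1])
    n = max(int(np.ceil(total / step)), 4)
    arcs = np.arange(n) * total / n if closed else np.linspace(0.0, total, n + 1)
    xs = np.interp(arcs, cum, coords[:, 0])
    ys = np.interp(arcs, cum, coords[:, 1])
    return np.column_stack([xs, ys]), total, closed


def brute_force_appositions(
    ref_curve,
    other_curve,
    d_max: float = 20.0,
    merge_gap: float = 30.0,
    min_len: float = 5.0,
    step: float = 1.0,
) -> list[dict]:
    """1-nm boundary-sampling reference for apposition runs.

    Returns one dict per surviving run with ``length`` and ``min_dist``.
    Run forming is written as a plain Python scan so it shares no code
    with the package implementation.
    """
    pts, total, closed = dense_boundary(ref_curve, step)
    if isinstance(other_curve, Polygon):
        other = LinearRing(other_curve.exterior.coords)
    else:
        other = other_curve if hasattr(other_curve, "coords") else LineString(other_curve)
    d = shapely.distance(shapely.points(pts), other)
    n = pts.shape[0]
    spacing = total / n if closed else total / (n - 1)
    apposed = d < d_max

    # collect maximal runs by linear scan (rotated so index 0 is not apposed)
    if closed and apposed.all():
        runs = [(0, n)]
    else:
        if closed:
            off = int(np.argmin(apposed))
            rolled = np.roll(apposed, -off)
        else:
            off, rolled = 0, apposed
        runs = []
        start = None
        for i, flag in enumerate(rolled):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(rolled)))
        runs = [((s + off) % n if closed else s, e - s) for s, e in runs]

    # merge runs separated by small arc gaps, then drop short ones
    merged: list[list[tuple[int, int]]] = []
    for run in runs:
        if merged:
            prev_s, prev_c = merged[-1][-1]
            gap = (run[0] * spacing) - (prev_s * spacing + (prev_c - 1) * spacing)
            if closed:
                gap = gap % total
            if 0 <= gap < merge_gap:
                merged[-1].append(run)
                continue
        merged.append([run])
    if closed and len(merged) > 1:
        first_s, _ = merged[0][0]
        last_s, last_c = merged[-1][-1]
        gap = (first_s * spacing + total - (last_s * spacing + (last_c - 1) * spacing)) % total
        if gap < merge_gap:
            merged[0] = merged.pop() + merged[0]

    out = []
    for group in merged:
        s0, _ = group[0]
        s1, c1 = group[-1]
        end = s1 * spacing + (c1 - 1) * spacing
        startpos = s0 * spacing
        if closed and end < startpos:
            end += total
        length = end - startpos
        if length < min_len:
            continue
        idx = np.concatenate([
            (np.arange(s, s + c) % n if closed else np.arange(s, s + c))
            for s, c in group
        ])
        out.append({"length": float(length), "min_dist": float(d[idx].min())})
    return out


def brute_force_cell_contacts(cell, d_max=20.0, merge_gap=30.0, min_len=5.0, step=1.0):
    """Per-kind brute-force contact runs for a whole cell (nm space)."""
    er = [cell.scaled_to_nm(p) for p in cell.er]
    mito = [cell.scaled_to_nm(p) for p in cell.mito]
    pm = cell.scaled_to_nm(cell.plasma_membrane)
    kinds: dict[str, list[dict]] = {"MAM": [], "PAM": [], "MITO_PM": [], "MITO_MITO": []}

    def scan(ref, other, kind):
        ref_b = ref.exterior if isinstance(ref, Polygon) else ref
        other_b = other.exterior if isinstance(other, Polygon) else other
        if shapely.distance(ref_b, other_b) >= d_max:
            return
        kinds[kind].extend(
            brute_force_appositions(ref, other_b, d_max, merge_gap, min_len, step)
        )

    for e in er:
        for m in mito:
            scan(e, m, "MAM")
        scan(e, pm, "PAM")
    for j, m in enumerate(mito):
        scan(m, pm, "MITO_PM")
        for k in range(j + 1, len(mito)):
            scan(m, mito[k], "MITO_MITO")
    return kinds
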