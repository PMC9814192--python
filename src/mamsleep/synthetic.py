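"""Seeded ground-truthed generators for every pipeline stage.

* :func:`synth_cells` — neuronal-soma segmentations (annular cytoplasm,
  ER tubes, mitochondrion ellipses) with geometrically planted contacts:
  MAMs are built by wrapping an ER tube around a mitochondrion at a sampled
  membrane separation inside the detection band, mitochondrion pairs are
  translated to a sampled sub-threshold gap, and every non-contact membrane
  is kept beyond a clearance margin so no accidental contact corrupts the
  recorded truth.
* :func:`synth_dam` — two-state (sleep/wake) semi-Markov activity traces
  with light/dark-dependent dwell parameters, an optional enforced-wake
  night and a next-day rebound effect.
* :func:`synth_expr` — log-normal expression noise around planted fold
  changes on chosen gene subsets.
* :func:`synth_blot` — densitometry lanes with known loading factors and a
  planted group effect.

Randomness is split with ``numpy.random.SeedSequence`` keyed by
``(seed, unit index, purpose)``, so sub-generators are order-independent
and — crucially for contrast recovery — the *same* per-unit base draws are
reused across groups, with group effects entering only through rate
multipliers via comonotone inverse-CDF sampling.  Group contrasts are
therefore estimated with common random numbers (paired simulation), which
shrinks their Monte-Carlo error far below the planted effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy import stats as sps
from shapely.geometry import LineString, Point, Polygon

from .dam_sleep import DAY_MIN, HALF_DAY_MIN, ActivityTrace, sleep_architecture
from .de_intersect import ExpressionStudy
from .errors import GenerationError
from .geometry import CellGeometry, validate_geometry
from .stats import BlotLane

# ---------------------------------------------------------------------------
# EM cells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGenParams:
    """Conditions for one group of synthetic soma segmentations.

    Base rates describe the sleep (S) condition; a sleep-deprived-like
    group is generated with the same seed and the group effect multipliers
    (``effect_mam``, ``effect_er``, ``effect_mito_pair``) set to the
    planted contrasts.
    """

    n_cells: int = 139
    group: str = "S"
    pixel_size_nm: float = 2.0
    cytoplasm_radius_um: tuple[float, float] = (3.8, 4.6)
    nucleus_radius_um: tuple[float, float] = (1.8, 2.2)
    n_er_mean: float = 25.0                 # expected ER cisternae per cell
    er_width_nm: tuple[float, float] = (40.0, 65.0)
    er_length_nm: tuple[float, float] = (300.0, 1000.0)
    n_mito_range: tuple[int, int] = (14, 18)
    mito_major_nm: tuple[float, float] = (250.0, 420.0)   # semi-axis
    mito_minor_nm: tuple[float, float] = (140.0, 220.0)   # semi-axis
    mam_rate_per_mito: float = 0.4          # λ, expected MAMs per mitochondrion
    contact_len_nm: tuple[float, float] = (80.0, 250.0)
    contact_dist_nm: tuple[float, float] = (6.0, 16.0)
    pam_rate: float = 1.0                   # expected PAMs per cell
    mito_pm_prob: float = 0.01
    mito_pair_prob: float = 0.45            # per disjoint mitochondrion slot
    effect_mam: float = 1.0
    effect_er: float = 1.0
    effect_mito_pair: float = 1.0
    outlier_fraction: float = 0.0
    outlier_multiplier: float = 3.0
    clearance_nm: float = 45.0              # margin for non-contact membranes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mam_rate_per_mito < 0 or self.pam_rate < 0:
            raise ValueError("rates must be non-negative")
        lo, hi = self.contact_dist_nm
        if not (0 < lo < hi < 20):
            raise ValueError("contact distance support must lie inside (0, 20) nm")
        for name in ("effect_mam", "effect_er", "effect_mito_pair"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")


@dataclass
class CellTruth:
    """Planted per-cell truth serialized beside the generated geometry."""

    table: pd.DataFrame

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


def _uniform(rng: np.random.Generator, lohi: tuple[float, float]) -> float:
    return float(rng.uniform(*lohi))


def _ellipse(a: float, b: float, angle_deg: float, cx: float, cy: float) -> Polygon:
    e = Point(0.0, 0.0).buffer(1.0, quad_segs=32)
    e = shapely.affinity.scale(e, a, b)
    e = shapely.affinity.rotate(e, angle_deg)
    return shapely.affinity.translate(e, cx, cy)


def _capsule(p0, p1, width: float) -> Polygon:
    return LineString([p0, p1]).buffer(width / 2.0, quad_segs=16)


def _boundary_samples(poly: Polygon, step: float = 4.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boundary points, outward normals and cumulative arc positions."""
    coords = np.asarray(poly.exterior.coords)[:-1]
    seg = np.diff(np.vstack([coords, coords[:1]]), axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n = max(int(total / step), 32)
    arcs = np.arange(n) * total / n
    xs = np.interp(arcs, cum, np.append(coords[:, 0], coords[0, 0]))
    ys = np.interp(arcs, cum, np.append(coords[:, 1], coords[0, 1]))
    pts = np.column_stack([xs, ys])
    tang = np.gradient(pts, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    # exterior is CCW (positive shoelace), so outward normal = (ty, -tx)
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    centroid = np.asarray(poly.centroid.coords)[0]
    flip = np.einsum("ij,ij->i", pts - centroid, normals) < 0
    normals[flip] *= -1
    return pts, normals, arcs


def _arc_tube(poly: Polygon, arc_center: float, arc_len: float, dist: float,
              width: float) -> Polygon:
    """ER tube hugging the boundary of ``poly`` over an arc of length
    ``arc_len`` centred at arc position ``arc_center``, at membrane
    separation ``dist``; the tube extends ``width`` outward."""
    pts, normals, arcs = _boundary_samples(poly)
    total = arcs[-1] + (arcs[1] - arcs[0])
    rel = (arcs - arc_center) % total
    rel = np.where(rel > total / 2, rel - total, rel)
    sel = np.abs(rel) <= arc_len / 2
    order = np.argsort(rel[sel])
    p = pts[sel][order]
    n = normals[sel][order]
    inner = p + n * dist
    outer = p + n * (dist + width)
    return Polygon(np.vstack([inner, outer[::-1]]))


def _min_distance(geom, others: list) -> float:
    if not others:
        return math.inf
    return float(min(shapely.distance(geom, o) for o in others))


def _place(rng, make_candidate, accept, max_tries: int = 200):
    for _ in range(max_tries):
        cand = make_candidate(rng)
        if cand is not None and accept(cand):
            return cand
    raise GenerationError(
        "could not place an organelle within the packing constraints; "
        "reduce organelle counts or enlarge the cytoplasm"
    )


def _coupled_poisson(u: float, mu: float) -> int:
    """Comonotone Poisson draw (inverse CDF of a shared uniform)."""
    return int(sps.poisson.ppf(u, mu)) if mu > 0 else 0


def synth_cells(params: CellGenParams) -> tuple[list[CellGeometry], CellTruth]:
    """Generate one group of ground-truthed soma segmentations.

    Every returned cell passes geometric validation; the truth table
    records, per cell, the planted MAM/PAM/mito-PM/mito-pair counts and
    the planted apposition lengths and distances.
    """
    cells: list[CellGeometry] = []
    rows = []
    n_outliers = int(round(params.outlier_fraction * params.n_cells))
    for idx in range(params.n_cells):
        cell, row = _synth_one_cell(params, idx, outlier=idx < n_outliers)
        cells.append(cell)
        rows.append(row)
    return cells, CellTruth(pd.DataFrame(rows))


def _synth_one_cell(params: CellGenParams, idx: int, outlier: bool):
    shape_rng = _rng(params.seed, idx, 0)
    count_rng = _rng(params.seed, idx, 1)
    place_rng = _rng(params.seed, idx, 2)

    r_cyto = _uniform(shape_rng, params.cytoplasm_radius_um) * 1000.0
    r_nuc = _uniform(shape_rng, params.nucleus_radius_um) * 1000.0
    n_mito = int(shape_rng.integers(params.n_mito_range[0], params.n_mito_range[1] + 1))

    clearance = params.clearance_nm
    centre = (r_cyto + 100.0, r_cyto + 100.0)
    outer = Point(centre).buffer(r_cyto, quad_segs=64)
    nucleus = Point(centre).buffer(r_nuc, quad_segs=48)
    cytoplasm = Polygon(outer.exterior.coords, [nucleus.exterior.coords[::-1]])
    pm_ring = LineString(outer.exterior.coords)
    nuc_ring = LineString(nucleus.exterior.coords)

    # --- planted counts (comonotone across groups via shared uniforms) ----
    lam = params.mam_rate_per_mito * params.effect_mam
    if outlier:
        lam *= params.outlier_multiplier
    u_mam = count_rng.random(n_mito)
    mam_counts = np.array([_coupled_poisson(u, lam) for u in u_mam])
    u_er = count_rng.random()
    n_er_total = _coupled_poisson(u_er, params.n_er_mean * params.effect_er)
    u_pam = count_rng.random()
    n_pam = _coupled_poisson(u_pam, params.pam_rate)
    n_slots = n_mito // 2
    u_pairs = count_rng.random(n_slots)
    paired_slots = u_pairs < params.mito_pair_prob * params.effect_mito_pair
    n_pairs = int(paired_slots.sum())
    has_mito_pm = count_rng.random() < params.mito_pm_prob

    placed: list = []          # all organelle polygons, for clearance checks
    mitos: list[Polygon] = []
    ers: list[Polygon] = []

    def in_band(geom) -> bool:
        return (
            cytoplasm.covers(geom)
            and shapely.distance(geom, pm_ring) > clearance
            and shapely.distance(geom, nuc_ring) > clearance
        )

    def random_point(rng) -> tuple[float, float]:
        rr = math.sqrt(rng.uniform((r_nuc + 200.0) ** 2, (r_cyto - 200.0) ** 2))
        th = rng.uniform(0, 2 * math.pi)
        return centre[0] + rr * math.cos(th), centre[1] + rr * math.sin(th)

    def random_mito(rng) -> Polygon:
        a = _uniform(rng, params.mito_major_nm)
        b = _uniform(rng, params.mito_minor_nm)
        cx, cy = random_point(rng)
        return _ellipse(a, b, rng.uniform(0, 180), cx, cy)

    # --- mitochondria: touching pairs first, then singletons --------------
    pair_dists = []
    for _ in range(n_pairs):
        gap = _uniform(place_rng, params.contact_dist_nm)

        def make(rng):
            first = random_mito(rng)
            if not (in_band(first) and _min_distance(first, placed) > clearance):
                return None
            second = random_mito(rng)
            th = rng.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(th), math.sin(th)])
            c1 = np.asarray(first.centroid.coords)[0]
            # bisect the centre separation until the membrane gap hits `gap`
            lo, hi = 0.0, 2000.0
            for _ in range(40):
                mid = (lo + hi) / 2
                cand = shapely.affinity.translate(
                    second,
                    c1[0] + direction[0] * mid - second.centroid.x,
                    c1[1] + direction[1] * mid - second.centroid.y,
                )
                d = shapely.distance(first.exterior, cand.exterior)
                if cand.intersects(first) or d < gap:
                    lo = mid
                else:
                    hi = mid
            cand = shapely.affinity.translate(
                second,
                c1[0] + direction[0] * hi - second.centroid.x,
                c1[1] + direction[1] * hi - second.centroid.y,
            )
            d = shapely.distance(first.exterior, cand.exterior)
            if not (gap - 1.0 <= d <= gap + 1.0):
                return None
            if not (in_band(cand) and _min_distance(cand, placed) > clearance):
                return None
            return first, cand

        first, second = _place(place_rng, make, lambda c: True)
        mitos += [first, second]
        placed += [first, second]
        pair_dists.append(gap)

    for _ in range(n_mito - 2 * n_pairs - (1 if has_mito_pm else 0)):
        m = _place(
            place_rng,
            random_mito,
            lambda c: in_band(c) and _min_distance(c, placed) > clearance,
        )
        mitos.append(m)
        placed.append(m)

    if has_mito_pm:
        gap = _uniform(place_rng, params.contact_dist_nm)

        def make_pm_mito(rng):
            a = _uniform(rng, params.mito_major_nm)
            b = _uniform(rng, params.mito_minor_nm)
            th = rng.uniform(0, 2 * math.pi)
            lo, hi = r_nuc + 300.0, r_cyto
            for _ in range(40):
                mid = (lo + hi) / 2
                cand = _ellipse(a, b, math.degrees(th) + 90,
                                centre[0] + mid * math.cos(th),
                                centre[1] + mid * math.sin(th))
                if not outer.covers(cand) or shapely.distance(cand.exterior, pm_ring) < gap:
                    hi = mid
                else:
                    lo = mid
            cand = _ellipse(a, b, math.degrees(th) + 90,
                            centre[0] + lo * math.cos(th),
                            centre[1] + lo * math.sin(th))
            d = shapely.distance(cand.exterior, pm_ring)
            if not (gap - 1.0 <= d <= gap + 1.0) or not outer.covers(cand):
                return None
            if _min_distance(cand, placed) <= clearance or shapely.distance(cand, nuc_ring) <= clearance:
                return None
            return cand

        m = _place(place_rng, make_pm_mito, lambda c: True)
        mitos.append(m)
        placed.append(m)

    # --- planted MAM tubes -------------------------------------------------
    # Tubes are planted per mitochondrion; if a host's boundary cannot take
    # another tube (crowded or blocked by its touching partner) the tube is
    # reassigned to the next mitochondrion, preserving the planted total.
    width_rng = params.er_width_nm
    mam_lengths, mam_dists = [], []
    realized_mam = np.zeros(len(mitos), dtype=int)
    used_arcs: dict[int, list[tuple[float, float]]] = {i: [] for i in range(len(mitos))}
    perimeters = [m.exterior.length for m in mitos]

    def try_plant_on(m_idx: int, L: float, d: float, w: float) -> bool:
        mito = mitos[m_idx]
        total = perimeters[m_idx]
        for _ in range(80):
            centre_arc = place_rng.uniform(0, total)
            blocked = False
            for c_used, l_used in used_arcs[m_idx]:
                gap = abs((centre_arc - c_used + total / 2) % total - total / 2)
                if gap < (L + l_used) / 2 + 1.5 * clearance:
                    blocked = True
                    break
            if blocked:
                continue
            tube = _arc_tube(mito, centre_arc, L, d, w)
            if not tube.is_valid or not in_band(tube):
                continue
            others = [g for g in placed if g is not mito]
            if _min_distance(tube, others) <= clearance:
                continue
            ers.append(tube)
            placed.append(tube)
            used_arcs[m_idx].append((centre_arc, L))
            realized_mam[m_idx] += 1
            mam_lengths.append(L)
            mam_dists.append(d)
            return True
        return False

    for m_idx, k in enumerate(mam_counts[: len(mitos)]):
        for _ in range(int(k)):
            L = _uniform(place_rng, params.contact_len_nm)
            d = _uniform(place_rng, params.contact_dist_nm)
            w = _uniform(place_rng, width_rng)
            planted = False
            for j in range(len(mitos)):
                if try_plant_on((m_idx + j) % len(mitos), L, d, w):
                    planted = True
                    break
            if not planted:
                raise GenerationError(
                    "could not plant a MAM tube on any mitochondrion; "
                    "reduce the contact rate or enlarge the cytoplasm"
                )

    # --- planted PAM tubes (hugging the plasma membrane from inside) ------
    pam_lengths = []
    pm_poly = Polygon(outer.exterior.coords)
    for _ in range(n_pam):
        L = _uniform(place_rng, params.contact_len_nm)
        d = _uniform(place_rng, params.contact_dist_nm)
        w = _uniform(place_rng, width_rng)

        def make_pam(rng):
            centre_arc = rng.uniform(0, 2 * math.pi * r_cyto)
            tube = _arc_tube(pm_poly, centre_arc, L, -d - w, w)  # inward offset
            if not tube.is_valid or not cytoplasm.covers(tube):
                return None
            if shapely.distance(tube, nuc_ring) <= clearance:
                return None
            if _min_distance(tube, placed) <= clearance:
                return None
            return tube

        tube = _place(place_rng, make_pam, lambda c: True, max_tries=400)
        ers.append(tube)
        placed.append(tube)
        pam_lengths.append(L)

    # --- free ER tubes -----------------------------------------------------
    n_free = max(0, n_er_total - len(ers))
    for _ in range(n_free):
        def make_er(rng):
            L = _uniform(rng, params.er_length_nm)
            w = _uniform(rng, width_rng)
            cx, cy = random_point(rng)
            th = rng.uniform(0, 2 * math.pi)
            dx, dy = math.cos(th) * L / 2, math.sin(th) * L / 2
            return _capsule((cx - dx, cy - dy), (cx + dx, cy + dy), w)

        tube = _place(
            place_rng,
            make_er,
            lambda c: in_band(c) and _min_distance(c, placed) > clearance,
        )
        ers.append(tube)
        placed.append(tube)

    s = params.pixel_size_nm
    scale = lambda g: shapely.affinity.scale(g, 1 / s, 1 / s, origin=(0, 0))
    cell = CellGeometry(
        cell_id=f"{params.group}_{idx:04d}",
        group=params.group,
        pixel_size_nm=s,
        cytoplasm=scale(cytoplasm),
        er=[scale(g) for g in ers],
        mito=[scale(g) for g in mitos],
    )
    violations = validate_geometry(cell)
    if violations:
        raise GenerationError(
            f"{cell.cell_id}: generated geometry failed validation: "
            + "; ".join(map(str, violations))
        )
    row = {
        "cell_id": cell.cell_id, "group": params.group, "outlier": outlier,
        "n_mito": len(mitos), "n_er": len(ers),
        "mam_total": int(realized_mam.sum()),
        "mam_per_mito": float(realized_mam.sum()) / len(mitos),
        "mam_hist": realized_mam.tolist(),
        "mam_lengths_nm": mam_lengths, "mam_dists_nm": mam_dists,
        "pam_total": n_pam, "pam_lengths_nm": pam_lengths,
        "mito_pm": int(has_mito_pm), "mito_pairs": n_pairs,
        "cytoplasm_area_um2": cytoplasm.area / 1e6,
        "lambda_mam": lam,
    }
    return cell, row


# ---------------------------------------------------------------------------
# Fly activity traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlyGenParams:
    """Conditions for one genotype of synthetic activity traces.

    Sleep/wake dwell times are ``minimum + Exponential(mean excess)``
    minutes, with separate means for the light and dark halves of the
    12:12 cycle (regime fixed at bout onset).  ``fragmentation`` divides
    every dwell-excess mean (shorter, more numerous bouts at roughly
    constant sleep fraction); ``sleep_offset`` multiplies the sleep
    dwell-excess means only (total-sleep effect); ``rebound`` divides the
    wake dwell-excess means on the day following the enforced-wake night.
    """

    n_flies: int = 32
    genotype: str = "ctrl"
    n_days: int = 5
    sleep_excess_light_min: float = 9.0
    sleep_excess_dark_min: float = 42.0
    wake_excess_light_min: float = 21.0
    wake_excess_dark_min: float = 13.0
    min_sleep_min: int = 5
    min_wake_min: int = 1
    dwell_shape: float = 3.0        # Gamma shape of dwell excesses (1 = exponential)
    activity_rate: float = 2.0      # extra counts per awake minute (>= 1 always)
    fragmentation: float = 1.0
    sleep_offset: float = 1.0
    sd_night: int | None = None     # day index whose dark half is enforced wake
    rebound: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sleep_excess_light_min", "sleep_excess_dark_min",
                     "wake_excess_light_min", "wake_excess_dark_min",
                     "dwell_shape", "fragmentation", "sleep_offset", "rebound"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FlyTruth:
    """Realized per-fly per-day state-path truth."""

    table: pd.DataFrame

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def _simulate_fly(params: FlyGenParams, idx: int) -> tuple[np.ndarray, np.ndarray]:
    """State path (True = asleep) and activity counts for one fly."""
    dwell_rng = _rng(params.seed, idx, 0)
    act_rng = _rng(params.seed, idx, 1)
    # dwell excesses are mean/shape * G with G ~ Gamma(shape, 1); G is drawn
    # per bout from the fly's stream, so scaling a dwell mean (group effect)
    # rescales the same realization comonotonically
    k = params.dwell_shape
    g_block = dwell_rng.gamma(k, 1.0, size=4096)
    g_idx = 0
    n_min = params.n_days * DAY_MIN
    asleep_vec = np.zeros(n_min, dtype=bool)
    sd_start = sd_end = -1
    if params.sd_night is not None:
        sd_start = params.sd_night * DAY_MIN + HALF_DAY_MIN
        sd_end = sd_start + HALF_DAY_MIN

    t = 0
    state_sleep = False  # flies wake at lights-on
    while t < n_min:
        if sd_start <= t < sd_end:
            t = sd_end            # enforced wake for the whole dark phase
            state_sleep = True    # released into sleep at lights-on
            continue
        tod = t % DAY_MIN
        dark = tod >= HALF_DAY_MIN
        day = t // DAY_MIN
        rebound_day = (
            params.sd_night is not None and day == params.sd_night + 1
        )
        if g_idx >= g_block.size:
            g_block = np.concatenate([g_block, dwell_rng.gamma(k, 1.0, size=4096)])
        g = g_block[g_idx]
        g_idx += 1
        if state_sleep:
            mean = (params.sleep_excess_dark_min if dark
                    else params.sleep_excess_light_min)
            mean = mean * params.sleep_offset / params.fragmentation
            dwell = params.min_sleep_min + int(mean / k * g)
        else:
            mean = (params.wake_excess_dark_min if dark
                    else params.wake_excess_light_min)
            mean = mean / params.fragmentation
            if rebound_day:
                mean /= params.rebound
            dwell = params.min_wake_min + int(mean / k * g)
        end = min(t + dwell, n_min)
        if t < sd_start < end:
            end = sd_start
        if state_sleep:
            asleep_vec[t:end] = True
        t = end
        state_sleep = not state_sleep

    counts = np.zeros(n_min, dtype=int)
    awake = ~asleep_vec
    counts[awake] = 1 + act_rng.poisson(params.activity_rate, size=int(awake.sum()))
    return asleep_vec, counts


def synth_dam(params: FlyGenParams) -> tuple[list[ActivityTrace], FlyTruth]:
    """Generate one genotype's activity traces plus realized truth.

    Truth rows hold each fly's per-day minutes in the sleep state counted
    over maximal state-sleep runs of at least the scoring threshold, so
    the pipeline estimate can be compared against it directly.
    """
    start = datetime(2023, 1, 9, 8, 0, 0)  # lights-on at 08:00
    traces, rows = [], []
    for idx in range(params.n_flies):
        asleep, counts = _simulate_fly(params, idx)
        fly_id = f"{params.genotype}_{idx:03d}"
        traces.append(
            ActivityTrace(fly_id=fly_id, genotype=params.genotype,
                          start=start, counts=counts)
        )
        # truth: state-sleep runs >= 5 min, per day
        padded = np.concatenate([[False], asleep, [False]]).astype(int)
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1)
        truth_sleep = np.zeros_like(asleep)
        for s, e in zip(starts, ends):
            if e - s >= 5:
                truth_sleep[s:e] = True
        for day in range(params.n_days):
            sl = truth_sleep[day * DAY_MIN:(day + 1) * DAY_MIN]
            rows.append({
                "fly_id": fly_id, "genotype": params.genotype, "day": day,
                "true_sleep_min": int(sl.sum()),
                "true_sleep_dark_min": int(sl[HALF_DAY_MIN:].sum()),
                "true_sleep_fraction": float(sl.mean()),
            })
    return traces, FlyTruth(pd.DataFrame(rows))


def _mean_bouts_and_sleep(params: FlyGenParams, days: Iterable[int]) -> tuple[float, float]:
    """Cohort means of 24-h sleep-episode number and total sleep over the
    given days, measured with the scoring pipeline itself."""
    traces, _ = synth_dam(params)
    n_bouts, totals = [], []
    for tr in traces:
        recs = [sleep_architecture(tr, d) for d in days]
        n_bouts.append(np.mean([r.n_bouts for r in recs]))
        totals.append(np.mean([r.sleep_total_min for r in recs]))
    return float(np.mean(n_bouts)), float(np.mean(totals))


def calibrate_fragmentation(
    target_pct: float,
    control: FlyGenParams,
    sleep_offset: float = 1.0,
    n_flies: int = 600,
    seed: int = 1000,
    tol_pct: float = 0.02,
) -> float:
    """Fragmentation multiplier realizing a target percent increase in the
    24-h sleep-episode number relative to ``control`` (seeded bisection
    with common random numbers across the bracketing evaluations)."""
    days = range(min(4, control.n_days))
    base = replace(control, n_flies=n_flies, seed=seed)
    ref_bouts, _ = _mean_bouts_and_sleep(base, days)

    def realized(m: float) -> float:
        p = replace(base, fragmentation=m, sleep_offset=sleep_offset,
                    genotype="cal")
        bouts, _ = _mean_bouts_and_sleep(p, days)
        return (bouts - ref_bouts) / ref_bouts * 100.0

    lo, hi = 1.0, 3.0
    for _ in range(25):
        mid = (lo + hi) / 2
        r = realized(mid)
        if abs(r - target_pct) < tol_pct:
            return mid
        if r < target_pct:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def calibrate_sleep_offset(
    target_pct: float,
    control: FlyGenParams,
    n_flies: int = 600,
    seed: int = 1500,
    tol_pct: float = 0.02,
) -> float:
    """Sleep-dwell multiplier realizing a target percent change of 24-h
    total sleep relative to ``control`` (negative target = less sleep)."""
    days = range(min(4, control.n_days))
    base = replace(control, n_flies=n_flies, seed=seed)
    _, ref_total = _mean_bouts_and_sleep(base, days)

    def realized(off: float) -> float:
        p = replace(base, sleep_offset=off, genotype="cal")
        _, total = _mean_bouts_and_sleep(p, days)
        return (total - ref_total) / ref_total * 100.0

    lo, hi = 0.3, 1.5
    for _ in range(25):
        mid = (lo + hi) / 2
        r = realized(mid)
        if abs(r - target_pct) < tol_pct:
            return mid
        if r < target_pct:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def calibrate_rebound(
    target_pct: float,
    base: FlyGenParams,
    n_flies: int = 700,
    seed: int = 2000,
    tol_pct: float = 0.02,
) -> float:
    """Rebound multiplier realizing a target percent increase of post-SD
    total sleep over the 4-day baseline mean (seeded bisection)."""
    if base.sd_night is None:
        raise ValueError("base params must define an SD night")
    cal = replace(base, n_flies=n_flies, seed=seed)
    baseline_days = range(min(4, cal.sd_night))
    post_day = cal.sd_night + 1

    def realized(rho: float) -> float:
        p = replace(cal, rebound=rho)
        traces, _ = synth_dam(p)
        deltas = []
        for tr in traces:
            base_recs = [sleep_architecture(tr, d) for d in baseline_days]
            base_mean = np.mean([r.sleep_total_min for r in base_recs])
            post = sleep_architecture(tr, post_day).sleep_total_min
            deltas.append((post - base_mean) / base_mean * 100.0)
        return float(np.mean(deltas))

    lo, hi = 1.0, 6.0
    for _ in range(25):
        mid = (lo + hi) / 2
        r = realized(mid)
        if abs(r - target_pct) < tol_pct:
            return mid
        if r < target_pct:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# Expression matrices and blot lanes
# ---------------------------------------------------------------------------


def synth_expr(
    n_genes: int,
    n_per_group: int,
    planted: dict[str, tuple[Iterable[str], float]] | None = None,
    noise_sd_log2: float = 0.1,
    baseline_mean_log2: float = 7.0,
    baseline_sd_log2: float = 1.5,
    seed: int = 0,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Log2 expression matrix with planted linear fold changes.

    ``planted`` maps a set name to ``(gene ids, fold change %)``; the SD
    group mean of a planted gene is shifted by ``log2(1 + FC/100)``.
    Overlapping planted sets with conflicting fold changes are an error.
    Returns the study plus a per-gene truth table.
    """
    if noise_sd_log2 <= 0:
        raise ValueError("noise_sd_log2 must be positive")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    gene_fc = {}
    for name, (members, fc) in (planted or {}).items():
        if not math.isfinite(fc):
            raise ValueError(f"non-finite fold change for set {name!r}")
        for g in members:
            g = str(g).upper()
            if g in gene_fc and gene_fc[g] != fc:
                raise ValueError(
                    f"gene {g} planted with conflicting fold changes "
                    f"({gene_fc[g]} vs {fc})"
                )
            gene_fc[g] = fc
    rng = _rng(seed, 0)
    baseline = rng.normal(baseline_mean_log2, baseline_sd_log2, size=n_genes)
    effect = np.array([
        math.log2(1 + gene_fc.get(g, 0.0) / 100.0) for g in genes
    ])
    cols = {}
    for j in range(n_per_group):
        cols[f"S{j + 1}"] = baseline + _rng(seed, 1, j).normal(0, noise_sd_log2, n_genes)
    for j in range(n_per_group):
        cols[f"SD{j + 1}"] = (
            baseline + effect + _rng(seed, 2, j).normal(0, noise_sd_log2, n_genes)
        )
    matrix = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    groups = {c: ("SD" if c.startswith("SD") else "S") for c in matrix.columns}
    truth = pd.DataFrame({
        "gene": genes,
        "planted_fc_pct": [gene_fc.get(g, 0.0) for g in genes],
        "baseline_log2": baseline,
    })
    return ExpressionStudy(matrix=matrix, sample_groups=groups), truth


def synth_blot(
    effect_pct: float,
    n_per_group: int = 5,
    base_signal: float = 1000.0,
    loading_range: tuple[float, float] = (0.55, 1.0),
    noise_cv: float = 0.05,
    seed: int = 0,
) -> tuple[list[BlotLane], pd.DataFrame]:
    """Densitometry lanes with known per-lane loading factors.

    The observed target signal is (true expression) x (loading) x noise and
    the Ponceau total-protein signal is proportional to loading (with its
    own noise), so total-protein normalization must undo the loading to
    recover the planted group effect.
    """
    rng = _rng(seed, 0)
    lanes, rows = [], []
    for grp, mult, tag in (("S", 1.0, "S"), ("SD", 1 + effect_pct / 100.0, "SD")):
        for j in range(n_per_group):
            loading = rng.uniform(*loading_range)
            expr = base_signal * mult * rng.lognormal(0.0, noise_cv)
            total = 5e4 * loading * rng.lognormal(0.0, noise_cv / 2)
            lanes.append(BlotLane(lane_id=f"{tag}{j + 1}", group=grp,
                                  signal=expr * loading, total_protein=total))
            rows.append({"lane_id": f"{tag}{j + 1}", "group": grp,
                         "true_loading": loading, "true_expression": expr})
    return lanes, pd.DataFrame(rows)
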