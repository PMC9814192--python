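"""Apposition detection against constant-distance geometry and a dense
brute-force sampling reference."""

import math

import numpy as np
import pytest
import shapely.affinity
from shapely.geometry import LineString, Point, Polygon

from mamsleep.contacts import (
    ContactParams,
    apposition_segments,
    detect_contacts,
    mam_per_mito,
)
from mamsleep.errors import GeometryError, UndefinedMetricError
from mamsleep.geometry import CellGeometry
from mamsleep.synthetic import CellGenParams, _arc_tube, synth_cells

from oracles import brute_force_appositions, brute_force_cell_contacts

PARAMS = ContactParams()


def make_cell(er=(), mito=(), radius_nm=12000.0, pixel_size_nm=1.0):
    """Cell with a large circular boundary far from the test organelles."""
    cyto = Point(0, 0).buffer(radius_nm, quad_segs=64)
    return CellGeometry("t", "S", pixel_size_nm, cyto, er=list(er), mito=list(mito))


class TestAppositionSegments:
    def test_parallel_membranes_within_threshold(self):
        ref = LineString([(0, 0), (200, 0)])
        other = LineString([(-50, 15), (250, 15)])
        segs = apposition_segments(ref, other, PARAMS)
        assert len(segs) == 1
        assert segs[0].length_nm == pytest.approx(200, abs=2 * PARAMS.sample_step_nm)
        assert segs[0].min_distance_nm == pytest.approx(15, abs=1e-6)

    def test_parallel_membranes_beyond_threshold(self):
        ref = LineString([(0, 0), (200, 0)])
        other = LineString([(-50, 25), (250, 25)])
        assert apposition_segments(ref, other, PARAMS) == []

    def test_two_circles_matches_dense_sampling_oracle(self):
        # r = 150 nm, centres 315 nm apart -> closest approach 15 nm
        a = Point(0, 0).buffer(150, quad_segs=128)
        b = Point(315, 0).buffer(150, quad_segs=128)
        segs = apposition_segments(a.exterior, b.exterior, PARAMS)
        oracle = brute_force_appositions(a, b.exterior)
        assert len(segs) == len(oracle) == 1
        assert segs[0].length_nm == pytest.approx(oracle[0]["length"], abs=4.0)
        # closed form: apposed where cos(phi) > ((r+d_max)^2 - r^2 - c^2)/(-2 r c)
        phi = math.acos((150**2 + 315**2 - 170**2) / (2 * 150 * 315))
        assert segs[0].length_nm == pytest.approx(2 * 150 * phi, abs=6.0)

    def test_intersecting_curves_raise(self):
        ref = LineString([(0, 0), (100, 0)])
        other = LineString([(50, -10), (50, 10)])
        with pytest.raises(GeometryError):
            apposition_segments(ref, other, PARAMS)

    def test_monotone_in_threshold(self):
        """Enlarging d_max never decreases the total apposed span."""
        a = Point(0, 0).buffer(150, quad_segs=96)
        b = Point(310, 0).buffer(150, quad_segs=96)
        lengths = []
        for d_max in (12.0, 16.0, 20.0, 24.0):
            p = ContactParams(d_max_nm=d_max)
            segs = apposition_segments(a.exterior, b.exterior, p)
            lengths.append(sum(s.length_nm for s in segs))
        assert lengths == sorted(lengths)


class TestDetectContacts:
    def test_single_planted_mam_only(self):
        mito = Point(2000, 0).buffer(200, quad_segs=64)
        tube = _arc_tube(mito, arc_center=100.0, arc_len=150.0, dist=15.0, width=50.0)
        cell = make_cell(er=[tube], mito=[mito])
        cs = detect_contacts(cell, PARAMS)
        assert cs.count("MAM") == 1
        assert cs.count("PAM") == cs.count("MITO_PM") == cs.count("MITO_MITO") == 0
        oracle = brute_force_cell_contacts(cell)
        assert len(oracle["MAM"]) == 1
        assert cs.of_kind("MAM")[0].length_nm == pytest.approx(
            oracle["MAM"][0]["length"], abs=4.0
        )

    def test_one_cisterna_touching_twice_gives_two_mams(self):
        """Two apposition loci on one ER/mito pair separated by an arc gap
        far above merge_gap are annotated as multiple MAMs."""
        mito = Point(0, 0).buffer(300, quad_segs=96)
        # one C-shaped cisterna hugging the mito: apposed (12 nm) along two
        # 120-nm loci, bulging to 90 nm over the 260-nm stretch in between
        arc = np.linspace(-60.0, 560.0, 400)  # arc position on the mito, nm
        theta = arc / 300.0
        d = np.where((arc <= 60.0) | (arc >= 440.0), 12.0,
                     np.where((arc > 110.0) & (arc < 390.0), 90.0, 0.0))
        ramp_up = (arc > 60.0) & (arc <= 110.0)
        d[ramp_up] = 12.0 + (arc[ramp_up] - 60.0) / 50.0 * 78.0
        ramp_dn = (arc >= 390.0) & (arc < 440.0)
        d[ramp_dn] = 90.0 - (arc[ramp_dn] - 390.0) / 50.0 * 78.0
        inner = np.column_stack([(300 + d) * np.cos(theta), (300 + d) * np.sin(theta)])
        outer = np.column_stack([(300 + d + 45) * np.cos(theta), (300 + d + 45) * np.sin(theta)])
        er = Polygon(np.vstack([inner, outer[::-1]]))
        assert er.is_valid
        cell = make_cell(er=[er], mito=[mito])
        cs = detect_contacts(cell, PARAMS)
        assert cs.count("MAM") == 2
        assert cs.pair_multiplicity()[("er_0", "mito_0")] == 2

    def test_distant_mitochondria_have_no_contacts(self):
        mitos = [Point(x, 0).buffer(150, quad_segs=32) for x in (0, 1000, 2000)]
        cell = make_cell(mito=mitos)
        cs = detect_contacts(cell, PARAMS)
        assert cs.count("MITO_MITO") == 0

    def test_rigid_motion_invariance(self, one_cell):
        cs0 = detect_contacts(one_cell, PARAMS)
        moved = CellGeometry(
            cell_id=one_cell.cell_id, group=one_cell.group,
            pixel_size_nm=one_cell.pixel_size_nm,
            cytoplasm=shapely.affinity.rotate(
                shapely.affinity.translate(one_cell.cytoplasm, 37.5, -12.25), 31.0,
                origin=(0, 0)),
            er=[shapely.affinity.rotate(
                shapely.affinity.translate(p, 37.5, -12.25), 31.0, origin=(0, 0))
                for p in one_cell.er],
            mito=[shapely.affinity.rotate(
                shapely.affinity.translate(p, 37.5, -12.25), 31.0, origin=(0, 0))
                for p in one_cell.mito],
        )
        cs1 = detect_contacts(moved, PARAMS)
        for kind in ("MAM", "PAM", "MITO_PM", "MITO_MITO"):
            assert cs0.count(kind) == cs1.count(kind)
        l0 = sorted(s.length_nm for s in cs0.segments)
        l1 = sorted(s.length_nm for s in cs1.segments)
        assert np.allclose(l0, l1, atol=2 * PARAMS.sample_step_nm)

    def test_mito_mito_symmetric_under_reference_swap(self):
        a = Point(0, 0).buffer(200, quad_segs=96)
        b = Point(412, 0).buffer(200, quad_segs=96)
        s_ab = apposition_segments(a.exterior, b.exterior, PARAMS)
        s_ba = apposition_segments(b.exterior, a.exterior, PARAMS)
        assert len(s_ab) == len(s_ba) == 1
        assert s_ab[0].length_nm == pytest.approx(s_ba[0].length_nm, rel=0.10)


def test_contact_table_export(one_cell):
    from mamsleep.contacts import contacts_to_frame

    cs = detect_contacts(one_cell, PARAMS)
    df = contacts_to_frame([cs])
    assert len(df) == len(cs.segments)
    assert (df["min_distance_nm"] < PARAMS.d_max_nm).all()
    assert set(df["kind"]) <= {"MAM", "PAM", "MITO_PM", "MITO_MITO"}


class TestMamPerMito:
    def test_counts_and_histogram(self):
        mitos = [Point(0, 0).buffer(250, quad_segs=64),
                 Point(2500, 0).buffer(250, quad_segs=64)]
        tubes = [
            _arc_tube(mitos[0], 50.0, 120.0, 12.0, 45.0),
            _arc_tube(mitos[0], 800.0, 120.0, 12.0, 45.0),
            _arc_tube(mitos[1], 50.0, 120.0, 12.0, 45.0),
        ]
        cell = make_cell(er=tubes, mito=mitos)
        cs = detect_contacts(cell, PARAMS)
        ratio, hist = mam_per_mito(cs, cell)
        assert ratio == pytest.approx(1.5)
        assert sorted(hist.tolist()) == [1, 2]
        assert hist.sum() == cs.count("MAM")

    def test_no_mams(self):
        mitos = [Point(i * 2000, 0).buffer(200, quad_segs=32) for i in range(4)]
        cell = make_cell(mito=mitos)
        cs = detect_contacts(cell, PARAMS)
        ratio, hist = mam_per_mito(cs, cell)
        assert ratio == 0.0
        assert hist.tolist() == [0, 0, 0, 0]

    def test_zero_mitochondria_is_an_error(self):
        cell = make_cell(er=[Point(0, 0).buffer(100, quad_segs=32)])
        cs = detect_contacts(cell, PARAMS)
        with pytest.raises(UndefinedMetricError):
            mam_per_mito(cs, cell)
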