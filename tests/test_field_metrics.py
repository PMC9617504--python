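import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mcht.eye_sim import PtoticEye, lid_elevation_profile, synthesize_hvfa_grid
from mcht.field_metrics import (
    GRID_FRAME,
    MILD,
    NORMAL,
    SEVERE,
    Meridian,
    VisualFieldGrid,
    asb_to_db,
    aum_trapezoid,
    classify_severity,
    db_to_asb,
    iqr_outlier_filter,
    percent_degrees_visible,
    percent_improvement,
    percent_visible,
    trace_grid_meridian,
)
from mcht.geometry import DEFAULT_GEOMETRY, GridPoint, make_grid_pattern


def flat_meridian(elevation, azimuths=(-24.0, -12.0, 0.0, 12.0, 24.0)):
    return Meridian(tuple((a, elevation) for a in azimuths))


def grid_from_extents(extents: dict, visible_db=34.0, blind_db=1.0):
    """Synthetic grid whose column visible extents are prescribed."""
    pts = []
    for p in make_grid_pattern():
        if p.elevation_deg <= 0:
            pts.append(GridPoint(p.azimuth_deg, p.elevation_deg, visible_db))
        else:
            e = extents.get(p.azimuth_deg, 30.0)
            db = visible_db if p.elevation_deg <= e else blind_db
            pts.append(GridPoint(p.azimuth_deg, p.elevation_deg, db))
    return VisualFieldGrid(points=pts)


class TestAUM:
    def test_rectangle(self):
        assert aum_trapezoid(flat_meridian(24.0, (-24.0, 24.0))) == 1152.0

    def test_linear_ramp_triangle_equivalent(self):
        ramp = Meridian(((-24.0, 0.0), (24.0, 48.0)))
        assert aum_trapezoid(ramp) == 1152.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            aum_trapezoid(Meridian(((0.0, 10.0),)))

    def test_mirror_invariance_and_additivity(self):
        rng = np.random.default_rng(5)
        az = (-24.0, -12.0, 0.0, 12.0, 24.0)
        e1, e2 = rng.uniform(0, 24, 5), rng.uniform(0, 24, 5)
        m1 = Meridian(tuple(zip(az, e1)))
        m2 = Meridian(tuple(zip(az, e2)))
        both = Meridian(tuple(zip(az, e1 + e2)))
        assert aum_trapezoid(m1.mirrored()) == pytest.approx(aum_trapezoid(m1))
        assert aum_trapezoid(both) == pytest.approx(
            aum_trapezoid(m1) + aum_trapezoid(m2))

    def test_unsorted_meridian_rejected(self):
        with pytest.raises(ValueError):
            Meridian(((0.0, 1.0), (0.0, 2.0)))


class TestPercentVisible:
    def test_half_field(self):
        assert percent_visible(1152.0, DEFAULT_GEOMETRY) == 50.0

    def test_extremes(self):
        assert percent_visible(0.0, DEFAULT_GEOMETRY) == 0.0
        assert percent_visible(2304.0, DEFAULT_GEOMETRY) == 100.0

    def test_full_extent_meridian_is_exactly_100(self):
        full = flat_meridian(48.0, DEFAULT_GEOMETRY.column_azimuths_deg)
        assert percent_visible(aum_trapezoid(full), DEFAULT_GEOMETRY) == 100.0

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            percent_visible(-1.0, DEFAULT_GEOMETRY)


class TestPercentImprovement:
    @pytest.mark.parametrize("untaped,taped,expected", [
        (1000.0, 1300.0, 30.0),   # exactly the eligibility threshold
        (576.0, 1728.0, 200.0),
        (0.0, 0.0, 0.0),
    ])
    def test_known_values(self, untaped, taped, expected):
        assert percent_improvement(untaped, taped) == pytest.approx(expected)

    def test_zero_baseline_opens_to_infinity(self):
        assert percent_improvement(0.0, 100.0) == float("inf")

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            percent_improvement(-1.0, 10.0)


class TestSeverity:
    @pytest.mark.parametrize("mrd1,grade", [
        (1.5, SEVERE), (0.0, SEVERE), (1.999, SEVERE),
        (2.0, MILD), (3.0, MILD), (3.999, MILD),
        (4.0, NORMAL), (5.0, NORMAL),
    ])
    def test_grading_boundaries(self, mrd1, grade):
        assert classify_severity(mrd1) == grade

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_severity(-0.1)


class TestApostilbScale:
    @pytest.mark.parametrize("db,asb", [(0.0, 10000.0), (30.0, 10.0),
                                        (40.0, 1.0)])
    def test_known_conversions(self, db, asb):
        assert db_to_asb(db) == pytest.approx(asb)

    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_round_trip(self, db):
        assert asb_to_db(db_to_asb(db)) == pytest.approx(db, rel=1e-9, abs=1e-9)

    def test_strictly_decreasing(self):
        dbs = np.linspace(0, 50, 100)
        asbs = [db_to_asb(d) for d in dbs]
        assert all(b < a for a, b in zip(asbs, asbs[1:]))


class TestGridTracing:
    def test_fully_visible_grid_reads_full_extent(self):
        grid = grid_from_extents({}, visible_db=31.0)
        meridian = trace_grid_meridian(grid)
        assert all(e == 30.0 for _, e in meridian.samples)

    def test_partial_column_half_cell_credit(self):
        # visible at 3° and 9° only → extent 9 + 3 = 12°
        grid = grid_from_extents({3.0: 9.0})
        extent = dict(trace_grid_meridian(grid).samples)[3.0]
        assert extent == 12.0

    def test_scotoma_truncates_at_first_gap(self):
        # visible at 3° and 15° but blind at 9° → contiguity stops: 3 + 3 = 6°
        pts = []
        for p in make_grid_pattern():
            if p.azimuth_deg == 3.0 and p.elevation_deg in (3.0, 15.0):
                db = 34.0
            elif p.azimuth_deg == 3.0 and p.elevation_deg > 0:
                db = 1.0
            else:
                db = 34.0
            pts.append(GridPoint(p.azimuth_deg, p.elevation_deg, db))
        extent = dict(trace_grid_meridian(VisualFieldGrid(points=pts)).samples)[3.0]
        assert extent == 6.0

    def test_blind_lowest_row_reads_zero(self):
        grid = grid_from_extents({-3.0: 0.0})
        assert dict(trace_grid_meridian(grid).samples)[-3.0] == 0.0

    def test_empty_superior_field_rejected(self):
        pts = [GridPoint(p.azimuth_deg, p.elevation_deg, 30.0)
               for p in make_grid_pattern() if p.elevation_deg < 0]
        with pytest.raises(ValueError):
            trace_grid_meridian(VisualFieldGrid(points=pts))

    def test_tracer_recovers_lid_extent_within_one_cell(self):
        """Noise-free synthesized grids: the traced extent of the central
        columns matches the generating lid extent within one 6° cell over
        random MRD1 values (the programmatic tracer-validation analog)."""
        rng = np.random.default_rng(17)
        for mrd1 in rng.uniform(0.0, 5.0, size=100):
            eye = PtoticEye(mrd1_mm=float(mrd1))
            grid = synthesize_hvfa_grid(eye, noise_sd_db=0.0)
            traced = dict(trace_grid_meridian(grid).samples)
            for az in (-9.0, -3.0, 3.0, 9.0):  # full five-point columns
                truth = min(lid_elevation_profile(eye, az),
                            GRID_FRAME.elevation_max_deg)
                assert abs(traced[az] - truth) <= 6.0


class TestPercentDegreesVisible:
    def test_midline_average_of_adjacent_columns(self):
        grid = grid_from_extents({-3.0: 12.0, 3.0: 18.0})
        assert percent_degrees_visible(grid) == pytest.approx(50.0)

    def test_fully_visible_grid(self):
        assert percent_degrees_visible(grid_from_extents({})) == 100.0

    def test_exam_meridian_interpolation(self):
        assert percent_degrees_visible(flat_meridian(24.0),
                                       DEFAULT_GEOMETRY) == 50.0

    def test_meridian_far_from_midline_rejected(self):
        m = Meridian(((12.0, 10.0), (24.0, 10.0)))
        with pytest.raises(ValueError):
            percent_degrees_visible(m, DEFAULT_GEOMETRY)


class TestIQRFilter:
    @pytest.mark.parametrize("values,k,expected_flagged", [
        ([1, 2, 3, 4, 100], 1.5, [100]),
        ([1, 2, 3, 4], 1.5, []),
        ([1, 1, 1, 9], 0.0, [9]),
    ])
    def test_known_cases(self, values, k, expected_flagged):
        kept, flagged = iqr_outlier_filter(values, k=k)
        assert flagged == expected_flagged
        assert sorted(kept + flagged) == sorted(values)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_filter([1, 2, 3])

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=4,
                    max_size=30))
    def test_partition_property(self, values):
        kept, flagged = iqr_outlier_filter(values)
        assert len(kept) + len(flagged) == len(values)
        assert len(kept) >= len(values) // 2  # quartile box always kept
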