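"""ROI summaries, relative-change (Delta) statistics, pressures, pixel counts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meniscus_qmri.phantom import generate_wedge_mask
from meniscus_qmri.relaxometry import ParameterMap
from meniscus_qmri.response import (
    LoadingState,
    pixel_count_series,
    pressure_from_force,
    relative_change,
    summarize_maps,
    summarize_roi,
)
from meniscus_qmri.zones import partition_thirds


def map_from(values: np.ndarray, converged=None) -> ParameterMap:
    values = np.asarray(values, dtype=float)
    if converged is None:
        converged = np.isfinite(values)
    return ParameterMap(
        relaxation_time=values,
        amplitude=np.where(np.isfinite(values), 100.0, np.nan),
        converged=converged,
        residual_norm=np.zeros_like(values),
        contrast="T2",
        bounds=(1.0, 500.0),
    )


def sorted_quartiles_oracle(values):
    """Hand-rolled linear-interpolation quartiles on sorted data."""
    v = np.sort(np.asarray(values, dtype=float))
    out = []
    for q in (0.25, 0.5, 0.75):
        h = (len(v) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(v) - 1)
        out.append(v[lo] + (h - lo) * (v[hi] - v[lo]))
    return out


@pytest.fixture
def rect_partition():
    mask = np.zeros((6, 12), dtype=bool)
    mask[1:5, 1:10] = True  # 9 columns -> thirds of 3 columns
    return mask, partition_thirds(mask, "left")


class TestSummarizeRoi:
    def test_uniform_map_median_iqr(self, rect_partition):
        mask, part = rect_partition
        values = np.where(mask, 50.0, np.nan)
        s = summarize_roi(map_from(values), part, "entire", "s1")
        assert s.median == 50.0 and s.iqr == 0.0
        assert s.pixel_count == mask.sum()

    def test_small_roi_matches_sort_oracle(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, :] = True
        values = np.arange(1.0, 10.0).reshape(3, 3)
        part = partition_thirds(mask, "left")
        s = summarize_roi(map_from(np.where(mask, values, np.nan)), part, "entire")
        q1, med, q3 = sorted_quartiles_oracle(values.ravel())
        assert s.median == med == 5.0
        assert s.q1 == pytest.approx(q1)
        assert s.q3 == pytest.approx(q3)

    def test_flagged_pixels_excluded(self, rect_partition):
        mask, part = rect_partition
        values = np.where(mask, 40.0, np.nan)
        converged = mask.copy()
        bad = np.argwhere(mask)[:5]
        values[bad[:, 0], bad[:, 1]] = 400.0
        converged[bad[:, 0], bad[:, 1]] = False
        s = summarize_roi(map_from(values, converged), part, "entire")
        assert s.median == 40.0
        assert s.pixel_count == mask.sum() - 5

    def test_empty_roi_yields_missing_entry(self, rect_partition, caplog):
        mask, part = rect_partition
        values = np.where(mask, 40.0, np.nan)
        converged = np.zeros_like(mask)  # everything flagged
        s = summarize_roi(map_from(values, converged), part, "I", "s9")
        assert np.isnan(s.median) and s.pixel_count == 0

    def test_zonal_medians_of_piecewise_constant_map(self, rect_partition):
        mask, part = rect_partition
        values = np.full(mask.shape, np.nan)
        for zone, v in zip(("I", "II", "III"), (10.0, 20.0, 30.0)):
            values[part.zone_mask(zone)] = v
        for zone, v in zip(("I", "II", "III"), (10.0, 20.0, 30.0)):
            assert summarize_roi(map_from(values), part, zone).median == v

    def test_entire_count_equals_zone_sum(self, rect_partition):
        mask, part = rect_partition
        values = np.where(mask, 33.0, np.nan)
        pmap = map_from(values)
        entire = summarize_roi(pmap, part, "entire").pixel_count
        zones = sum(summarize_roi(pmap, part, z).pixel_count for z in ("I", "II", "III"))
        assert entire == zones

    def test_grid_mismatch_rejected(self, rect_partition):
        _, part = rect_partition
        with pytest.raises(ValueError, match="grid"):
            summarize_roi(map_from(np.ones((4, 4))), part, "entire")


class TestRelativeChange:
    def test_basic_arithmetic(self):
        assert relative_change(50.0, 40.0) == pytest.approx(25.0)
        assert relative_change(42.0, 42.0) == 0.0

    def test_cohort_t1_magnitude_consistent_with_published_delta2(self):
        # entire-sample cohort medians 696 ms unloaded -> 554 ms at delta2;
        # the cohort-mean Delta2 was -20.5 +/- 8.5 %
        d = relative_change(554.0, 696.0)
        assert d == pytest.approx(-20.4, abs=0.05)
        assert abs(d - (-20.5)) < 8.5

    def test_missing_for_bad_reference(self):
        assert np.isnan(relative_change(50.0, 0.0))
        assert np.isnan(relative_change(50.0, np.nan))
        assert np.isnan(relative_change(np.nan, 50.0))

    @given(
        a=st.floats(1.0, 1e3),
        b=st.floats(1.0, 1e3),
        k=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, a, b, k):
        assert relative_change(a * k, b * k) == pytest.approx(relative_change(a, b), rel=1e-9)


class TestPressureFromForce:
    @pytest.mark.parametrize(
        "force,expected",
        [(38.0, 0.30), (69.0, 0.55), (0.0, 0.0)],
    )
    def test_published_worked_example(self, force, expected):
        # standard 15 mm length x mean 8.4 mm width => 126 mm^2 contact area
        assert 15.0 * 8.4 == pytest.approx(126.0)
        assert pressure_from_force(force, 15.0, 8.4) == pytest.approx(expected)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            pressure_from_force(10.0, 0.0, 8.4)
        with pytest.raises(ValueError):
            pressure_from_force(-1.0, 15.0, 8.4)


class TestPixelCountSeries:
    def test_compression_ratio_recovered(self):
        masks = {
            "delta0": generate_wedge_mask(8.4, 11.45, 0.25, 1.0),
            "delta1": generate_wedge_mask(8.4, 11.45, 0.25, 0.9),
            "delta2": generate_wedge_mask(8.4, 11.45, 0.25, 0.75),
        }
        df = pixel_count_series(masks)
        n0 = df["pixel_count"].iloc[0]
        ratios = df["pixel_count"].to_numpy() / n0
        assert np.allclose(ratios, [1.0, 0.9, 0.75], atol=0.01)
        assert df["monotone_decrease"].all()

    def test_identical_masks_no_change(self):
        m = generate_wedge_mask(8.4, 11.45, 0.25)
        df = pixel_count_series([m, m, m])
        assert df["pixel_count"].nunique() == 1
        assert not df["monotone_decrease"].any()

    def test_published_count_ordering(self):
        counts = pixel_count_series(
            {
                "delta0": generate_wedge_mask(8.4, 11.45, 0.25, 1.0),
                "delta1": generate_wedge_mask(8.4, 11.45, 0.25, 0.896),
                "delta2": generate_wedge_mask(8.4, 11.45, 0.25, 0.754),
            }
        )["pixel_count"].tolist()
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 700 and counts[2] < 700  # 801 > 718 > 604 regime


class TestLoadingState:
    def test_delta0_must_be_unloaded(self, rect_partition):
        mask, part = rect_partition
        pmap = map_from(np.where(mask, 30.0, np.nan))
        with pytest.raises(ValueError, match="zero force"):
            LoadingState("delta0", {"T2": pmap}, part, compressive_force_n=10.0)

    def test_default_forces_follow_label(self, rect_partition):
        mask, part = rect_partition
        pmap = map_from(np.where(mask, 30.0, np.nan))
        state = LoadingState("delta2", {"T2": pmap}, part)
        assert state.set_pressure_bar == 4.0
        assert state.compressive_force_n == pytest.approx(69.1)

    def test_summarize_maps_long_format(self, rect_partition):
        mask, part = rect_partition
        pmap = map_from(np.where(mask, 30.0, np.nan))
        states = [
            LoadingState(label, {"T2": pmap}, part) for label in ("delta0", "delta1")
        ]
        df = summarize_maps(states, "s1", grade_group="I")
        assert len(df) == 2 * 1 * 4  # loads x contrasts x ROIs
        assert set(df["roi"]) == {"entire", "I", "II", "III"}
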