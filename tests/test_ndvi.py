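"""NDVI smoothing rules: negative runs, winter zeroing, despiking, aggregation."""

import numpy as np
import pytest

from breedsync.ndvi import (
    DEFAULT_WINTER_WINDOW_24,
    PixelSeries,
    aggregate_location,
    correct_spikes,
    flag_negative_runs,
    frame_to_pixels,
    pixels_to_frame,
    smooth_frame,
    smooth_location,
    zero_winter_negatives,
)
from breedsync.synthetic import NdviGenConfig, generate_pixel_series


def px(values, **kwargs):
    v = np.asarray(values, dtype=float)
    if v.ndim == 1:
        v = v[None, :]
    return PixelSeries(location_id="L", pixel_id="p", values=v, **kwargs)


class TestNegativeRuns:
    @pytest.mark.parametrize(
        "values, removed",
        [
            ([0.2, -0.1, -0.1, -0.1, 0.3], True),   # run of 3
            ([0.2, -0.1, -0.1, 0.3], False),        # run of 2
            ([0.2, 0.0, 0.1, 0.3], False),          # no negatives (0 not negative)
            ([-0.1, -0.1, -0.1], True),
        ],
    )
    def test_run_detection(self, values, removed):
        out = flag_negative_runs(px(values))
        assert out.removed is removed
        assert out.removal_reason == ("negative_run" if removed else "none")

    def test_run_spanning_year_boundary_detected(self):
        v = np.array([[0.2, 0.1, -0.1, -0.1], [-0.1, 0.2, 0.3, 0.1]])
        assert flag_negative_runs(px(v)).removed

    def test_already_removed_raises(self):
        with pytest.raises(ValueError, match="removed"):
            flag_negative_runs(px([0.1, 0.2], removed=True))


class TestWinterZeroing:
    def test_negative_winter_value_zeroed(self):
        v = np.zeros((1, 24))
        v[0, 0] = -0.05   # early January: inside the default window
        v[0, 15] = -0.05  # summer: outside
        v[0, 1] = 0.10    # winter but non-negative
        out = zero_winter_negatives(px(v), DEFAULT_WINTER_WINDOW_24)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 15] == -0.05
        assert out.values[0, 1] == 0.10

    def test_window_longer_than_six_months_rejected(self):
        with pytest.raises(ValueError, match="6 month"):
            zero_winter_negatives(px(np.zeros((1, 24))), frozenset(range(13)))


class TestSpikeCorrection:
    def test_single_spike_replaced_by_flank_mean(self):
        out, fixed = correct_spikes(px([0.5, 0.8, 0.5]))
        assert out.flat().tolist() == [0.5, 0.5, 0.5]
        assert fixed == [1]

    def test_below_threshold_untouched(self):
        out, fixed = correct_spikes(px([0.5, 0.7, 0.5]))
        assert out.flat().tolist() == [0.5, 0.7, 0.5]
        assert fixed == []

    def test_double_spike_interpolated_between_flanks(self):
        out, fixed = correct_spikes(px([0.3, 0.9, 0.9, 0.3]))
        assert np.allclose(out.flat(), [0.3, 0.3, 0.3, 0.3])
        assert fixed == [1, 2]

    def test_double_spike_unequal_flanks_linear(self):
        out, _ = correct_spikes(px([0.0, 0.9, 0.9, 0.15]))
        assert out.flat()[1] == pytest.approx(0.05)
        assert out.flat()[2] == pytest.approx(0.10)

    def test_double_spike_without_return_untouched(self):
        # flanks differ by more than the threshold: no "rapid return"
        vals = [0.0, 0.9, 0.9, 0.3]
        out, fixed = correct_spikes(px(vals))
        assert out.flat().tolist() == vals
        assert fixed == []

    def test_step_change_not_corrected(self):
        # A persistent level shift has no rapid return: leave it alone.
        vals = [0.1, 0.1, 0.6, 0.6, 0.6, 0.6]
        out, fixed = correct_spikes(px(vals))
        assert out.flat().tolist() == vals
        assert fixed == []

    def test_short_series_returned_unchanged(self):
        out, fixed = correct_spikes(px([0.1, 0.9]))
        assert out.flat().tolist() == [0.1, 0.9]
        assert fixed == []

    def test_corrections_local_to_anomaly(self):
        rng = np.random.default_rng(0)
        base = 0.4 + 0.05 * rng.standard_normal(48)
        spiked = base.copy()
        spiked[20] -= 0.5
        out, fixed = correct_spikes(px(spiked))
        assert fixed == [20]
        untouched = np.delete(np.arange(48), 20)
        assert np.array_equal(out.flat()[untouched], spiked[untouched])


class TestAggregation:
    def make_pixels(self, n, n_removed):
        out = []
        for i in range(n):
            out.append(
                PixelSeries(
                    location_id="L", pixel_id=f"p{i}",
                    values=np.full((2, 4), 0.1 * (i + 1)),
                    removed=i < n_removed,
                    removal_reason="negative_run" if i < n_removed else "none",
                )
            )
        return out

    def test_exactly_half_retained_is_kept(self):
        loc = aggregate_location(self.make_pixels(4, 2))
        assert loc.retained
        assert loc.values[0, 0] == pytest.approx((0.3 + 0.4) / 2)

    def test_below_half_excluded(self):
        loc = aggregate_location(self.make_pixels(4, 3))
        assert not loc.retained

    def test_single_pixel_identity(self):
        pixels = self.make_pixels(1, 0)
        loc = aggregate_location(pixels)
        assert np.array_equal(loc.values, pixels[0].values)

    def test_all_removed_excluded(self):
        loc = aggregate_location(self.make_pixels(2, 2))
        assert not loc.retained

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_location([])


class TestPipelineProperties:
    def test_clean_series_pass_through_unchanged(self):
        # Idempotence: no anomalies -> every stage is the identity.
        cfg = NdviGenConfig(interannual_sd=0.0, amplitude_cv=0.0, seed=1)
        pixels, ledger = generate_pixel_series(cfg, 3)
        assert ledger.empty
        loc, qc = smooth_location(pixels)
        assert qc.n_spikes_corrected == 0
        assert qc.n_pixels_retained == 3
        stacked = np.stack([p.values for p in pixels]).mean(axis=0)
        assert np.allclose(loc.values, stacked)

    def test_spike_recovery_on_ground_truth_ledger(self):
        # >= 95% of injected isolated spikes corrected; zero false positives
        # established by the clean-series test above.
        cfg = NdviGenConfig(spike_rate=0.01, seed=42)
        pixels, ledger = generate_pixel_series(cfg, 20)
        spikes = ledger[ledger.kind == "spike"]
        assert len(spikes) > 30
        hits = 0
        for pxs in pixels:
            _, fixed = correct_spikes(pxs)
            truth = {
                int(r.year) * pxs.periods_per_year + int(r.period)
                for r in spikes[spikes.pixel_id == pxs.pixel_id].itertuples()
            }
            hits += len(truth & set(fixed))
        assert hits / len(spikes) >= 0.95

    def test_winter_zeroing_precedes_run_removal(self):
        # Three consecutive winter negatives survive for a northern location
        # (zeroed first), but remove a non-northern pixel.
        v = np.full((1, 24), 0.3)
        v[0, 2:5] = -0.05  # periods 2..4 are in the Nov-May window
        pixels = [px(v)]
        loc_n, qc_n = smooth_location(pixels, northern=True)
        assert qc_n.n_pixels_retained == 1
        assert np.all(loc_n.values[0, 2:5] == 0.0)
        loc_s, qc_s = smooth_location(pixels, northern=False)
        assert qc_s.n_pixels_retained == 0


class TestCsvRoundTrip:
    def test_long_format_round_trip(self):
        cfg = NdviGenConfig(n_years=3, seed=5)
        pixels, _ = generate_pixel_series(cfg, 2)
        df = pixels_to_frame(pixels)
        assert set(df.columns) == {"location_id", "pixel_id", "year", "period", "ndvi"}
        back = frame_to_pixels(df)
        assert len(back) == 2
        for a, b in zip(pixels, back):
            assert np.allclose(a.values, b.values)

    def test_smooth_frame_qc_report(self):
        cfg = NdviGenConfig(n_years=3, spike_rate=0.02, seed=9)
        pixels, _ = generate_pixel_series(cfg, 4, location_id="locA")
        locs, qc = smooth_frame(pixels_to_frame(pixels))
        assert set(locs) == {"locA"}
        assert qc.loc[0, "n_pixels_initial"] == 4
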