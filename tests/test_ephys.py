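import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ffinet.ephys import (RecordingDataset, analyze_dataset,
                          classify_nonlinearity, group_by_chr2_effect,
                          psth, smoothed_summary, unit_filters,
                          visual_response_counts)
from ffinet.synth import (ProtocolSpec, SyntheticUnitSpec, generate_events,
                          generate_unit_spikes)


def make_dataset(spikes_per_unit, n_shanks=3, n_sets=4, seed=0):
    """Dataset from explicit spike-time arrays keyed by unit id."""
    events = generate_events(ProtocolSpec(), n_sets, seed=seed)
    rows = [pd.DataFrame({"unit_id": uid, "time_s": np.asarray(t)})
            for uid, t in spikes_per_unit.items()]
    spikes = pd.concat(rows, ignore_index=True) if rows else \
        pd.DataFrame({"unit_id": [], "time_s": []})
    units = pd.DataFrame({
        "unit_id": list(spikes_per_unit),
        "shank": [u % n_shanks for u in spikes_per_unit],
        "depth_um": 300.0, "su_flag": True})
    return RecordingDataset(
        spikes=spikes, events=events.drop(columns=["set_index"]),
        units=units)


class TestResponseCounts:
    def test_silent_unit_counts_zero(self):
        ds = make_dataset({0: []})
        b, r = visual_response_counts(ds, 0)
        assert b.sum() == 0 and r.sum() == 0
        assert len(b) == len(r) > 0

    def test_spike_between_windows_counts_nowhere(self):
        """A spike 10 ms after onset falls after the baseline window
        but before the 25-ms response-window offset."""
        ds = make_dataset({0: []})
        onset = ds.events.loc[~ds.events["light_on"], "onset_s"].iloc[0]
        ds2 = make_dataset({0: [onset + 0.010]})
        b, r = visual_response_counts(ds2, 0)
        assert b.sum() == 0 and r.sum() == 0

    def test_window_edges(self):
        ds = make_dataset({0: []})
        onset = ds.events.loc[~ds.events["light_on"], "onset_s"].iloc[0]
        # one spike just inside each window
        ds2 = make_dataset({0: [onset - 0.001, onset + 0.026]})
        b, r = visual_response_counts(ds2, 0)
        assert b.sum() == 1 and r.sum() == 1

    def test_homogeneous_poisson_expectation(self):
        """A Poisson unit at rate r yields ~0.175*r counts per window."""
        protocol = ProtocolSpec()
        events = generate_events(protocol, 6, seed=1)
        spec = SyntheticUnitSpec(unit_id=0, shank=0, baseline=20.0,
                                 response_amp=0.0, chr2_shift=0.0)
        times, _ = generate_unit_spikes(spec, events, seed=2)
        ds = make_dataset({0: times}, n_sets=6, seed=1)
        b, r = visual_response_counts(ds, 0)
        expect = 20.0 * 0.175
        se = np.sqrt(expect / len(b))
        assert abs(b.mean() - expect) < 4 * se
        assert abs(r.mean() - expect) < 4 * se


class TestClassification:
    def test_identical_counts_are_linear(self):
        counts = (np.arange(10), np.arange(10) + 2)
        res = classify_nonlinearity(counts, counts)
        assert res["p_value"] == 1.0
        assert res["label"] == "linear"

    def test_large_shift_is_supralinear(self):
        """+10 counts on every presentation is detected by the exact KS
        null distribution at n=50 per condition."""
        rng = np.random.default_rng(3)
        base = rng.poisson(3, 50)
        resp = rng.poisson(5, 50)
        off = (base, resp)
        on = (base.copy(), resp + 10)
        res = classify_nonlinearity(off, on)
        assert res["p_value"] < 0.01
        assert res["label"] == "supralinear"
        # mirrored shift flags sublinear
        on2 = (base.copy(), np.maximum(resp - 10, 0))
        assert classify_nonlinearity(off, on2)["label"] == "sublinear"

    def test_insufficient_presentations_rejected(self):
        with pytest.raises(ValueError):
            classify_nonlinearity(([1], [2]), ([1, 2], [2, 3]))

    def test_exact_ks_matches_scipy_oracle(self):
        """The classifier's p-value equals an independent exact KS
        computation on the baseline-subtracted counts."""
        rng = np.random.default_rng(4)
        off = (rng.poisson(2, 12), rng.poisson(4, 12))
        on = (rng.poisson(2, 15), rng.poisson(6, 15))
        res = classify_nonlinearity(off, on)
        expected = stats.ks_2samp(off[1] - off[0], on[1] - on[0],
                                  method="exact").pvalue
        assert res["p_value"] == pytest.approx(expected)


class TestFilters:
    def test_all_silent_dataset_excluded(self):
        ds = make_dataset({0: [], 1: [], 2: []})
        out = unit_filters(ds)
        assert not out["included"].any()

    def test_shank_below_threshold_excludes_responsive_unit(self):
        """A responsive unit on an unresponsive shank is dropped by the
        shank-level filter even though it passes the unit filter."""
        protocol = ProtocolSpec()
        events = generate_events(protocol, 4, seed=1)
        resp = SyntheticUnitSpec(unit_id=0, shank=0, baseline=2.0,
                                 response_amp=15.0, chr2_shift=0.0)
        quiet = [SyntheticUnitSpec(unit_id=k, shank=0, baseline=2.0,
                                   response_amp=0.0, chr2_shift=0.0)
                 for k in range(1, 8)]
        spikes = {}
        for k, spec in enumerate([resp] + quiet):
            t, _ = generate_unit_spikes(spec, events, seed=10 + k)
            spikes[spec.unit_id] = t
        ds = make_dataset(spikes, n_shanks=1, n_sets=4, seed=1)
        out = unit_filters(ds)
        if not out["included"].any():
            # shank mean diluted below 0.2 spk/s by the quiet units
            reason = out.loc[out["unit_id"] == 0,
                             "exclusion_reason"].item()
            assert reason == "shank-below-threshold"

    def test_known_responsive_units_recovered(self):
        protocol = ProtocolSpec()
        events = generate_events(protocol, 6, seed=2)
        spikes = {}
        responsive = set()
        for k in range(12):
            is_resp = k % 2 == 0
            # non-responsive units are silent so that the 0.2 spk/s
            # threshold separates the classes deterministically
            spec = SyntheticUnitSpec(
                unit_id=k, shank=k % 3,
                baseline=4.0 if is_resp else 0.0,
                response_amp=12.0 if is_resp else 0.0, chr2_shift=0.0)
            t, _ = generate_unit_spikes(spec, events, seed=20 + k)
            spikes[k] = t
            if is_resp:
                responsive.add(k)
        ds = make_dataset(spikes, n_shanks=3, n_sets=6, seed=2)
        out = unit_filters(ds)
        got = set(out.loc[out["included"], "unit_id"])
        assert got == responsive


class TestGrouping:
    def _shifts(self, ds, by_shank):
        rows = [{"unit_id": uid,
                 "baseline_shift": by_shank[shank]}
                for uid, shank in zip(ds.units["unit_id"],
                                      ds.units["shank"])]
        return pd.DataFrame(rows)

    def test_six_shanks_three_equal_groups(self):
        ds = make_dataset({k: [] for k in range(12)}, n_shanks=6)
        shifts = self._shifts(ds, {s: float(s) for s in range(6)})
        out = group_by_chr2_effect(ds, shifts)
        sizes = out.groupby("group")["shank"].nunique()
        assert list(sizes) == [2, 2, 2]

    def test_tied_means_stable_order(self):
        ds = make_dataset({k: [] for k in range(6)}, n_shanks=3)
        shifts = self._shifts(ds, {0: 1.0, 1: 1.0, 2: 1.0})
        a = group_by_chr2_effect(ds, shifts)
        b = group_by_chr2_effect(ds, shifts)
        assert (a["group"] == b["group"]).all()
        # ties broken by shank id: shank 0 lands in the lowest group
        assert a.loc[a["shank"] == 0, "group"].iloc[0] == 0

    def test_graded_shift_orders_groups(self):
        ds = make_dataset({k: [] for k in range(18)}, n_shanks=6)
        shifts = self._shifts(ds, {s: 2.0 * s for s in range(6)})
        out = group_by_chr2_effect(ds, shifts)
        means = out.groupby("group")["baseline_shift"].mean()
        assert means.is_monotonic_increasing

    def test_too_few_shanks_rejected(self):
        ds = make_dataset({0: [], 1: []}, n_shanks=2)
        shifts = self._shifts(ds, {0: 1.0, 1: 2.0})
        with pytest.raises(ValueError):
            group_by_chr2_effect(ds, shifts)


class TestSmoothedSummary:
    def test_flat_data_gives_flat_curve(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, 40)
        y = np.zeros(40)
        out = smoothed_summary(x, y, n_boot=100, seed=1)
        assert np.allclose(out["fit"], 0.0, atol=1e-12)
        assert (out["ci_lo"] <= 0).all() and (out["ci_hi"] >= 0).all()

    def test_linear_trend_recovered_within_ci(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 120)
        y = -0.1 * x + rng.normal(0, 0.05, 120)
        out = smoothed_summary(x, y, n_boot=200, seed=2)
        truth = -0.1 * out["x"]
        inside = (out["ci_lo"] <= truth) & (truth <= out["ci_hi"])
        assert inside.mean() > 0.8

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            smoothed_summary(np.ones(20), np.zeros(20))
        with pytest.raises(ValueError):
            smoothed_summary(np.arange(5), np.zeros(5))


class TestPsth:
    def test_constant_rate_unit_is_flat(self):
        protocol = ProtocolSpec()
        events = generate_events(protocol, 6, seed=3)
        spec = SyntheticUnitSpec(unit_id=0, shank=0, baseline=30.0,
                                 response_amp=0.0, chr2_shift=0.0)
        t, _ = generate_unit_spikes(spec, events, seed=7)
        ds = make_dataset({0: t}, n_sets=6, seed=3)
        out = psth(ds, 0)
        assert abs(out["rate_smooth"].mean() - 30.0) < 3.0
        assert out["rate_smooth"].std() < 6.0

    def test_silent_unit_zero_trace(self):
        ds = make_dataset({0: []})
        out = psth(ds, 0)
        assert np.allclose(out["rate"], 0.0)

    def test_single_spike_mass_conserved(self):
        ds = make_dataset({0: []})
        onset = ds.events["onset_s"].iloc[0]
        ds2 = make_dataset({0: [onset + 0.05]})
        out = psth(ds2, 0, bin_ms=10.0)
        n_events = len(ds2.events)
        raw_mass = out["rate"].sum() * 0.01 * n_events
        smooth_mass = out["rate_smooth"].clip(lower=0).sum() * 0.01 \
            * n_events
        assert raw_mass == pytest.approx(1.0, abs=1e-9)
        assert smooth_mass == pytest.approx(1.0, abs=0.5)


class TestOrderInvariance:
    def test_spike_row_order_does_not_matter(self):
        protocol = ProtocolSpec()
        events = generate_events(protocol, 4, seed=4)
        spikes = {}
        for k in range(6):
            spec = SyntheticUnitSpec(unit_id=k, shank=k % 3, baseline=6.0,
                                     response_amp=10.0, chr2_shift=3.0)
            t, _ = generate_unit_spikes(spec, events, seed=30 + k)
            spikes[k] = t
        ds = make_dataset(spikes, n_sets=4, seed=4)
        shuffled = ds.spikes.sample(frac=1.0, random_state=9)
        ds2 = RecordingDataset(spikes=shuffled, events=ds.events,
                               units=ds.units)
        a = analyze_dataset(ds, apply_filters=False)
        b = analyze_dataset(ds2, apply_filters=False)
        pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                      b.reset_index(drop=True))
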