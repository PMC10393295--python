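"""Synthetic cohort generator: QC arithmetic, ground-truth patterns,
forward-consistent LFP, spikes and input pools."""

import numpy as np
import pandas as pd
import pytest

from lamcsd.core import InvalidArgumentError
from lamcsd.icsd import build_forward, delta_icsd
from lamcsd.preprocess import trial_average
from lamcsd.synthetic import (
    DEFAULT_COMPONENTS,
    CanonicalComponentSpec,
    PopulationRateSpec,
    VariabilitySpec,
    assign_input_trains,
    build_lgn_input_pool,
    default_population_specs,
    filter_cohort,
    generate_cohort_manifest,
    manifest_from_frame,
    manifest_to_frame,
    rate_profile,
    synth_ground_truth_csd,
    synth_lfp_trials,
    synth_spike_cohort,
)

DEPTHS = np.arange(0.0, 861.0, 20.0)
FS = 1000.0
TAX = np.arange(-250.0, 250.0, 1.0)


class TestManifest:
    def test_cohort_counts(self):
        m = generate_cohort_manifest(58, 5, 9, 2, 75, seed=0)
        assert len(m) == 58
        assert sum(not x.has_v1_lfp for x in m) == 5
        assert sum(not x.probe_recoverable for x in m) == 9
        assert sum(not x.has_v1_units for x in m) == 2
        assert all(x.n_trials == 75 for x in m)
        assert len({x.animal_id for x in m}) == 58

    def test_retained_counts_match_qc_arithmetic(self):
        m = generate_cohort_manifest(58, 5, 9, 2, 75, seed=1)
        assert len(filter_cohort(m, "csd")) == 44
        assert len(filter_cohort(m, "spikes")) == 47

    def test_no_flags(self):
        m = generate_cohort_manifest(10, 0, 0, 0, 1, seed=0)
        assert len(filter_cohort(m, "csd")) == 10
        assert len(filter_cohort(m, "spikes")) == 10

    def test_determinism(self):
        a = generate_cohort_manifest(20, 2, 3, 1, 5, seed=42)
        b = generate_cohort_manifest(20, 2, 3, 1, 5, seed=42)
        assert a == b
        c = generate_cohort_manifest(20, 2, 3, 1, 5, seed=43)
        assert a != c

    def test_flag_counts_validated(self):
        with pytest.raises(InvalidArgumentError):
            generate_cohort_manifest(10, 11, 0, 0, 5, seed=0)
        with pytest.raises(InvalidArgumentError):
            generate_cohort_manifest(10, 5, 5, 5, 5, seed=0)  # disjoint overflow

    def test_overlap_mode_allows_shared_flags(self):
        m = generate_cohort_manifest(10, 5, 5, 5, 5, seed=0, allow_overlap=True)
        assert len(m) == 10
        assert sum(not x.has_v1_lfp for x in m) == 5

    def test_filter_preserves_order_and_subset_property(self):
        m = generate_cohort_manifest(30, 3, 4, 2, 5, seed=9)
        kept = filter_cohort(m, "csd")
        ids = [x.animal_id for x in m]
        assert kept == [i for i in ids if i in set(kept)]  # order preserved
        recoverable = {x.animal_id for x in m if x.probe_recoverable}
        assert set(kept) <= recoverable

    def test_unknown_modality(self):
        with pytest.raises(InvalidArgumentError):
            filter_cohort([], "lfp")

    def test_empty_manifest(self):
        assert filter_cohort([], "csd") == []

    def test_csv_round_trip(self):
        m = generate_cohort_manifest(6, 1, 1, 1, 3, seed=5)
        assert manifest_from_frame(manifest_to_frame(m)) == m


class TestGroundTruth:
    def test_early_sink_in_l4_band(self):
        p = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=0)
        early = p.values[:, (TAX >= 0) & (TAX < 50)]
        depth_of_min = DEPTHS[np.unravel_index(np.argmin(early), early.shape)[0]]
        assert 310 <= depth_of_min <= 500  # L4 band

    def test_empty_component_list(self):
        p = synth_ground_truth_csd([], DEPTHS, TAX, None, seed=0)
        assert not p.values.any()

    def test_zero_jitter_deterministic(self):
        a = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=1)
        b = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=2)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_component_single_signed(self):
        for comp in DEFAULT_COMPONENTS:
            p = synth_ground_truth_csd([comp], DEPTHS, TAX, None, seed=0)
            if comp.polarity == "sink":
                assert p.values.max() <= 0 and p.values.min() < 0
            else:
                assert p.values.min() >= 0 and p.values.max() > 0

    def test_jitter_clipping_warns(self):
        comp = CanonicalComponentSpec("edge", "sink", 850.0, 50.0, 40.0, 20.0,
                                      -1.0, "transient")
        jit = VariabilitySpec(animal_depth_sd=500.0)
        with pytest.warns(UserWarning, match="clipping"):
            # some seed will push the component off the grid
            for seed in range(20):
                synth_ground_truth_csd([comp], DEPTHS, TAX, jit, seed=seed)

    def test_component_polarity_validation(self):
        with pytest.raises(InvalidArgumentError):
            CanonicalComponentSpec("bad", "sink", 400.0, 50.0, 40.0, 20.0,
                                   +1.0, "transient")
        with pytest.raises(InvalidArgumentError):
            CanonicalComponentSpec("bad", "source", 400.0, 50.0, 40.0, 20.0,
                                   -1.0, "sustained")


class TestLfpTrials:
    def _op(self):
        return build_forward(DEPTHS, context="experiment")

    def test_zero_truth_zero_noise(self):
        truth = synth_ground_truth_csd([], DEPTHS, TAX, None, seed=0)
        rec = synth_lfp_trials(truth, DEPTHS, 2, VariabilitySpec(), self._op(),
                               seed=0, fs=FS)
        assert not rec.lfp.any()
        assert rec.n_trials == 2

    def test_forward_inverse_round_trip(self):
        truth = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=0)
        op = self._op()
        rec = synth_lfp_trials(truth, DEPTHS, 1, VariabilitySpec(), op, seed=0, fs=FS)
        avg = trial_average(rec, (TAX[0], TAX[-1] + 1.0))
        est = delta_icsd(op, avg)
        err = np.abs(est.values - truth.values).max() / np.abs(truth.values).max()
        assert err < 1e-8

    def test_averaging_reduces_noise(self):
        truth = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=0)
        op = self._op()
        noise = VariabilitySpec(trial_noise_sd=5.0)
        evoked = op.matrix @ truth.values

        def rms_dev(n_trials, seed):
            rec = synth_lfp_trials(truth, DEPTHS, n_trials, noise, op,
                                   seed=seed, fs=FS)
            avg = trial_average(rec, (TAX[0], TAX[-1] + 1.0))
            return np.sqrt(np.mean((avg.values - evoked) ** 2))

        assert rms_dev(75, seed=3) < rms_dev(1, seed=3)
        # and quantitatively ~ 1/sqrt(n)
        assert rms_dev(75, seed=3) == pytest.approx(5.0 / np.sqrt(75), rel=0.2)

    def test_gamma_band_oscillation_present(self):
        truth = synth_ground_truth_csd([], DEPTHS, TAX, None, seed=0)
        noise = VariabilitySpec(gamma_amplitude=5.0, gamma_period=20.0)
        rec = synth_lfp_trials(truth, DEPTHS, 1, noise, self._op(), seed=0, fs=FS)
        ch = np.argmin(np.abs(rec.depths - 300.0))  # envelope center
        seg = rec.lfp[ch]
        seg = seg[np.abs(seg) > 0]
        spec = np.abs(np.fft.rfft(seg - seg.mean()))
        freqs = np.fft.rfftfreq(seg.size, 1 / FS)
        peak_f = freqs[np.argmax(spec)]
        assert peak_f == pytest.approx(50.0, abs=2.0)  # 20 ms period

    def test_depth_mismatch_rejected(self):
        truth = synth_ground_truth_csd([], DEPTHS, TAX, None, seed=0)
        with pytest.raises(InvalidArgumentError):
            synth_lfp_trials(truth, DEPTHS + 10.0, 1, VariabilitySpec(),
                             self._op(), seed=0, fs=FS)
        op_bad = build_forward(DEPTHS[:-1], context="experiment")
        with pytest.raises(InvalidArgumentError):
            synth_lfp_trials(truth, DEPTHS, 1, VariabilitySpec(), op_bad,
                             seed=0, fs=FS)

    def test_determinism(self):
        truth = synth_ground_truth_csd(DEFAULT_COMPONENTS, DEPTHS, TAX, None, seed=0)
        noise = VariabilitySpec(trial_noise_sd=3.0, gamma_amplitude=2.0)
        a = synth_lfp_trials(truth, DEPTHS, 3, noise, self._op(), seed=11, fs=FS)
        b = synth_lfp_trials(truth, DEPTHS, 3, noise, self._op(), seed=11, fs=FS)
        np.testing.assert_array_equal(a.lfp, b.lfp)


class TestSpikes:
    def test_zero_baseline_no_prestimulus_spikes(self):
        spec = PopulationRateSpec("RS L4", 0.0, 20.0, 5.0, 45.0, 10, 0.55,
                                  "V1", "4", "RS")
        table = synth_spike_cohort([spec], 20, seed=0)
        assert (table.spikes["spike_time_s"] >= 0).all()

    def test_baseline_rate_recovery_within_3_se(self):
        rate = 8.0
        n_units, n_trials = 60, 30
        spec = PopulationRateSpec("FS", rate, 30.0, 12.0, 45.0, n_units, 0.25,
                                  "V1", "none", "FS")
        table = synth_spike_cohort([spec], n_trials, seed=1)
        win_s = 0.25
        n_spikes = (table.spikes["spike_time_s"] < 0).sum()
        est = n_spikes / (n_units * n_trials * win_s)
        se = np.sqrt(rate / (n_units * n_trials * win_s))
        assert abs(est - rate) < 3 * se

    def test_determinism(self):
        specs = default_population_specs(5)
        a = synth_spike_cohort(specs, 4, seed=2)
        b = synth_spike_cohort(specs, 4, seed=2)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.units, b.units)

    def test_default_specs_fs_baseline_dominates(self):
        specs = default_population_specs()
        fs = next(s for s in specs if s.population == "FS")
        for s in specs:
            if s.cls == "RS":
                assert fs.baseline_rate > 2 * s.baseline_rate

    def test_waveform_modes_separate_classes(self):
        table = synth_spike_cohort(default_population_specs(40), 1, seed=3)
        rs = table.units[table.units["population"] != "FS"]["duration_ms"]
        fs = table.units[table.units["population"] == "FS"]["duration_ms"]
        assert (rs >= 0.4).mean() > 0.95
        assert (fs < 0.4).mean() > 0.95

    def test_negative_rates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PopulationRateSpec("RS L4", -1.0, 20.0, 5.0, 45.0, 10, 0.55)

    def test_empty_specs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            synth_spike_cohort([], 5, seed=0)

    def test_rate_profile_hits_anchors(self):
        spec = PopulationRateSpec("RS L4", 3.0, 16.0, 5.0, 45.0, 1, 0.55)
        t = np.arange(-250.0, 350.0, 1.0)
        r = rate_profile(spec, t)
        assert r[t < 33].max() == pytest.approx(3.0)
        assert r[np.argmin(np.abs(t - 45.0))] == pytest.approx(16.0)
        assert r[(t > 62) & (t < 250)].max() == pytest.approx(5.0)


class TestInputPools:
    _template = PopulationRateSpec("LGN RS", 5.0, 25.0, 10.0, 35.0, 1, 0.42,
                                   "LGN", "none", "RS")

    def test_pool_size_multiplicative(self):
        pool = build_lgn_input_pool(21, 5, self._template, seed=0)
        assert pool.n_trains == 21 * 5

    def test_full_scale_pool_count(self):
        pool = build_lgn_input_pool(1263, 75, self._template, seed=0)
        assert pool.n_trains == 94_725

    def test_assignment_covers_all_targets(self):
        pool = build_lgn_input_pool(40, 5, self._template, seed=0)
        assignment = assign_input_trains(pool, n_target_units=300, n_sim_trials=4,
                                         n_subsets=10, seed=0)
        assert assignment.shape == (4, 300)
        assert (assignment >= 0).all() and (assignment < pool.n_trains).all()

    def test_one_subset_per_trial(self):
        pool = build_lgn_input_pool(100, 1, self._template, seed=0)
        assignment = assign_input_trains(pool, 500, n_sim_trials=5,
                                         n_subsets=5, seed=0)
        # trains used in different trials come from disjoint subsets
        used = [set(row.tolist()) for row in assignment]
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (used[i] & used[j])

    def test_degenerate_single_train_pool(self):
        pool = build_lgn_input_pool(1, 1, self._template, seed=0)
        assignment = assign_input_trains(pool, 3, n_sim_trials=1, n_subsets=1,
                                         seed=0)
        assert (assignment == 0).all()

    def test_preconditions(self):
        pool = build_lgn_input_pool(4, 2, self._template, seed=0)
        with pytest.raises(InvalidArgumentError):
            assign_input_trains(pool, 10, n_sim_trials=5, n_subsets=3, seed=0)
        with pytest.raises(InvalidArgumentError):
            build_lgn_input_pool(0, 5, self._template, seed=0)

    def test_trains_sorted_and_quantized(self):
        pool = build_lgn_input_pool(30, 2, self._template, seed=4)
        for i in range(0, pool.n_trains, 7):
            tr = pool.train(i)
            assert (np.diff(tr) >= 0).all()
            np.testing.assert_allclose(tr, np.round(tr / 1e-4) * 1e-4, atol=1e-12)
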