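"""Coded-vector classifier: coding arithmetic, training, classification."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

import cortstate as cs
from cortstate.classifier import (
    DESYNCHRONISED,
    SYNCHRONISED,
    Bounds,
    ModelVectorSet,
    StateSegmentation,
    classify,
    classify_trials,
    compute_bounds,
    define_model_vectors,
    encode,
    label_coded_vectors,
    pairwise_differences,
)
from cortstate.simulate import SimConfig, StateParams, simulate_lfp
from cortstate.spectral import BandPowerSeries, WindowScheme


def _bps(powers, step_s=1.0, window_s=10.0, normalisation="relative"):
    powers = np.asarray(powers, dtype=float)
    return BandPowerSeries(
        times=np.arange(powers.shape[0], dtype=float) * step_s,
        powers=powers,
        scheme=WindowScheme(window_s, step_s),
        channels_used=[1],
        normalisation=normalisation,
    )


class TestPairwiseDifferences:
    def test_ten_series_produced(self):
        err = pairwise_differences(_bps(np.ones((7, 5))))
        assert err.shape == (7, 10)

    def test_equal_bands_give_zero(self):
        err = pairwise_differences(_bps(3.3 * np.ones((4, 5))))
        assert np.all(err == 0.0)

    def test_hand_enumerated_multiset(self):
        # bands (1,2,3,4,5): all C(5,2) differences by hand
        err = pairwise_differences(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        assert sorted(err[0]) == [1, 1, 1, 1, 2, 2, 2, 3, 3, 4]

    def test_order_of_subtraction_immaterial(self):
        a = pairwise_differences(np.array([[5.0, 4.0, 3.0, 2.0, 1.0]]))
        b = pairwise_differences(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        np.testing.assert_array_equal(sorted(a[0]), sorted(b[0]))

    def test_wrong_band_count_rejected(self):
        with pytest.raises(ValueError, match="5"):
            pairwise_differences(np.ones((3, 4)))


class TestComputeBounds:
    def test_toy_matrix_matches_hand_calculation(self):
        # two windows, hand-computable per-pair means
        err = np.array([
            [0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00],
            [0.32, 0.42, 0.52, 0.62, 0.72, 0.82, 0.92, 1.02, 1.12, 1.22],
        ])
        # per-pair means: 0.21,0.31,...,1.11 -> mean of |means| = 0.66 -> 0.7
        b = compute_bounds(err, rounding_precision=1)
        assert b.ub == pytest.approx(0.7)
        assert b.lb == pytest.approx(0.35)

    def test_lower_bound_is_half_upper(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            b = compute_bounds(rng.uniform(0.05, 2.0, size=(8, 10)))
            if b.ub > 0:
                assert b.lb / b.ub == 0.5

    def test_zero_err_gives_zero_bounds(self):
        b = compute_bounds(np.zeros((3, 10)))
        assert b.ub == 0.0 and b.lb == 0.0

    def test_rounding_precision(self):
        err = np.full((2, 10), 0.16)
        assert compute_bounds(err, rounding_precision=1).ub == pytest.approx(0.2)
        assert compute_bounds(err, rounding_precision=2).ub == pytest.approx(0.16)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_bounds(np.empty((0, 10)))


class TestEncode:
    BOUNDS = Bounds(ub=1.0, lb=0.5)

    def test_boundaries_belong_to_middle_code(self):
        err = np.array([[0.5, 1.0, 0.49999, 1.00001, 0.7, 0.0, 2.0, 0.5, 1.0, 0.6]])
        codes = encode(err, self.BOUNDS)
        assert list(codes[0]) == [3, 3, 2, 4, 3, 2, 4, 3, 3, 3]

    def test_all_zero_err_codes_low(self):
        codes = encode(np.zeros((2, 10)), self.BOUNDS)
        assert np.all(codes == 2)

    def test_hand_evaluated_row(self):
        err = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.2]])
        codes = encode(err, self.BOUNDS)
        assert list(codes[0]) == [2, 2, 2, 2, 3, 3, 3, 3, 3, 4]

    def test_alternative_integer_coding(self):
        err = np.array([[0.1, 0.7, 1.5] + [0.0] * 7])
        codes = encode(err, self.BOUNDS, codes=(10, 20, 30))
        assert list(codes[0][:3]) == [10, 20, 30]


def _model_from_codes(sync_vecs, desync_vecs, bounds=None):
    bounds = bounds or Bounds(ub=1.0, lb=0.5)
    return ModelVectorSet(
        vectors={
            SYNCHRONISED: np.asarray(sync_vecs, dtype=int),
            DESYNCHRONISED: np.asarray(desync_vecs, dtype=int),
        },
        counts={
            SYNCHRONISED: np.ones(len(sync_vecs), dtype=int),
            DESYNCHRONISED: np.ones(len(desync_vecs), dtype=int),
        },
        bounds=bounds,
    )


class TestDefineModelVectors:
    def _series_with_pattern_counts(self, patterns, counts):
        rows = []
        for p, c in zip(patterns, counts):
            rows.extend([p] * c)
        return _bps(np.array(rows, dtype=float))

    def test_top_vectors_match_counting_oracle(self):
        # band-power patterns with known occurrence counts; the coded
        # vectors inherit those counts exactly
        patterns = [
            (0.9, 0.02, 0.02, 0.03, 0.03),
            (0.6, 0.2, 0.1, 0.05, 0.05),
            (0.3, 0.3, 0.2, 0.1, 0.1),
            (0.25, 0.25, 0.2, 0.15, 0.15),
            (0.2, 0.2, 0.2, 0.2, 0.2),
            (0.1, 0.1, 0.2, 0.3, 0.3),
            (0.05, 0.1, 0.15, 0.3, 0.4),
        ]
        counts = [7, 5, 3, 2, 1, 1, 1]
        sync = self._series_with_pattern_counts(patterns, counts)
        desync = self._series_with_pattern_counts(list(reversed(patterns)), counts)
        model = define_model_vectors(
            {SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=5
        )
        # independent counting oracle over the same coded vectors
        for state, series in ((SYNCHRONISED, sync), (DESYNCHRONISED, desync)):
            coded = encode(pairwise_differences(series), model.bounds)
            tally = Counter(tuple(row) for row in coded)
            expected = {v for v, _ in tally.most_common(5)}
            got = {tuple(row) for row in model.vectors[state]}
            # resolve possible count ties by comparing count multisets
            assert sorted(tally[v] for v in got) == sorted(
                tally[v] for v in expected
            )
            np.testing.assert_array_equal(
                model.counts[state], sorted(model.counts[state])[::-1]
            )

    def test_two_states_l5_give_ten_vectors(self, trained_model):
        assert trained_model.l == 5
        assert trained_model.n_vectors == 10

    def test_identical_windows_fully_explained_with_l1(self):
        sync = _bps(np.tile((0.8, 0.05, 0.05, 0.05, 0.05), (6, 1)))
        desync = _bps(np.tile((0.1, 0.1, 0.2, 0.3, 0.3), (6, 1)))
        model = define_model_vectors(
            {SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=1
        )
        assert model.variance_explained[SYNCHRONISED] == 1.0
        assert model.variance_explained[DESYNCHRONISED] == 1.0

    def test_variance_explained_is_occurrence_coverage(self):
        # 3 windows of one pattern + 1 of another, l=1 -> coverage 0.75
        sync = _bps(np.array([(0.8, 0.05, 0.05, 0.05, 0.05)] * 3
                             + [(0.3, 0.3, 0.2, 0.1, 0.1)]))
        desync = _bps(np.array([(0.05, 0.05, 0.1, 0.4, 0.4)] * 4))
        model = define_model_vectors(
            {SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=1
        )
        assert model.variance_explained[SYNCHRONISED] == pytest.approx(0.75)

    def test_single_state_training_rejected(self):
        with pytest.raises(ValueError, match="two states"):
            define_model_vectors({SYNCHRONISED: _bps(np.ones((5, 5)))})

    def test_too_few_distinct_vectors_rejected(self):
        sync = _bps(np.tile((0.8, 0.05, 0.05, 0.05, 0.05), (6, 1)))
        desync = _bps(np.tile((0.1, 0.1, 0.2, 0.3, 0.3), (6, 1)))
        with pytest.raises(ValueError, match="distinct coded vectors"):
            define_model_vectors({SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=5)

    def test_bounds_from_lower_variance_state(self):
        rng = np.random.default_rng(1)
        base_s = np.array((0.5, 0.2, 0.1, 0.1, 0.1))
        base_d = np.array((0.1, 0.15, 0.15, 0.3, 0.3))
        sync = _bps(np.abs(base_s + 0.2 * rng.standard_normal((40, 5))))
        desync = _bps(np.abs(base_d + 0.01 * rng.standard_normal((40, 5))))
        model = define_model_vectors(
            {SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=3
        )
        assert model.bounds.source_state == DESYNCHRONISED
        forced = define_model_vectors(
            {SYNCHRONISED: sync, DESYNCHRONISED: desync}, l=3,
            bounds_state=SYNCHRONISED,
        )
        assert forced.bounds.source_state == SYNCHRONISED


class TestClassify:
    def test_exact_model_vector_match(self):
        model = _model_from_codes([[2] * 10], [[4] * 10])
        # every pairwise difference > UB codes to all-4 -> desynchronised
        data = _bps(np.array([[10.0, 1.0, 20.0, 4.0, 40.0]]), normalisation="raw")
        model.feature_config = data.feature_config()
        seg = classify(data, model)
        assert seg.labels[0] == DESYNCHRONISED
        assert seg.distances[DESYNCHRONISED][0] == 0

    def test_every_window_labelled(self, test_segmentation):
        assert seg_all_labelled(test_segmentation)

    def test_determinism(self, test_experiment, trained_model):
        _, rec, _ = test_experiment
        s1 = cs.classify_recording(rec, trained_model)
        s2 = cs.classify_recording(rec, trained_model)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_tie_keeps_previous_label(self):
        model = _model_from_codes([[2] * 10], [[4] * 10])
        model.feature_config = {}
        # codes all-3 are equidistant (10 vs 10) from both model vectors
        tie = [3] * 10
        labels, _ = label_coded_vectors(
            np.array([tie, [4] * 10, tie, [2] * 10, tie]), model
        )
        assert list(labels) == [
            SYNCHRONISED,       # first-window tie defaults to synchronised
            DESYNCHRONISED,
            DESYNCHRONISED,     # tie retains previous
            SYNCHRONISED,
            SYNCHRONISED,       # tie retains previous
        ]

    def test_scale_robust_in_relative_mode(self, test_experiment, trained_model):
        _, rec, _ = test_experiment
        scaled = cs.LFPRecording(
            rec.samples * 12.5, sample_rate=rec.sample_rate,
            channel_ids=rec.channel_ids,
        )
        s1 = cs.classify_recording(rec, trained_model)
        s2 = cs.classify_recording(scaled, trained_model)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_feature_config_mismatch_rejected(self, trained_model):
        data = _bps(np.ones((3, 5)), normalisation="raw")
        with pytest.raises(ValueError, match="mismatch"):
            classify(data, trained_model)

    def test_accuracy_on_separated_states(self, test_experiment,
                                          test_segmentation):
        # strongly separated simulated states: >=90% of windows correct
        _, _, truth = test_experiment
        row = cs.score(test_segmentation, truth)
        assert row.percent_unclassified == 0.0
        assert row.total_accuracy >= 90.0

    def test_brute_force_nearest_vector_oracle(self, rng):
        # fuzzed model set; every realisable coded pattern in a sample of
        # the 3^10 space must agree with an exhaustive python search
        all_codes = rng.integers(2, 5, size=(500, 10))
        sync_v = rng.integers(2, 5, size=(5, 10))
        desync_v = rng.integers(2, 5, size=(5, 10))
        model = _model_from_codes(sync_v, desync_v)
        labels, dists = label_coded_vectors(all_codes, model)
        prev = SYNCHRONISED
        for i, code in enumerate(all_codes):
            ds = min(sum(abs(int(a) - int(b)) for a, b in zip(code, v))
                     for v in sync_v)
            dd = min(sum(abs(int(a) - int(b)) for a, b in zip(code, v))
                     for v in desync_v)
            if ds < dd:
                expect = SYNCHRONISED
            elif dd < ds:
                expect = DESYNCHRONISED
            else:
                expect = prev
            assert labels[i] == expect
            assert dists[SYNCHRONISED][i] == ds
            assert dists[DESYNCHRONISED][i] == dd
            prev = labels[i]


def seg_all_labelled(seg: StateSegmentation) -> bool:
    return all(lab in (SYNCHRONISED, DESYNCHRONISED) for lab in seg.labels)


class TestMonotoneDegradation:
    SYNC_W = np.array((0.55, 0.15, 0.08, 0.12, 0.10))
    DESYNC_W = np.array((0.08, 0.10, 0.12, 0.30, 0.40))

    def _config(self, sep: float, seed: int = 7) -> SimConfig:
        w = tuple(self.SYNC_W + sep * (self.DESYNC_W - self.SYNC_W))
        rms = 1.0 + sep * (0.4 - 1.0)
        return SimConfig(duration_s=300.0, n_channels=4, rng_seed=seed,
                         desync_params=StateParams(w, rms))

    def test_accuracy_degrades_to_chance_as_separation_shrinks(self):
        accs = []
        majority = None
        for sep in (1.0, 0.6, 0.3, 0.0):
            rec, truth = simulate_lfp(self._config(sep))
            model = cs.train_classifier(rec, truth, l=3)
            seg = cs.classify_recording(rec, model)
            accs.append(cs.score(seg, truth).total_accuracy)
            if sep == 0.0:
                majority = 100.0 * max(truth.occupancy().values())
        # non-increasing within stochastic slack
        for a, b in zip(accs, accs[1:]):
            assert b <= a + 8.0
        assert accs[0] >= 90.0
        # indistinguishable states: no better than majority-class guessing
        assert accs[-1] <= majority + 5.0


class _Trials:
    def __init__(self, onsets):
        self.onsets = np.asarray(onsets, dtype=float)


class TestClassifyTrials:
    def _seg(self, labels, times=None):
        labels = np.asarray(labels, dtype=object)
        if times is None:
            times = np.arange(len(labels), dtype=float)
        return StateSegmentation(window_times=times, labels=labels,
                                 step_s=1.0, window_s=10.0)

    def test_unanimous_prestim_state(self):
        seg = self._seg([SYNCHRONISED] * 100)
        states = classify_trials(seg, _Trials([50.0]), prestim_window_s=10.0)
        assert list(states) == [SYNCHRONISED]

    def test_majority_vote(self):
        labels = [SYNCHRONISED] * 100
        for i in (40, 41, 42, 43):
            labels[i] = DESYNCHRONISED  # 4 of the 10 pre-stim windows
        seg = self._seg(labels)
        states = classify_trials(seg, _Trials([50.0]), prestim_window_s=10.0)
        assert list(states) == [SYNCHRONISED]

    def test_majority_tie_takes_window_nearest_onset(self):
        labels = [SYNCHRONISED] * 100
        labels[48] = DESYNCHRONISED
        labels[49] = DESYNCHRONISED
        seg = self._seg(labels)
        states = classify_trials(seg, _Trials([50.0]), prestim_window_s=4.0)
        # windows 46..49: 2 sync vs 2 desync; window 49 is nearest onset
        assert list(states) == [DESYNCHRONISED]

    def test_stimulation_windows_excluded(self):
        # trial 1's stimulation period lies inside trial 2's look-back:
        # its windows must not contribute to trial 2
        labels = [SYNCHRONISED] * 120
        for i in range(50, 67):
            labels[i] = DESYNCHRONISED  # stim-period windows of trial 1
        seg = self._seg(labels)
        states = classify_trials(
            seg, _Trials([50.0, 75.0]), prestim_window_s=10.0,
            exclusion=(0.001, 16.432),
        )
        # trial 2 pre-stim span 65..74 overlaps exclusion 49.999..66.432;
        # windows 65, 66 are excluded so the sync windows 67..74 decide
        assert list(states) == [SYNCHRONISED, SYNCHRONISED]

    def test_empty_prestim_period_rejected(self):
        seg = self._seg([SYNCHRONISED] * 30)
        with pytest.raises(ValueError, match="no usable windows"):
            classify_trials(seg, _Trials([0.5]), prestim_window_s=0.4)

    def test_simulated_trial_recovery(self, trained_model):
        sched = cs.StimSchedule(n_trials=6, iti_s=70.0)
        cfg = SimConfig(duration_s=450.0, n_channels=4, rng_seed=21,
                        stim_schedule=sched)
        rec, truth = simulate_lfp(cfg)
        trials = cs.simulate_stimulus_trials(cfg)
        seg = cs.classify_recording(rec, trained_model)
        states = classify_trials(seg, trials)
        true_states = truth.label_at(trials.onsets)
        agree = np.mean(states.astype(str) == true_states.astype(str))
        assert agree >= 0.8
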