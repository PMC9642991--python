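import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgecode.classify import (
    NeuronSignals,
    classify_within_detailed,
    confusion_matrix,
    delta_theta_pairs,
    fit_population_speed_function,
    intensity_classify_across,
    intensity_classify_within,
    pairwise_accuracy,
    pearson_rows,
    profile_classify_across,
    profile_classify_within,
    shuffle_labels,
)

ORIENTS = (-10.0, -5.0, 5.0, 10.0)
SPEEDS8 = (15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0, 180.0)


def scalar_signals(data, speeds=None, ntype="FA-1"):
    speeds = tuple(data) if speeds is None else speeds
    return NeuronSignals("n1", ntype, ORIENTS, tuple(sorted(speeds)), data, "intensity-peak")


def profile_sig(data, ntype="FA-1"):
    return NeuronSignals("n1", ntype, ORIENTS, tuple(sorted(data)), data, "profile-spatial")


class TestPearson:
    def test_zero_variance_rows_give_zero(self):
        a = np.vstack([np.ones(10), np.arange(10.0)])
        c = pearson_rows(a)
        assert c[0, 0] == 0.0 and c[0, 1] == 0.0 and c[1, 1] == pytest.approx(1.0)

    def test_matches_numpy_corrcoef(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(6, 30))
        assert np.allclose(pearson_rows(a), np.corrcoef(a), atol=1e-12)


class TestWithinSpeed:
    def test_perfectly_separated_intensities(self):
        v = np.array([[10.0] * 15, [20.0] * 15, [30.0] * 15, [40.0] * 15])
        r = intensity_classify_within(scalar_signals({30.0: v}), 30.0)
        assert r.accuracy == 1.0 and r.n_decisions == 60 and r.chance == 0.25

    def test_all_identical_values_tie_to_incorrect(self):
        v = np.full((4, 15), 7.0)
        r = intensity_classify_within(scalar_signals({30.0: v}), 30.0)
        assert r.accuracy == 0.0

    def test_iid_null_is_at_chance(self):
        rng = np.random.default_rng(1)
        accs = [
            intensity_classify_within(
                scalar_signals({30.0: rng.normal(size=(4, 15))}), 30.0
            ).accuracy
            for _ in range(3000)
        ]
        m, se = np.mean(accs), np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(m - 0.25) < 3 * se

    def test_separable_profile_templates(self):
        rng = np.random.default_rng(2)
        templates = rng.normal(size=(4, 1, 50))
        p = np.repeat(templates, 15, axis=1) + 1e-3 * rng.normal(size=(4, 15, 50))
        r = profile_classify_within(profile_sig({30.0: p}), 30.0)
        assert r.accuracy == 1.0

    def test_all_zero_profiles_score_zero(self):
        p = np.zeros((4, 15, 50))
        r = profile_classify_within(profile_sig({30.0: p}), 30.0)
        assert r.accuracy == 0.0

    def test_profile_null_is_at_chance(self):
        rng = np.random.default_rng(3)
        accs = [
            profile_classify_within(
                profile_sig({30.0: rng.normal(size=(4, 15, 30))}), 30.0
            ).accuracy
            for _ in range(400)
        ]
        m, se = np.mean(accs), np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(m - 0.25) < 3 * se

    def test_missing_speed_is_an_error(self):
        v = np.zeros((4, 15))
        with pytest.raises(KeyError):
            intensity_classify_within(scalar_signals({30.0: v}), 60.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_profile_decision_scale_offset_invariant(self, a, b):
        rng = np.random.default_rng(4)
        p = rng.normal(size=(4, 15, 40))
        r1 = profile_classify_within(profile_sig({30.0: p}), 30.0)
        r2 = profile_classify_within(profile_sig({30.0: a * p + b}), 30.0)
        assert r1.accuracy == r2.accuracy


class TestHoldOutDiscipline:
    def test_detailed_classifier_matches_vectorized(self, mini_trials):
        from edgecode.classify import intensity_signals, profile_signals

        trials = next(iter(mini_trials.values()))
        sig_i = intensity_signals(trials, "mean")
        sig_p = profile_signals(trials, "spatial")
        v = sig_i.speeds[0]
        acc_i, det_i = classify_within_detailed(sig_i, v)
        acc_p, det_p = classify_within_detailed(sig_p, v)
        assert acc_i == pytest.approx(intensity_classify_within(sig_i, v).accuracy)
        assert acc_p == pytest.approx(profile_classify_within(sig_p, v).accuracy)

    def test_no_reference_contains_its_own_trial(self, mini_trials):
        from edgecode.classify import intensity_signals

        trials = next(iter(mini_trials.values()))
        sig = intensity_signals(trials, "peak")
        _, decisions = classify_within_detailed(sig, sig.speeds[0])
        for d in decisions:
            for refs in d["references"].values():
                assert d["trial"] not in refs
                assert len(refs) == 14


class TestAcrossSpeed:
    def test_speed_invariant_separated_intensities(self):
        data = {v: np.array([[10.0] * 15, [20.0] * 15, [30.0] * 15, [40.0] * 15]) for v in SPEEDS8}
        r = intensity_classify_across(scalar_signals(data), 30.0)
        assert r.accuracy == 1.0
        assert r.n_decisions == 60 * 7

    def test_pure_speed_coding_is_chance_with_and_without_normalization(self):
        rng = np.random.default_rng(5)
        accs, accs_n = [], []
        for _ in range(200):
            data = {v: v * (1.0 + 0.05 * rng.normal(size=(4, 15))) for v in SPEEDS8}
            sig = scalar_signals(data)
            feats = pd.DataFrame(
                [
                    {"type": "FA-1", "speed": v, "peak_hz": x}
                    for v, arr in data.items()
                    for x in arr.ravel()
                ]
            )
            fits = fit_population_speed_function(feats, "peak")
            accs.append(intensity_classify_across(sig, 30.0).accuracy)
            accs_n.append(intensity_classify_across(sig, 30.0, fits).accuracy)
        for vals in (accs, accs_n):
            m, se = np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))
            # unnormalized decisions collapse to "nearest reference wins for
            # everyone", which is *exactly* chance (zero variance)
            assert abs(m - 0.25) <= 3 * se + 1e-12

    def test_normalization_rescues_multiplicative_orientation_code(self):
        s = np.array([0.5, 1.0, 1.5, 2.0])
        data = {v: np.tile((s * v)[:, None], (1, 15)) for v in SPEEDS8}
        sig = scalar_signals(data)
        feats = pd.DataFrame(
            [
                {"type": "FA-1", "speed": v, "peak_hz": x}
                for v, arr in data.items()
                for x in arr.ravel()
            ]
        )
        fits = fit_population_speed_function(feats, "peak")
        plain = intensity_classify_across(sig, 15.0).accuracy
        normalized = intensity_classify_across(sig, 15.0, fits).accuracy
        assert normalized == 1.0
        assert plain < 0.6  # distant speeds misclassify without normalization

    def test_single_speed_is_an_error(self):
        data = {30.0: np.zeros((4, 15, 10))}
        with pytest.raises(ValueError):
            profile_classify_across(profile_sig(data), 30.0)

    def test_label_shuffle_restores_chance(self, mini_trials):
        from edgecode.classify import profile_signals

        rng = np.random.default_rng(6)
        accs = []
        for trials in mini_trials.values():
            (sig,) = shuffle_labels([profile_signals(trials, "spatial")], rng)
            for v in sig.speeds:
                accs.append(profile_classify_across(sig, v).accuracy)
        m, se = np.mean(accs), np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(m - 0.25) < 4 * se


class TestSpeedFit:
    def test_exact_linear_recovery(self):
        df = pd.DataFrame(
            [
                {"type": "FA-1", "speed": v, "mean_hz": 2.0 * v + 5.0}
                for v in SPEEDS8
                for _ in range(3)
            ]
        )
        fit = fit_population_speed_function(df, "mean")["FA-1"]
        assert fit.slope == pytest.approx(2.0, rel=1e-9)
        assert fit.intercept == pytest.approx(5.0, rel=1e-9)

    def test_constant_means_zero_slope(self):
        df = pd.DataFrame(
            [{"type": "SA-1", "speed": v, "peak_hz": 40.0} for v in (15.0, 60.0, 180.0)]
        )
        fit = fit_population_speed_function(df, "peak")["SA-1"]
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_ols(self):
        df = pd.DataFrame(
            [
                {"type": "FA-1", "speed": 15.0, "mean_hz": 20.0},
                {"type": "FA-1", "speed": 30.0, "mean_hz": 30.0},
                {"type": "FA-1", "speed": 60.0, "mean_hz": 50.0},
            ]
        )
        fit = fit_population_speed_function(df, "mean")["FA-1"]
        assert fit.slope == pytest.approx(2.0 / 3.0, rel=1e-9)
        assert fit.intercept == pytest.approx(10.0, rel=1e-9)

    def test_single_speed_is_singular(self):
        df = pd.DataFrame([{"type": "FA-1", "speed": 30.0, "mean_hz": 10.0}])
        with pytest.raises(ValueError):
            fit_population_speed_function(df, "mean")


class TestPairwise:
    def test_pair_structure_matches_design(self):
        pairs = delta_theta_pairs(ORIENTS)
        assert pairs[20.0] == [(-10.0, 10.0)]  # exactly one pair at 20 deg
        assert len(pairs[5.0]) == 2 and len(pairs[15.0]) == 2 and len(pairs[10.0]) == 1

    def test_perfectly_separable_pair(self):
        rng = np.random.default_rng(7)
        templates = rng.normal(size=(4, 1, 50))
        data = {
            v: np.repeat(templates, 15, axis=1) + 1e-4 * rng.normal(size=(4, 15, 50))
            for v in (20.0, 60.0)
        }
        r = pairwise_accuracy(profile_sig(data), 20.0)
        assert r.accuracy == 1.0 and r.chance == 0.5

    def test_unknown_delta_theta_rejected(self):
        data = {v: np.zeros((4, 15, 10)) for v in (20.0, 60.0)}
        with pytest.raises(ValueError):
            pairwise_accuracy(profile_sig(data), 7.5)


class TestConfusionMatrix:
    def test_identity_pattern_and_block_normalization(self):
        rng = np.random.default_rng(8)
        templates = rng.normal(size=(4, 1, 60))
        data = {
            v: np.repeat(templates, 15, axis=1) + 1e-4 * rng.normal(size=(4, 15, 60))
            for v in (20.0, 60.0, 120.0)
        }
        mat, labels = confusion_matrix([profile_sig(data)])
        assert mat.shape == (12, 12) and len(labels) == 12
        blocks = mat.reshape(3, 4, 3, 4).sum(axis=3)
        assert np.allclose(blocks, 1.0)
        assert np.allclose(np.diag(mat), 1.0)  # speed-invariant templates
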