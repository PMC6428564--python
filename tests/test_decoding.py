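import numpy as np
import pytest
from scipy import stats

from stcorr.decoding import (
    decode_session,
    detrend_by_period_mean,
    lda_decode,
    paired_rate_comparison,
    select_neurons,
    split_by_scheme,
    trial_shuffle,
    tuning_curve_pca,
)
from stcorr.estimator import short_term_correlation
from stcorr.session import RunConfig, select_stimulus, to_rates
from stcorr.simulate import (
    SessionSpec,
    TrendSpec,
    circular_gaussian_tuning,
    simulate_session,
)


@pytest.fixture(scope="module")
def rate_table(reference_session):
    return to_rates(reference_session)


class TestSplitByScheme:
    def test_former_latter_disjoint_halves(self, rate_table):
        train, test = split_by_scheme(rate_table, "former_latter")
        assert not np.any(train & test)
        assert train.sum() == test.sum() == 320
        # former trials precede latter trials within every stimulus
        for s in range(16):
            sel = rate_table.stimulus == s
            assert rate_table.trial_index[train & sel].max() < \
                rate_table.trial_index[test & sel].min()

    def test_even_odd_counts(self, rate_table):
        train, test = split_by_scheme(rate_table, "even_odd")
        for s in range(16):
            sel = rate_table.stimulus == s
            assert (train & sel).sum() == 20
            assert (test & sel).sum() == 20
        # 1st occurrence (odd-numbered) is a test trial
        first = np.flatnonzero(rate_table.stimulus == 0)[0]
        assert test[first] and not train[first]

    def test_unknown_scheme_rejected(self, rate_table):
        with pytest.raises(ValueError):
            split_by_scheme(rate_table, "bogus")


class TestDetrend:
    def test_centers_each_period(self, rng):
        a = rng.normal(5, 1, size=(30, 4))
        b = rng.normal(9, 1, size=(30, 4))
        da, db = detrend_by_period_mean(a, b)
        np.testing.assert_allclose(da.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(db.mean(axis=0), 0, atol=1e-12)

    def test_idempotent(self, rng):
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        once = detrend_by_period_mean(a, b)
        twice = detrend_by_period_mean(*once)
        np.testing.assert_allclose(once[0], twice[0])
        np.testing.assert_allclose(once[1], twice[1])


class TestLDA:
    def test_separated_point_classes(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 10])
        y = np.repeat([0, 1], 10)
        res = lda_decode(X + 0.01 * np.arange(20)[:, None], y, X, y, ridge=1e-6)
        assert res.success_rate == 1.0

    def test_shuffled_labels_decode_at_chance(self, rate_table, rng):
        y = rng.permutation(rate_table.stimulus)
        train = np.arange(rate_table.n_trials) % 2 == 0
        res = lda_decode(
            rate_table.rates[train], y[train],
            rate_table.rates[~train], y[~train],
        )
        # binomial 3-sigma band around 1/16
        n = res.n_test_trials
        assert abs(res.success_rate - 1 / 16) < 3 * np.sqrt(0.0625 * 0.9375 / n)

    def test_strong_tuning_beats_chance_and_grows_with_neurons(self):
        rates = {}
        for m in (2, 8):
            sess = simulate_session(
                SessionSpec(tuning=circular_gaussian_tuning(m, seed=21)), seed=31
            )
            rates[m] = decode_session(to_rates(sess), "even_odd").success_rate
        assert rates[2] > 1 / 16
        assert rates[8] > rates[2]

    def test_singular_covariance_instructs_ridge(self, rng):
        # more features than training rows per class -> singular pooled cov
        X = rng.standard_normal((8, 30))
        y = np.repeat([0, 1], 4)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            lda_decode(X, y, X, y, ridge=0.0)


@pytest.fixture(scope="module")
def drifting_sessions():
    n = 640
    out = []
    for s in range(8):
        drift = [
            TrendSpec("stepwise", n, {"change_points": [n // 2], "levels": [0.0, 6.0]})
            for _ in range(6)
        ]
        sess = simulate_session(
            SessionSpec(tuning=circular_gaussian_tuning(6, seed=s), drift=drift),
            seed=50 + s,
        )
        out.append(to_rates(sess))
    return out


class TestSchemesUnderDrift:
    def test_drift_harms_generalization_and_detrending_recovers(
        self, drifting_sessions
    ):
        ff = [decode_session(r, "former_former").success_rate for r in drifting_sessions]
        fl = [decode_session(r, "former_latter").success_rate for r in drifting_sessions]
        fld = [
            decode_session(r, "former_latter_detrended").success_rate
            for r in drifting_sessions
        ]
        cmp_fl = paired_rate_comparison(ff, fl)
        assert cmp_fl["mean_diff"] > 0 and cmp_fl["p_value"] < 0.05
        assert abs(np.mean(fld) - np.mean(ff)) < 0.08

    def test_even_odd_robust_to_between_half_drift(self, drifting_sessions):
        eo = [decode_session(r, "even_odd").success_rate for r in drifting_sessions]
        fl = [decode_session(r, "former_latter").success_rate for r in drifting_sessions]
        assert np.mean(eo) > np.mean(fl)


class TestTrialShuffle:
    def test_marginals_preserved_exactly(self, rate_table):
        shuffled = trial_shuffle(rate_table, seed=5)
        for s in range(16):
            a = np.sort(select_stimulus(rate_table, s).rates, axis=0)
            b = np.sort(select_stimulus(shuffled, s).rates, axis=0)
            np.testing.assert_array_equal(a, b)

    def test_planted_correlation_destroyed(self):
        cov = np.eye(2)
        cov[0, 1] = cov[1, 0] = 0.5
        cov *= 9.0
        sess = simulate_session(
            SessionSpec(tuning=np.full((2, 16), 15.0), noise_cov=cov), seed=77
        )
        rates = to_rates(sess)
        shuffled = trial_shuffle(rates, seed=3)
        before, after = [], []
        for s in range(16):
            sub = select_stimulus(rates, s)
            before.append(short_term_correlation(sub.rates[:, 0], sub.rates[:, 1]))
            sub2 = select_stimulus(shuffled, s)
            after.append(short_term_correlation(sub2.rates[:, 0], sub2.rates[:, 1]))
        assert np.mean(before) > 0.3
        assert abs(np.mean(after)) < 0.15

    def test_seed_determinism(self, rate_table):
        a = trial_shuffle(rate_table, seed=9)
        b = trial_shuffle(rate_table, seed=9)
        np.testing.assert_array_equal(a.rates, b.rates)


class TestSelectNeurons:
    def test_stationary_session_keeps_all(self, reference_session):
        cfg = RunConfig(seed=0, monte_carlo_reps=10_000)
        keep = select_neurons(reference_session, "stationary", cfg)
        assert len(keep) >= 7  # 8 neurons at level 0.01

    def test_drifting_neuron_excluded(self):
        n = 640
        drift = [TrendSpec("constant", n)] * 3 + [
            TrendSpec("linear", n, {"slope": 0.05})
        ]
        sess = simulate_session(
            SessionSpec(tuning=circular_gaussian_tuning(4, seed=2), drift=drift),
            seed=19,
        )
        cfg = RunConfig(seed=0, monte_carlo_reps=10_000)
        keep = select_neurons(sess, "stationary", cfg)
        assert "n003" not in keep

    def test_correlated_pair_excluded_by_short_term_criterion(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = 0.7
        cov *= 4.0
        sess = simulate_session(
            SessionSpec(tuning=circular_gaussian_tuning(4, seed=3), noise_cov=cov),
            seed=23,
        )
        cfg = RunConfig(seed=0, monte_carlo_reps=20_000)
        keep = select_neurons(sess, "no_short_term_pair", cfg)
        assert "n000" not in keep and "n001" not in keep
        assert "n002" in keep and "n003" in keep


class TestTuningCurvePCA:
    def test_identical_halves_coincide(self):
        sess = simulate_session(
            SessionSpec(tuning=circular_gaussian_tuning(5, seed=4)), seed=41
        )
        rates = to_rates(sess)
        former, latter = tuning_curve_pca(rates)[:2]
        # stationary session: halves differ only by trial noise, so each
        # neuron's two points nearly coincide relative to the spread of
        # tuning curves across neurons
        pairwise = np.linalg.norm(former - latter, axis=1).mean()
        across = np.linalg.norm(former - former.mean(axis=0), axis=1).mean()
        assert pairwise < across

    def test_additive_offset_displaces_along_common_direction(self):
        n = 640
        drift = [
            TrendSpec("stepwise", n, {"change_points": [n // 2], "levels": [0.0, 5.0]})
            for _ in range(5)
        ]
        sess = simulate_session(
            SessionSpec(tuning=circular_gaussian_tuning(5, seed=4), drift=drift),
            seed=43,
        )
        former, latter = tuning_curve_pca(to_rates(sess))[:2]
        disp = latter - former
        # displacement vectors share a dominant direction
        u, s, _ = np.linalg.svd(disp - disp.mean(axis=0), full_matrices=False)
        mean_shift = np.linalg.norm(disp.mean(axis=0))
        assert mean_shift > 2.0

    def test_components_orthonormal(self, rate_table):
        _, _, components = tuning_curve_pca(rate_table)
        np.testing.assert_allclose(components @ components.T, np.eye(2), atol=1e-10)


class TestPairedComparison:
    def test_identical_inputs_give_null_result(self):
        out = paired_rate_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert out["t"] == 0.0 and out["p_value"] == 1.0

    def test_constant_offset_is_significant(self, rng):
        a = 0.6 + 0.001 * rng.standard_normal(10)
        out = paired_rate_comparison(a, a - 0.05)
        assert out["p_value"] < 1e-6 and out["mean_diff"] == pytest.approx(0.05, abs=1e-3)

    def test_antisymmetry(self, rng):
        a = rng.uniform(0.4, 0.8, size=8)
        b = rng.uniform(0.4, 0.8, size=8)
        assert paired_rate_comparison(a, b)["t"] == pytest.approx(
            -paired_rate_comparison(b, a)["t"]
        )
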