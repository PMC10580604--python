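"""Survival evaluation: strict concordance index vs. all-pairs oracle,
Kaplan-Meier, log-rank, maxstat cutpoints vs. exhaustive scan, feature
merging and the six cross-validated survival models."""

import numpy as np
import pandas as pd
import pytest

from histoarea import (
    MODEL_NAMES,
    concordance_index,
    cross_validate,
    discretize,
    fit_survival_model,
    kaplan_meier,
    logrank_test,
    maxstat_cutoff,
    merge_features,
)
from oracles import cindex_pairs


def frame(times, events, risks=None):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "time": times,
            "event": events,
        }
    )


class TestConcordanceIndex:
    def test_perfect_prediction(self):
        rec = frame([1, 2, 3], [1, 1, 1])
        assert concordance_index(rec, [3, 2, 1]) == 1.0

    def test_fully_discordant(self):
        rec = frame([1, 2, 3], [1, 1, 1])
        assert concordance_index(rec, [1, 2, 3]) == 0.0

    def test_hand_enumerated_partial_order(self):
        rec = frame([1, 2, 3, 4], [1, 1, 1, 1])
        # comparable pairs: (1,2),(1,3),(1,4),(2,3),(2,4),(3,4);
        # risks (4,3,1,2): concordant all but (3,4) -> 5/6
        assert concordance_index(rec, [4, 3, 1, 2]) == pytest.approx(5 / 6)

    def test_matches_all_pairs_oracle_with_censoring(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 30))
            t = rng.exponential(size=n) + 0.01
            if rng.random() < 0.4:
                t = np.round(t, 1) + 0.05
            e = (rng.random(n) < 0.7).astype(int)
            r = np.round(rng.normal(size=n), 1)  # rounded: provokes risk ties
            rec = frame(t, e)
            for tie_credit in (False, True):
                try:
                    expected = cindex_pairs(t, e, r, tie_credit)
                except ZeroDivisionError:
                    with pytest.raises(ValueError):
                        concordance_index(rec, r, tie_credit)
                    continue
                assert concordance_index(rec, r, tie_credit) == pytest.approx(expected)

    def test_harrell_variant_matches_sksurv(self, rng):
        from sksurv.metrics import concordance_index_censored

        for _ in range(20):
            n = 25
            t = rng.exponential(size=n) + 0.01
            e = (rng.random(n) < 0.7).astype(int)
            if not e.any():
                e[0] = 1
            r = rng.normal(size=n)
            ours = concordance_index(frame(t, e), r, tie_credit=True)
            ref = concordance_index_censored(e.astype(bool), t, r)[0]
            assert ours == pytest.approx(ref)

    def test_risk_reversal_complements_on_uncensored(self, rng):
        t = rng.exponential(size=15) + 0.01
        r = rng.normal(size=15)
        rec = frame(t, np.ones(15, int))
        assert concordance_index(rec, r) + concordance_index(rec, -r) == pytest.approx(1.0)

    def test_no_comparable_pair_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(frame([1.0], [1]), [0.0])


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = kaplan_meier(frame([1, 2, 3], [0, 0, 0]))
        assert (km.survival == 1.0).all()

    def test_two_event_product_limit(self):
        km = kaplan_meier(frame([1, 2], [1, 1]))
        assert km.survival.tolist() == [0.5, 0.0]

    def test_duplicating_records_leaves_curve_unchanged(self, rng):
        t = rng.exponential(size=12) + 0.01
        e = (rng.random(12) < 0.6).astype(int)
        km1 = kaplan_meier(frame(t, e))
        km2 = kaplan_meier(frame(np.r_[t, t], np.r_[e, e]))
        np.testing.assert_allclose(km1.survival, km2.survival)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        t = rng.exponential(size=40) + 0.01
        e = (rng.random(40) < 0.7).astype(int)
        km = kaplan_meier(frame(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km.time).to_numpy()
        np.testing.assert_allclose(km.survival, ref, atol=1e-12)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4.0] * 2
        e = [1, 1, 0, 1] * 2
        g = [0] * 4 + [1] * 4
        chi2, p = logrank_test(g, frame(t, e))
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self, rng):
        n = 100
        t = np.r_[rng.exponential(1.0, n), rng.exponential(5.0, n)] + 1e-3
        e = np.ones(2 * n, int)
        g = np.r_[np.zeros(n), np.ones(n)]
        chi2, p = logrank_test(g, frame(t, e))
        assert p < 0.01

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        t = rng.exponential(size=60) + 0.01
        e = (rng.random(60) < 0.7).astype(int)
        g = (rng.random(60) < 0.5).astype(int)
        chi2, p = logrank_test(g, frame(t, e))
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic)
        assert p == pytest.approx(ref.p_value)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 1, 1], frame([1, 2, 3], [1, 1, 1]))


def maxstat_oracle(x, t, e, min_prop=0.1):
    """Exhaustive scan using lifelines' log-rank statistic per cutoff."""
    from lifelines.statistics import logrank_test as ll_logrank

    n = len(x)
    min_size = int(np.ceil(min_prop * n))
    best = (None, -1.0)
    for c in np.unique(x):
        hi = x > c
        if hi.sum() < min_size or (~hi).sum() < min_size:
            continue
        res = ll_logrank(t[~hi], t[hi], e[~hi], e[hi])
        z = np.sqrt(res.test_statistic)
        if z > best[1]:
            best = (c, z)
    return best


class TestMaxstat:
    def test_constant_feature_rejected(self):
        rec = frame([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="constant"):
            maxstat_cutoff([5, 5, 5, 5], rec)

    def test_no_admissible_cutoff_rejected(self):
        rec = frame(np.arange(1, 21, dtype=float), np.ones(20, int))
        x = np.r_[np.zeros(19), [1.0]]  # split would leave 1 patient (5%)
        with pytest.raises(ValueError, match="admissible"):
            maxstat_cutoff(x, rec, min_prop=0.1)

    def test_cutoff_separates_two_survival_clusters(self, rng):
        # survival is a deterministic function of cluster membership, so the
        # maximal log-rank split must fall between the feature clusters
        n = 40
        x = np.r_[rng.normal(0, 0.3, n // 2), rng.normal(5, 0.3, n // 2)]
        t = np.r_[np.linspace(10, 20, n // 2), np.linspace(0.1, 1, n // 2)]
        rec = frame(t, np.ones(n, int))
        res = maxstat_cutoff(x, rec, n_permutations=0)
        assert x[:20].max() <= res.cutoff < x[20:].min()
        assert res.n_low == res.n_high == 20

    def test_matches_exhaustive_scan_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 45))
            x = np.round(rng.normal(size=n), 1)
            t = rng.exponential(size=n) + 0.01
            e = (rng.random(n) < 0.8).astype(int)
            if e.sum() == 0:
                e[0] = 1
            if len(np.unique(x)) < 2:
                continue
            rec = frame(t, e)
            try:
                res = maxstat_cutoff(x, rec, n_permutations=0)
            except ValueError:
                assert maxstat_oracle(x, t, e)[0] is None
                continue
            oc, oz = maxstat_oracle(x, t, e)
            assert res.cutoff == pytest.approx(oc)
            assert res.statistic == pytest.approx(oz, rel=1e-9)

    def test_permutation_p_small_for_strong_signal(self, rng):
        n = 60
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t = np.r_[rng.exponential(5.0, n // 2), rng.exponential(0.3, n // 2)] + 1e-3
        rec = frame(t, np.ones(n, int))
        res = maxstat_cutoff(x, rec, n_permutations=200, seed=1)
        assert res.p_value < 0.05


class TestDiscretizeAndMerge:
    def test_strictly_greater_than(self):
        assert discretize([2.0], 2.0)[0] == 0
        assert discretize([2.0 + 1e-9], 2.0)[0] == 1

    def test_monotone(self, rng):
        v = np.sort(rng.normal(size=20))
        d = discretize(v, 0.0)
        assert (np.diff(d) >= 0).all()

    def test_merge_widths_and_slicing(self, rng):
        h = rng.normal(size=128)
        a = rng.integers(0, 2, size=5).astype(float)
        out = merge_features(h, a)
        assert out.shape == (133,)
        np.testing.assert_array_equal(out[:128], h)
        np.testing.assert_array_equal(out[128:], a)
        zero = merge_features(np.zeros(128), np.zeros(5))
        assert not zero.any()

    def test_merge_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            merge_features(np.zeros(127), np.zeros(5))
        with pytest.raises(ValueError):
            merge_features(np.zeros(128), np.zeros(4))


def _cohort(n, betas=0.0, seed=0, censor=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    lp = betas * X[:, 0]
    t = rng.exponential(1 / np.exp(lp)) + 1e-4
    e = np.ones(n, int)
    if censor > 0:
        c = rng.exponential(np.mean(t) / censor, size=n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
    return X, frame(t, e)


class TestSurvivalModels:
    def test_all_six_fit_and_predict(self):
        X, rec = _cohort(60, betas=1.0, seed=1)
        for name in MODEL_NAMES:
            model = fit_survival_model(name, X, rec, seed=0)
            risks = model.predict_risk(X)
            assert np.isfinite(risks).all()
            assert risks.shape == (60,)

    def test_strong_covariate_gives_high_cindex(self):
        rng = np.random.default_rng(2)
        n = 150
        lh = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(1.5 * lh)) + 1e-4
        rec = frame(t, np.ones(n, int))
        results = cross_validate(lh[:, None], rec, model_names=["ridge_cox"], seed=0)
        assert results[0].mean > 0.7

    def test_pure_noise_cindex_near_half(self):
        X, rec = _cohort(150, betas=0.0, seed=3)
        results = cross_validate(X, rec, model_names=["ridge_cox", "rsf"], seed=0)
        for res in results:
            assert 0.4 <= res.mean <= 0.6

    def test_unknown_model_rejected(self):
        X, rec = _cohort(10)
        with pytest.raises(ValueError, match="unknown"):
            fit_survival_model("deep_cox", X, rec)

    def test_degenerate_input_rejected(self):
        X, rec = _cohort(10)
        rec2 = rec.assign(event=0)
        with pytest.raises(ValueError, match="degenerate"):
            fit_survival_model("ridge_cox", X, rec2)


class TestCrossValidate:
    def test_folds_partition_patients(self):
        X, rec = _cohort(100, betas=0.5, seed=4)
        from histoarea.survival_eval import _stratified_folds

        folds = _stratified_folds(rec.event.to_numpy(), 5, seed=0)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(100))
        assert all(len(f) == 20 for f in folds)

    def test_same_seed_same_results(self):
        X, rec = _cohort(80, betas=0.8, seed=5, censor=0.2)
        a = cross_validate(X, rec, model_names=["ridge_cox"], seed=7)
        b = cross_validate(X, rec, model_names=["ridge_cox"], seed=7)
        assert a[0].fold_cindices == b[0].fold_cindices

    def test_signal_beats_noise_paired(self):
        Xs, rs = _cohort(100, betas=1.5, seed=6)
        Xn, rn = _cohort(100, betas=0.0, seed=6)
        for name in ("ridge_cox", "rsf"):
            cs = cross_validate(Xs, rs, model_names=[name], seed=1)[0].mean
            cn = cross_validate(Xn, rn, model_names=[name], seed=1)[0].mean
            assert cs > cn

    def test_training_cutoffs_ignore_test_fold(self):
        # planting an extreme outlier in a patient's feature must not change
        # the training cutoff of the one fold that holds that patient out
        rng = np.random.default_rng(8)
        n = 50
        x = rng.normal(size=(n, 1))
        t = rng.exponential(1 / np.exp(x[:, 0])) + 1e-4
        rec = frame(t, np.ones(n, int))
        _, base_details = cross_validate(
            x, rec, model_names=["ridge_cox"], seed=0, area_cols=[0],
            return_details=True,
        )
        outlier = int(base_details[0]["test_idx"][0])
        x2 = x.copy()
        x2[outlier, 0] = 1e6
        _, pert_details = cross_validate(
            x2, rec, model_names=["ridge_cox"], seed=0, area_cols=[0],
            return_details=True,
        )
        assert base_details[0]["cutoffs"] == pert_details[0]["cutoffs"]
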