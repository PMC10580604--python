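"""Deep Cox feature extraction: partial-likelihood loss and gradient,
extractor training, weighted aggregation and concatenation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from histoarea import (
    DeepConvSurvConfig,
    SyntheticCohortConfig,
    TissueClass,
    aggregate_tissue,
    concat_histo,
    cox_partial_nll,
    cox_partial_nll_grad,
    enumerate_tissue_subsets,
    generate_cohort,
    generate_patch_images,
    tissue_combination_search,
    train_tissue_extractor,
)
from oracles import cox_nll_direct

TISSUES = (TissueClass.TUM, TissueClass.LYM, TissueClass.STR, TissueClass.MUC)


class TestCoxPartialNLL:
    def test_single_event_patient_has_zero_loss(self):
        assert cox_partial_nll([1.7], [2.0], [1]) == pytest.approx(0.0)

    def test_two_equal_risks_both_events(self):
        # only the earlier event has a non-trivial risk set: loss = log(2)/2
        assert cox_partial_nll([0.3, 0.3], [1.0, 2.0], [1, 1]) == pytest.approx(
            np.log(2) / 2
        )

    def test_matches_direct_double_loop(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 20))
            r = rng.normal(size=n)
            t = rng.exponential(size=n) + 0.01
            e = rng.random(n) < 0.7
            if not e.any():
                e[0] = True
            if rng.random() < 0.3:
                t = np.round(t, 1) + 0.05  # force ties
            assert cox_partial_nll(r, t, e) == pytest.approx(
                cox_nll_direct(r, t, e), rel=1e-12
            )

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            cox_partial_nll([1.0, 2.0], [1.0, 2.0], [0, 0])

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        for _ in range(100):
            n = int(rng.integers(2, 12))
            r = rng.normal(size=n)
            t = rng.exponential(size=n) + 0.01
            if rng.random() < 0.3:
                t = np.round(t, 1) + 0.05
            e = rng.random(n) < 0.7
            if not e.any():
                e[int(rng.integers(n))] = True
            g = cox_partial_nll_grad(r, t, e)
            for k in range(n):
                rp, rm = r.copy(), r.copy()
                rp[k] += h
                rm[k] -= h
                fd = (cox_partial_nll(rp, t, e) - cox_partial_nll(rm, t, e)) / (2 * h)
                assert abs(g[k] - fd) < 1e-5


def _toy_training_set(n_patients=12, patches_per_patient=4, edge=16, seed=0):
    rng = np.random.default_rng(seed)
    surv = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n_patients)],
            "time": rng.exponential(1.0, n_patients) + 0.05,
            "event": rng.random(n_patients) < 0.8,
        }
    ).astype({"event": int})
    patches, pids = [], []
    for i in range(n_patients):
        patches.append(rng.normal(0.5, 0.15, (patches_per_patient, edge, edge, 3)))
        pids.extend([f"P{i}"] * patches_per_patient)
    return np.concatenate(patches), pids, surv


class TestTrainExtractor:
    CFG = DeepConvSurvConfig(input_edge=16, conv_channels=(4, 8), epochs=10,
                             learning_rate=1e-3, seed=1)

    def test_training_reduces_loss(self):
        patches, pids, surv = _toy_training_set()
        net = train_tissue_extractor(patches, pids, surv, self.CFG)
        # re-train to inspect the loss history directly
        from histoarea._convnet import ConvSurvNet

        net2 = ConvSurvNet(16, (4, 8), 32, lr=1e-3, seed=1)
        t = surv.set_index("patient_id").loc[pids, "time"].to_numpy()
        e = surv.set_index("patient_id").loc[pids, "event"].to_numpy()
        hist = net2.fit(patches, t, e, epochs=10)
        assert hist[-1] < hist[0]
        np.testing.assert_allclose(net.features(patches), net2.features(patches))

    def test_seeded_determinism(self):
        patches, pids, surv = _toy_training_set()
        a = train_tissue_extractor(patches, pids, surv, self.CFG)
        b = train_tissue_extractor(patches, pids, surv, self.CFG)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_feature_width_is_32(self):
        patches, pids, surv = _toy_training_set()
        net = train_tissue_extractor(patches, pids, surv, self.CFG)
        assert net.features(patches[:3]).shape == (3, 32)

    def test_all_censored_rejected(self):
        patches, pids, surv = _toy_training_set()
        surv["event"] = 0
        with pytest.raises(ValueError, match="censored"):
            train_tissue_extractor(patches, pids, surv, self.CFG)

    def test_risks_track_texture_encoded_hazard(self):
        # patch brightness encodes the patient's log-hazard; held-out risks
        # should correlate with it after training
        rng = np.random.default_rng(5)
        n, per, edge = 30, 6, 16
        lh = rng.normal(0, 1, n)
        times = rng.exponential(1 / np.exp(lh)) + 1e-3
        surv = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(n)], "time": times, "event": 1}
        )
        patches, pids = [], []
        for i in range(n):
            imgs = generate_patch_images(
                TissueClass.TUM, per, edge, seed=100 + i, brightness_shift=40 * lh[i]
            )
            patches.append(imgs)
            pids.extend([f"P{i}"] * per)
        X = np.concatenate(patches)
        cfg = DeepConvSurvConfig(input_edge=edge, conv_channels=(4, 8), epochs=30,
                                 learning_rate=3e-3, seed=2)
        train_idx = np.arange(0, 20 * per)
        net = train_tissue_extractor(X[train_idx], pids[: 20 * per], surv, cfg)
        held_risk = [net.predict_risk(patches[i]).mean() for i in range(20, 30)]
        rho, _ = spearmanr(held_risk, lh[20:])
        assert rho > 0


class TestAggregation:
    def test_weighted_mean_rule(self):
        feats = np.ones((10, 32))
        out = aggregate_tissue(feats, 10, 40)
        np.testing.assert_allclose(out, np.full(32, 0.25))

    def test_zero_patch_tissue_gives_zero_vector(self):
        np.testing.assert_array_equal(aggregate_tissue(None, 0, 40), np.zeros(32))

    def test_full_weight_identity(self, rng):
        feats = rng.normal(size=(7, 32))
        np.testing.assert_allclose(aggregate_tissue(feats, 7, 7), feats.mean(axis=0))

    def test_permutation_invariance(self, rng):
        feats = rng.normal(size=(9, 32))
        perm = rng.permutation(9)
        np.testing.assert_allclose(
            aggregate_tissue(feats, 9, 20), aggregate_tissue(feats[perm], 9, 20)
        )

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            aggregate_tissue(np.ones((1, 32)), 1, 0)


class TestConcat:
    def test_blocks_recoverable_in_order(self):
        vecs = {t: np.full(32, float(i)) for i, t in enumerate(TISSUES)}
        out = concat_histo(vecs)
        assert out.shape == (128,)
        for i in range(4):
            np.testing.assert_array_equal(out[32 * i : 32 * (i + 1)], np.full(32, i))

    def test_width_mismatch_rejected(self):
        vecs = {t: np.zeros(32) for t in TISSUES}
        vecs[TissueClass.MUC] = np.zeros(16)
        with pytest.raises(ValueError, match="width"):
            concat_histo(vecs)

    def test_missing_tissue_rejected(self):
        vecs = {t: np.zeros(32) for t in TISSUES[:3]}
        with pytest.raises(ValueError, match="missing"):
            concat_histo(vecs)

    def test_zero_vectors_concatenate_to_zero(self):
        out = concat_histo({t: np.zeros(32) for t in TISSUES})
        assert out.shape == (128,) and not out.any()


class TestCombinationSearch:
    def test_enumerates_all_nonempty_subsets(self):
        assert len(enumerate_tissue_subsets()) == 255
        assert len(enumerate_tissue_subsets([TissueClass.TUM, TissueClass.LYM])) == 3

    def test_reduced_search_ranks_signal_tissue_first(self):
        # patient-level features: TUM column carries the log-hazard, LYM is noise
        rng = np.random.default_rng(3)
        n = 60
        lh = rng.normal(size=n)
        surv = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "time": rng.exponential(1 / np.exp(1.5 * lh)) + 1e-4,
                "event": 1,
            }
        )
        feats = {
            TissueClass.TUM: np.tile(lh[:, None], (1, 32)) + rng.normal(0, 0.1, (n, 32)),
            TissueClass.LYM: rng.normal(size=(n, 32)),
        }
        table = tissue_combination_search(
            feats, surv, model_names=["ridge_cox"], cv_seed=0
        )
        assert len(table) == 3
        assert "TUM" in table.iloc[0]["subset"]
        lym_only = table[table.subset == "LYM"]["mean_cindex"].iloc[0]
        assert table.iloc[0]["mean_cindex"] > lym_only
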