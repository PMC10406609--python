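"""Differential analysis: Bayes-factor identities, posterior-expectation FDR,
the exact Wilcoxon oracle, TF-IDF and concordance statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

import scmosaic as sm
from scmosaic.diffexp import posterior_expectation_fdr, tfidf_transform


class TestPosteriorExpectationFDR:
    def test_rejected_set_mean_null_probability_bounded(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        flags = posterior_expectation_fdr(p, 0.05)
        if flags.any():
            assert (1 - p[flags]).mean() <= 0.05
        # flags select the top-p prefix
        if flags.any() and (~flags).any():
            assert p[flags].min() >= p[~flags].max() - 1e-12

    def test_no_rejection_when_all_probabilities_moderate(self):
        p = np.full(50, 0.5)
        assert not posterior_expectation_fdr(p, 0.05).any()


class TestModelDifferential:
    def test_null_identity_group_against_itself(self, small_dataset, small_model):
        ds, _ = small_dataset
        model, _ = small_model
        idx = np.arange(60)
        res = sm.model_differential(model, ds, idx, idx, modality="rna",
                                    n_pairs=4000, mode="vanilla", seed=0)
        p = res.table["prob_de"].to_numpy()
        bf = res.table["bayes_factor"].to_numpy()
        assert np.abs(p - 0.5).max() < 0.06  # Monte-Carlo tolerance
        assert np.abs(bf).max() < 0.3

    def test_group_swap_antisymmetry(self, small_dataset, small_model):
        ds, gt = small_dataset
        model, _ = small_model
        ga = np.where(gt.type_labels == 0)[0]
        gb = np.where(gt.type_labels == 1)[0]
        r1 = sm.model_differential(model, ds, ga, gb, n_pairs=2000,
                                   mode="vanilla", seed=0)
        # swapping groups maps p -> 1-p exactly when the pair stream is
        # mirrored; statistically, BF flips sign
        r2 = sm.model_differential(model, ds, gb, ga, n_pairs=2000,
                                   mode="vanilla", seed=0)
        p1 = r1.table["prob_de"].to_numpy()
        p2 = r2.table["prob_de"].to_numpy()
        assert np.abs((p1 + p2) - 1.0).max() < 0.1
        strong = np.abs(r1.table["bayes_factor"].to_numpy()) > 1
        if strong.any():
            assert (np.sign(r1.table["bayes_factor"].to_numpy()[strong])
                    == -np.sign(r2.table["bayes_factor"].to_numpy()[strong])).all()

    def test_atac_mode_returns_probability_differences(self, small_dataset,
                                                       small_model):
        ds, gt = small_dataset
        model, _ = small_model
        ga = np.where(gt.type_labels == 0)[0]
        gb = np.where(gt.type_labels == 1)[0]
        res = sm.model_differential(model, ds, ga, gb, modality="atac",
                                    n_pairs=1000, mode="vanilla", seed=0)
        t = res.table
        assert len(t) == ds.n_regions
        # effect for ATAC is the mean probability difference, bounded by 1
        assert (t["effect"].abs() <= 1.0).all()
        assert ((t["mean_a"] > 0) & (t["mean_a"] < 1)).all()
        np.testing.assert_allclose(
            t["bayes_factor"],
            np.log(np.clip(t["prob_de"], 1e-3, 1 - 1e-3)
                   / (1 - np.clip(t["prob_de"], 1e-3, 1 - 1e-3))), atol=1e-9)

    def test_empty_group_rejected(self, small_dataset, small_model):
        ds, _ = small_dataset
        model, _ = small_model
        with pytest.raises(ValueError):
            sm.model_differential(model, ds, np.array([], int), np.arange(5))

    def test_small_n_pairs_warns(self, small_dataset, small_model):
        ds, _ = small_dataset
        model, _ = small_model
        with pytest.warns(UserWarning):
            sm.model_differential(model, ds, np.arange(5), np.arange(5, 10),
                                  n_pairs=50, seed=0)


def exact_wilcoxon_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = np.argsort(np.argsort(pooled, kind="stable")) + 1.0
    # midranks for ties
    order = np.argsort(pooled)
    sorted_vals = pooled[order]
    midranks = np.empty_like(ranks)
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        midranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    obs = midranks[:n].sum()
    stats = []
    for comb in itertools.combinations(range(n + m), n):
        stats.append(midranks[list(comb)].sum())
    stats = np.array(stats)
    ex = stats.mean()
    return np.mean(np.abs(stats - ex) >= np.abs(obs - ex) - 1e-12)


class TestWilcoxonOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(3, 8)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(3, 8)).astype(float)
        if np.allclose(np.concatenate([x, y]),
                       np.concatenate([x, y])[0]):
            return
        p_scipy = mannwhitneyu(x, y, alternative="two-sided",
                               method="exact" if len(np.unique(
                                   np.concatenate([x, y]))) == len(x) + len(y)
                               else "asymptotic").pvalue
        p_exact = exact_wilcoxon_p(x, y)
        # exact enumeration vs the implementation's test (scipy); for tied
        # data scipy's normal approximation is used, so allow looser agreement
        assert p_scipy == pytest.approx(p_exact, abs=0.08)

    def test_exact_match_untied_data(self):
        # feature expressed only in group a: maximal rank statistic; compare
        # to the closed-form two-sided probability 2/C(n+m, n)
        x = np.array([5.0, 6.0, 7.0])
        y = np.array([0.1, 0.2, 0.3, 0.4])
        p = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        from math import comb
        assert p == pytest.approx(2 / comb(7, 3))
        assert exact_wilcoxon_p(x, y) == pytest.approx(p)


class TestHeldout:
    def test_identical_groups_zero_effect(self, small_dataset):
        ds, _ = small_dataset
        idx = np.arange(40)
        res = sm.heldout_differential(ds, idx, idx, modality="rna")
        np.testing.assert_allclose(res.table["heldout_effect"], 0.0, atol=1e-12)
        assert not res.table["is_de_heldout"].any()

    def test_zero_variance_feature_p_one(self):
        import scipy.sparse as sp
        counts = np.ones((12, 2), dtype=int)
        counts[:6, 1] = 3
        mask = np.zeros((12, 3), bool)
        mask[:, 0] = True
        filler = np.zeros((12, 1), dtype=int)  # keeps library sizes equal
        filler[6:, 0] = 2
        ds = sm.MultiomicDataset(
            rna_counts=sp.csr_matrix(np.hstack([counts, filler])),
            atac_counts=sp.csr_matrix((12, 0)),
            protein_counts=sp.csr_matrix((12, 0)),
            batch=np.array(["b"] * 12), modality_mask=mask)
        res = sm.heldout_differential(ds, np.arange(6), np.arange(6, 12), "rna")
        # feature 0 identical everywhere after normalization -> p = 1
        assert res.table["pvalue"][0] == 1.0
        assert res.table["pvalue"][1] < 0.05

    def test_tfidf_all_ones_is_constant(self):
        out = tfidf_transform(np.ones((6, 9)))
        assert np.allclose(out, out[0, 0])

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, (60, 30))
        counts[:30, 0] *= 6
        import scipy.sparse as sp
        mask = np.zeros((60, 3), bool)
        mask[:, 0] = True
        ds = sm.MultiomicDataset(
            rna_counts=sp.csr_matrix(counts),
            atac_counts=sp.csr_matrix((60, 0)),
            protein_counts=sp.csr_matrix((60, 0)),
            batch=np.array(["b"] * 60), modality_mask=mask)
        res = sm.heldout_differential(ds, np.arange(30), np.arange(30, 60))
        assert res.table["qvalue"][0] < 0.01
        assert res.table["heldout_effect"][0] > 1.5


class TestConcordance:
    def _fake_results(self, model_hits, held_hits, n):
        import pandas as pd
        rng = np.random.default_rng(0)
        p = np.where(model_hits, 0.99, 0.5)
        bf = np.log(p / (1 - p))
        eff = rng.standard_normal(n)
        mt = pd.DataFrame({"feature": [f"f{i}" for i in range(n)],
                           "prob_de": p, "bayes_factor": bf, "effect": eff})
        ht = pd.DataFrame({"feature": [f"f{i}" for i in range(n)],
                           "qvalue": np.where(held_hits, 0.001, 0.9),
                           "heldout_effect": eff + rng.normal(0, 0.1, n)})
        return sm.DiffResult(mt), sm.DiffResult(ht)

    def test_identical_sets_full_overlap(self):
        n = 100
        hits = np.zeros(n, bool)
        hits[:20] = True
        mres, hres = self._fake_results(hits, hits, n)
        out = sm.concordance(mres, hres, bf_thresholds=(1.0,),
                             fdr_thresholds=(0.05,))
        row = out["curve"].iloc[0]
        assert row["overlap_fraction"] == 1.0
        assert row["fold_enrichment"] == pytest.approx(n / 20)

    def test_independent_random_sets_enrichment_near_one(self):
        n = 400
        rng = np.random.default_rng(3)
        enrich = []
        for _ in range(200):
            a = np.zeros(n, bool)
            b = np.zeros(n, bool)
            a[rng.choice(n, 80, replace=False)] = True
            b[rng.choice(n, 120, replace=False)] = True
            k = (a & b).sum()
            enrich.append(k / (80 * 120 / n))
        assert np.mean(enrich) == pytest.approx(1.0, abs=0.05)
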