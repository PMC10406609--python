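"""Latent-space machinery: encoding, fusion, consistency penalties, decoding
and the ELBO decomposition (including exact masking invariance)."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import integrate
from scipy.stats import norm

import scmosaic as sm
from scmosaic.model import MosaicVAE, _MOD_IDX


def make_model(ds, **kw):
    cfg = sm.ModelConfig(latent_dim=6, n_hidden=16, dropout=0.0, seed=3, **kw)
    return MosaicVAE(cfg, ds.n_genes, ds.n_regions, ds.n_proteins,
                     ds.batch_vocab, ds.gene_names, ds.region_names,
                     ds.protein_names)


class TestEncode:
    def test_single_modality_cell_has_single_posterior(self, small_dataset):
        ds, _ = small_dataset
        rna_only = ds.subset(np.arange(10))
        rna_only.modality_mask[:, 1:] = False
        model = make_model(ds)
        state = model.encode(rna_only)
        # posteriors exist for all encoders, but the mask exposes only RNA,
        # and the fused state equals the RNA posterior exactly
        assert not state.mask[:, 1].any() and not state.mask[:, 2].any()
        np.testing.assert_array_equal(state.fused_mean, state.means["rna"])
        np.testing.assert_array_equal(state.fused_variance,
                                      state.variances["rna"])

    def test_variances_strictly_positive(self, small_dataset):
        ds, _ = small_dataset
        state = make_model(ds).encode(ds)
        for m in state.modalities:
            assert (state.variances[m] > 0).all()

    def test_deterministic(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        s1 = model.encode(ds, np.arange(5))
        s2 = model.encode(ds, np.arange(5))
        for m in s1.modalities:
            np.testing.assert_array_equal(s1.means[m], s2.means[m])

    def test_unknown_batch_rejected(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        bad = ds.subset(np.arange(4))
        bad.batch = np.array(["novelbatch"] * 4)
        bad.batch_vocab = ds.batch_vocab  # vocabulary does not know it
        with pytest.raises(KeyError):
            bad.batch_codes  # noqa: B018


class TestFusion:
    def _state(self, mu_by_mod, var_by_mod, mask):
        return sm.LatentState(means=mu_by_mod, variances=var_by_mod,
                              mask=np.asarray(mask, bool))

    def test_equal_scheme_arithmetic_mean(self):
        st = self._state(
            {"rna": np.array([[1.0, 1.0]]), "atac": np.array([[3.0, 3.0]])},
            {"rna": np.ones((1, 2)), "atac": np.ones((1, 2)) * 3},
            [[True, True, False]])
        st = sm.fuse_latents(st, sm.MixingWeights("equal"))
        np.testing.assert_allclose(st.fused_mean, [[2.0, 2.0]])
        np.testing.assert_allclose(st.fused_variance, [[2.0, 2.0]])

    def test_single_modality_passthrough_any_scheme(self):
        for weights in (sm.MixingWeights("equal"),
                        sm.MixingWeights("global",
                                         global_weights=np.array([0.2, 0.5, 0.3])),
                        sm.MixingWeights("per_cell",
                                         per_cell_weights=np.array([[0.1, 7.0, 0.0]]))):
            st = self._state({"atac": np.array([[5.0, -1.0]])},
                             {"atac": np.array([[0.5, 2.0]])},
                             [[False, True, False]])
            st = sm.fuse_latents(st, weights)
            np.testing.assert_allclose(st.fused_mean, [[5.0, -1.0]])
            np.testing.assert_allclose(st.fused_variance, [[0.5, 2.0]])

    def test_degenerate_per_cell_weight_selects_modality(self):
        st = self._state(
            {"rna": np.array([[1.0, 0.0]]), "atac": np.array([[9.0, 9.0]])},
            {"rna": np.ones((1, 2)), "atac": np.full((1, 2), 4.0)},
            [[True, True, False]])
        w = sm.MixingWeights("per_cell",
                             per_cell_weights=np.array([[0.0, 1.0, 0.0]]))
        st = sm.fuse_latents(st, w)
        np.testing.assert_allclose(st.fused_mean, [[9.0, 9.0]])

    def test_permutation_invariance_and_weight_simplex(self):
        rng = np.random.default_rng(1)
        mus = {m: rng.standard_normal((4, 3)) for m in ("rna", "atac", "protein")}
        vars_ = {m: rng.uniform(0.5, 2, (4, 3)) for m in mus}
        mask = np.ones((4, 3), bool)
        st1 = sm.fuse_latents(self._state(dict(mus), dict(vars_), mask),
                              sm.MixingWeights("equal"))
        # reversed insertion order must not matter
        mus_r = dict(reversed(list(mus.items())))
        vars_r = dict(reversed(list(vars_.items())))
        st2 = sm.fuse_latents(self._state(mus_r, vars_r, mask),
                              sm.MixingWeights("equal"))
        np.testing.assert_allclose(st1.fused_mean, st2.fused_mean)
        np.testing.assert_allclose(st1.weights.sum(axis=1), 1.0)


class TestConsistencyPenalty:
    def _two_mod_state(self, mu_a, var_a, mu_b, var_b):
        n = np.asarray(mu_a).shape[0]
        mask = np.zeros((n, 3), bool)
        mask[:, 0] = mask[:, 1] = True
        return sm.LatentState(
            means={"rna": np.asarray(mu_a, float), "atac": np.asarray(mu_b, float)},
            variances={"rna": np.asarray(var_a, float),
                       "atac": np.asarray(var_b, float)},
            mask=mask)

    def test_identical_posteriors_zero(self):
        mu = np.random.default_rng(0).standard_normal((5, 3))
        var = np.full((5, 3), 1.3)
        st = self._two_mod_state(mu, var, mu.copy(), var.copy())
        np.testing.assert_allclose(sm.consistency_penalty(st, "symmkl"), 0.0)
        mmd = sm.consistency_penalty(st, "mmd", n_samples=128, seed=0)
        assert np.all(mmd < 0.05)  # Monte-Carlo tolerance

    def test_unit_variance_gaussians_closed_form(self):
        # means 0 and m, unit variances: symmKL = sum_d m_d^2
        m = np.array([[0.7, -1.2, 0.4]])
        st = self._two_mod_state(np.zeros((1, 3)), np.ones((1, 3)),
                                 m, np.ones((1, 3)))
        pen = sm.consistency_penalty(st, "symmkl")
        assert pen[0] == pytest.approx(np.sum(m**2), abs=1e-12)

    def test_closed_form_matches_numerical_integration(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            d = rng.integers(1, 4)
            mu_a, mu_b = rng.standard_normal((2, d))
            va, vb = rng.uniform(0.4, 2.0, size=(2, d))
            closed = sm.symm_kl_diag_gaussians(mu_a, va, mu_b, vb)

            total = 0.0
            for j in range(d):  # diagonal Gaussians factorize per dimension
                def kl_integrand(x, m1, s1, m2, s2):
                    p = norm.pdf(x, m1, s1)
                    return p * (norm.logpdf(x, m1, s1) - norm.logpdf(x, m2, s2))
                sa, sb = np.sqrt(va[j]), np.sqrt(vb[j])
                kl_ab, _ = integrate.quad(kl_integrand, -30, 30,
                                          args=(mu_a[j], sa, mu_b[j], sb))
                kl_ba, _ = integrate.quad(kl_integrand, -30, 30,
                                          args=(mu_b[j], sb, mu_a[j], sa))
                total += kl_ab + kl_ba
            assert closed == pytest.approx(total, abs=1e-4)

    def test_three_modalities_sum_over_pairs(self):
        rng = np.random.default_rng(5)
        mus = {m: rng.standard_normal((2, 3)) for m in ("rna", "atac", "protein")}
        vars_ = {m: rng.uniform(0.5, 2, (2, 3)) for m in mus}
        st = sm.LatentState(means=mus, variances=vars_, mask=np.ones((2, 3), bool))
        pen = sm.consistency_penalty(st, "symmkl")
        expected = sum(
            sm.symm_kl_diag_gaussians(mus[a], vars_[a], mus[b], vars_[b])
            for a, b in (("rna", "atac"), ("rna", "protein"), ("atac", "protein")))
        np.testing.assert_allclose(pen, expected)

    def test_single_modality_penalty_zero(self):
        mask = np.zeros((3, 3), bool)
        mask[:, 0] = True
        st = sm.LatentState(means={"rna": np.ones((3, 2))},
                            variances={"rna": np.ones((3, 2))}, mask=mask)
        np.testing.assert_array_equal(sm.consistency_penalty(st), 0.0)


class TestDecode:
    def test_rho_on_simplex_and_bernoulli_in_range(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        rng = np.random.default_rng(0)
        z = rng.standard_normal((7, model.config.latent_dim))
        dec = model.decode(z, np.zeros(7, int))
        np.testing.assert_allclose(dec.rho.sum(axis=1), 1.0, atol=1e-6)
        q = dec.atac_p * dec.atac_r[None, :] * 0.9  # any cell factor < 1
        assert ((q > 0) & (q < 1)).all()
        assert ((dec.protein_pi > 0) & (dec.protein_pi < 1)).all()
        assert (dec.protein_alpha >= 0).all()

    def test_batch_conditioning_changes_output(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        # perturb decoder weights so batch columns are nonzero
        rng = np.random.default_rng(9)
        for dec in model.decoders.values():
            lin = dec.trunk.linears[0]
            lin.weight.data += rng.normal(0, 0.5, lin.weight.data.shape)
        z = np.zeros((3, model.config.latent_dim))
        d0 = model.decode(z, np.zeros(3, int))
        d1 = model.decode(z, np.ones(3, int))
        assert not np.allclose(d0.rho, d1.rho)


class TestELBO:
    def test_component_additivity(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        comps = model.elbo(ds, np.arange(32), kl_weight=0.7)
        total = 0.0
        for k, v in comps.items():
            if k == "total":
                continue
            w = 0.7 if k.startswith("kl_") else 1.0
            if k == "penalty":
                w = model.config.penalty_weight
            if k == "adversarial":
                w = -model.config.adversarial_weight
            total += w * float(v.data)
        assert float(comps["total"].data) == pytest.approx(total, abs=1e-6)

    def test_masked_modality_contributes_exactly_zero(self, small_dataset):
        ds, _ = small_dataset
        sub = ds.subset(np.arange(40))
        sub.modality_mask[:, 1] = False  # hide ATAC everywhere
        model = make_model(ds)
        c1 = model.elbo(sub, np.arange(40), sample_seed=1)
        assert float(c1["recon_atac"].data) == 0.0
        # arbitrary edits to the masked counts leave every component unchanged
        tampered = sub.subset(np.arange(40))
        dense = np.asarray(tampered.atac_counts.todense())
        dense[:, :] = np.random.default_rng(2).integers(0, 5, dense.shape)
        tampered.atac_counts = sp.csr_matrix(dense)
        c2 = model.elbo(tampered, np.arange(40), sample_seed=1)
        for k in c1:
            assert float(c1[k].data) == float(c2[k].data), k

    def test_posterior_equal_to_prior_gives_zero_kl(self, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        # zero the encoder heads -> mu = 0; set var head bias so softplus+eps = 1
        from scipy.optimize import brentq
        b = brentq(lambda t: np.logaddexp(0, t) + 1e-4 - 1.0, -5, 5)
        for enc in model.encoders.values():
            enc.mu_head.weight.data[:] = 0
            enc.mu_head.bias.data[:] = 0
            enc.var_head.weight.data[:] = 0
            enc.var_head.bias.data[:] = b
        comps = model.elbo(ds, np.arange(16), sample_seed=0)
        for m in model.encoders:
            assert float(comps[f"kl_{m}"].data) == pytest.approx(0.0, abs=1e-10)
        # and identical posteriors make the consistency penalty vanish
        assert float(comps["penalty"].data) == pytest.approx(0.0, abs=1e-10)

    def test_empty_minibatch_rejected(self, small_dataset):
        ds, _ = small_dataset
        with pytest.raises(ValueError):
            make_model(ds).elbo(ds, np.array([], dtype=int))


class TestMMDPenaltyTraining:
    def test_mmd_elbo_finite_with_gradients_and_near_zero_at_identity(self):
        ds, _ = sm.simulate(sm.SimConfig(n_cells=60, n_genes=15, n_regions=20,
                                         n_proteins=4, seed=4))
        cfg = sm.ModelConfig(latent_dim=4, n_hidden=8, dropout=0.0,
                             penalty="mmd", mmd_samples=8, seed=0)
        model = MosaicVAE(cfg, ds.n_genes, ds.n_regions, ds.n_proteins,
                          ds.batch_vocab)
        comps = model.elbo(ds, np.arange(32), sample_seed=0)
        assert float(comps["penalty"].data) > 0
        comps["total"].backward()
        assert all(np.isfinite(p.grad).all() for p in model.parameters()
                   if p.grad is not None)
        # identical posteriors: MMD vanishes up to Monte-Carlo noise
        from scipy.optimize import brentq
        b = brentq(lambda t: np.logaddexp(0, t) + 1e-4 - 1.0, -5, 5)
        for enc in model.encoders.values():
            enc.mu_head.weight.data[:] = 0
            enc.mu_head.bias.data[:] = 0
            enc.var_head.weight.data[:] = 0
            enc.var_head.bias.data[:] = b
        comps = model.elbo(ds, np.arange(32), sample_seed=0)
        assert float(comps["penalty"].data) < 0.05

    def test_fit_runs_with_mmd_penalty(self):
        ds, _ = sm.simulate(sm.SimConfig(n_cells=60, n_genes=15, n_regions=20,
                                         n_proteins=4, seed=4))
        cfg = sm.ModelConfig(latent_dim=4, n_hidden=8, dropout=0.0,
                             penalty="mmd", mmd_samples=8, seed=0)
        model, state = sm.fit(ds, cfg, sm.TrainConfig(max_epochs=2, patience=2,
                                                      seed=0))
        assert state.epoch == 2
        assert np.isfinite(state.best_validation)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        model = make_model(ds)
        path = str(tmp_path / "model.ckpt.npz")
        model.save(path)
        loaded = MosaicVAE.load(path)
        s1 = model.encode(ds, np.arange(8))
        s2 = loaded.encode(ds, np.arange(8))
        np.testing.assert_array_equal(s1.fused_mean, s2.fused_mean)
        assert loaded.config == model.config


class TestConfig:
    def test_json_roundtrip(self):
        cfg = sm.ModelConfig(latent_dim=11, penalty="mmd", mixing="global")
        assert sm.ModelConfig.from_json(cfg.to_json()) == cfg

    @pytest.mark.parametrize("kw", [{"latent_dim": 1}, {"penalty": "l2"},
                                    {"mixing": "median"},
                                    {"penalty_weight": -1.0}])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            sm.ModelConfig(**kw)
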