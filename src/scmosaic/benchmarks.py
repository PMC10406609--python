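"""End-to-end benchmark procedures on synthetic data.

These are the package's standard self-checks: train on generator output and
measure how well the model recovers the generator's own parameters. They are
used both by the test suite and by ``scripts/acceptance.py``.

Problem sizes are deliberately desk-scale (the standard fixture: 2,000 cells;
the DE benchmark: 600 cells per replicate) so a full run finishes in minutes
on one CPU; docs/methods.md discusses what these sizes do and do not probe.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .diffexp import model_differential
from .infer import impute, uncertainty_error_relation
from .model import ModelConfig
from .simulate import SimConfig, simulate, simulate_de_pair
from .train import TrainConfig, fit
from .unpair import mosaic_patterns

__all__ = ["masked_atac_imputation", "de_recovery"]


def masked_atac_imputation(seed: int = 0, masked_fraction: float = 0.5,
                           max_epochs: int = 450) -> dict:
    """Hide ATAC for half the standard fixture, train, impute, and score.

    Returns the Spearman correlation between imputed accessibility
    probabilities and the generator's true p at cell-type pseudobulk level
    (mean over the ATAC-masked cells of each type, pooled across types), and
    the same correlation at detection scale (p*r) as a secondary readout.
    """
    ds, gt = simulate(SimConfig(seed=seed))
    masked = mosaic_patterns(
        ds, {"rna+atac+protein": 1.0 - masked_fraction,
             "rna+protein": masked_fraction}, seed=seed + 1)
    model, state = fit(masked, ModelConfig(seed=seed),
                       TrainConfig(max_epochs=max_epochs, patience=50,
                                   seed=seed))
    res = impute(masked, model, "atac", n_samples=15, seed=seed)
    no_atac = ~masked.modality_mask[:, 1]
    types = gt.type_labels
    imp, tru = [], []
    for k in np.unique(types):
        sel = no_atac & (types == k)
        if sel.any():
            imp.append(res.mean[sel].mean(axis=0))
            tru.append(gt.atac_p[sel].mean(axis=0))
    imp = np.concatenate(imp)
    tru = np.concatenate(tru)
    rho_p = float(spearmanr(imp, tru).statistic)

    # uncertainty calibration on the masked block: does the Monte-Carlo sd
    # track the squared error against observed detections and against truth?
    from dataclasses import replace
    res_masked = replace(res, mean=res.mean[no_atac], sd=res.sd[no_atac])
    y_hidden = ds.atac_binary.toarray()[no_atac]
    rel_obs = uncertainty_error_relation(res_masked, y_hidden)
    rel_true = uncertainty_error_relation(res_masked, gt.atac_p[no_atac])

    dec = model.decode(model.encode(masked).fused_mean, masked.batch_codes)
    qm = dec.atac_p * dec.atac_r[None, :]
    qt = gt.atac_p * gt.atac_r[None, :]
    imp_q = np.concatenate([qm[no_atac & (types == k)].mean(axis=0)
                            for k in np.unique(types)
                            if (no_atac & (types == k)).any()])
    tru_q = np.concatenate([qt[no_atac & (types == k)].mean(axis=0)
                            for k in np.unique(types)
                            if (no_atac & (types == k)).any()])
    return {
        "spearman_p_pseudobulk": rho_p,
        "spearman_detection_pseudobulk": float(spearmanr(imp_q, tru_q).statistic),
        "uncertainty_error_spearman_observed": rel_obs["spearman"],
        "uncertainty_error_spearman_true": rel_true["spearman"],
        "n_cells": int(ds.n_cells),
        "n_masked": int(no_atac.sum()),
        "epochs_run": int(state.epoch),
    }


def de_recovery(n_replicates: int = 20, base_seed: int = 0,
                n_pairs: int = 3000, fdr_target: float = 0.05) -> dict:
    """Planted-DE recovery with the latent-sampling Bayes-factor route.

    Each replicate simulates a two-population RNA-only dataset with 20 genes
    planted at 4-fold effect and exactly-null background genes, trains the
    model, runs 'change'-mode differential analysis and applies the
    posterior-expectation FDR rule at ``fdr_target``. Reports the pooled
    empirical FDR, mean sensitivity, and the mean fraction of planted genes
    among the top-|BF| ranks.
    """
    fp_total = hit_total = tp_total = 0
    planted_total = 0
    topk_fracs = []
    for i in range(n_replicates):
        seed = base_seed + i
        ds, gt = simulate_de_pair(seed=seed)
        model, _ = fit(ds, ModelConfig(latent_dim=10, n_hidden=128, seed=seed),
                       TrainConfig(max_epochs=500, patience=50, seed=seed))
        ga = np.where(gt.type_labels == 0)[0]
        gb = np.where(gt.type_labels == 1)[0]
        res = model_differential(model, ds, gb, ga, modality="rna",
                                 mode="change", n_pairs=n_pairs,
                                 fdr_target=fdr_target, seed=seed)
        hits = res.table["is_de_model"].to_numpy()
        planted = np.zeros(ds.n_genes, bool)
        planted[gt.de_genes] = True
        fp_total += int((hits & ~planted).sum())
        tp_total += int((hits & planted).sum())
        hit_total += int(hits.sum())
        planted_total += int(planted.sum())
        order = np.argsort(-np.abs(res.table["bayes_factor"].to_numpy()))
        topk_fracs.append(planted[order[:planted.sum()]].mean())
    return {
        "empirical_fdr": fp_total / max(hit_total, 1),
        "sensitivity": tp_total / planted_total,
        "top_rank_fraction_planted": float(np.mean(topk_fracs)),
        "n_replicates": n_replicates,
        "n_discoveries": hit_total,
    }
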