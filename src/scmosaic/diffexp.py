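"""Differential expression / accessibility.

Two routes are implemented:

1. Model-based: sample pairs of cells (one from each group), draw latents from
   their posteriors, decode normalized values, and estimate per feature the
   posterior probability of the differential hypothesis. 'vanilla' mode tests
   P(value_a > value_b); 'change' mode tests P(|log2 fold change| > delta).
   Significance is summarized by the Bayes factor ln(p/(1-p)) and a
   posterior-expectation FDR rule: sort features by p descending and grow the
   rejection set while the running mean of (1-p) stays at or below the target
   rate.
2. Held-out counts: per-cell library normalization (RNA) or TF-IDF (ATAC),
   Wilcoxon rank-sum per feature, Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

from .data import MultiomicDataset
from .model import MosaicVAE

__all__ = ["DiffResult", "model_differential", "heldout_differential",
           "tfidf_transform", "posterior_expectation_fdr", "concordance"]


@dataclass
class DiffResult:
    table: pd.DataFrame  # one row per feature

    def significant(self, column: str = "is_de_model") -> np.ndarray:
        return self.table[column].to_numpy()


def posterior_expectation_fdr(p: np.ndarray, fdr_target: float) -> np.ndarray:
    """Rejection flags controlling the posterior expectation of the FDR.

    Sort p descending; the largest prefix whose mean (1 - p) is <= the target
    is rejected. By construction the mean posterior null probability of the
    rejected set is at most ``fdr_target``.
    """
    order = np.argsort(-p, kind="stable")
    running = np.cumsum(1.0 - p[order]) / np.arange(1, len(p) + 1)
    k = np.max(np.where(running <= fdr_target)[0]) + 1 if np.any(
        running <= fdr_target) else 0
    flags = np.zeros(len(p), dtype=bool)
    flags[order[:k]] = True
    return flags


def model_differential(model: MosaicVAE, dataset: MultiomicDataset,
                       group_a: np.ndarray, group_b: np.ndarray,
                       modality: str = "rna", n_pairs: int = 10_000,
                       mode: str = "vanilla", delta: float = 0.25,
                       fdr_target: float = 0.05, seed: int = 0,
                       batch_size: int = 512) -> DiffResult:
    """Latent-sampling differential analysis between two groups of cells.

    For each of ``n_pairs`` draws, one cell is sampled uniformly from each
    group, a latent is drawn from its fused posterior and decoded to the
    normalized value (rho for RNA, p for ATAC); the per-feature hypothesis
    probability is the fraction of pairs satisfying it.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("vanilla", "change"):
        raise ValueError("mode must be 'vanilla' or 'change'")
    import warnings
    if n_pairs < 100:
        warnings.warn("n_pairs < 100 gives a noisy posterior probability",
                      stacklevel=2)
    state = model.encode(dataset)
    mu, var = state.fused_mean, state.fused_variance
    codes = dataset.batch_codes
    rng = np.random.default_rng(seed)
    n_feat = dataset.n_genes if modality == "rna" else dataset.n_regions

    hits = np.zeros(n_feat)
    lfc_sum = np.zeros(n_feat)
    val_a_sum = np.zeros(n_feat)
    val_b_sum = np.zeros(n_feat)
    done = 0
    pseudo = 1e-4
    while done < n_pairs:
        m = min(batch_size, n_pairs - done)
        ia = rng.choice(group_a, size=m)
        ib = rng.choice(group_b, size=m)
        za = mu[ia] + np.sqrt(var[ia]) * rng.standard_normal((m, mu.shape[1]))
        zb = mu[ib] + np.sqrt(var[ib]) * rng.standard_normal((m, mu.shape[1]))
        da = model.decode(za, codes[ia])
        db = model.decode(zb, codes[ib])
        va = da.rho if modality == "rna" else da.atac_p
        vb = db.rho if modality == "rna" else db.atac_p
        lfc = np.log2(va + pseudo) - np.log2(vb + pseudo)
        if mode == "vanilla":
            hits += (va > vb).sum(axis=0)
        else:
            hits += (np.abs(lfc) > delta).sum(axis=0)
        lfc_sum += lfc.sum(axis=0)
        val_a_sum += va.sum(axis=0)
        val_b_sum += vb.sum(axis=0)
        done += m

    p = hits / n_pairs
    p_clip = np.clip(p, 1.0 / n_pairs, 1.0 - 1.0 / n_pairs)
    bf = np.log(p_clip / (1.0 - p_clip))
    names = (dataset.gene_names if modality == "rna"
             else dataset.region_names) or [f"f{i}" for i in range(n_feat)]
    table = pd.DataFrame({
        "feature": names,
        "prob_de": p,
        "bayes_factor": bf,
        "lfc_mean": lfc_sum / n_pairs,
        "mean_a": val_a_sum / n_pairs,
        "mean_b": val_b_sum / n_pairs,
    })
    table["effect"] = (table["lfc_mean"] if modality == "rna"
                       else table["mean_a"] - table["mean_b"])
    table["is_de_model"] = posterior_expectation_fdr(p, fdr_target)
    return DiffResult(table=table)


def tfidf_transform(binary: sp.spmatrix | np.ndarray) -> np.ndarray:
    """TF-IDF for binarized accessibility.

    Term frequency: detection indicator divided by the cell's detected-region
    count; IDF: log(1 + C / (1 + df_j)). One fixed dialect, used consistently
    for the held-out route and for LSA smoothing.
    """
    x = np.asarray(sp.csr_matrix(binary).todense(), dtype=float)
    x = (x > 0).astype(float)
    depth = x.sum(axis=1, keepdims=True)
    depth = np.where(depth > 0, depth, 1.0)
    tf = x / depth
    df = x.sum(axis=0)
    idf = np.log(1.0 + x.shape[0] / (1.0 + df))
    return tf * idf[None, :]


def heldout_differential(dataset: MultiomicDataset, group_a: np.ndarray,
                         group_b: np.ndarray, modality: str = "rna",
                         fdr_target: float = 0.05) -> DiffResult:
    """Wilcoxon rank-sum differential test on held-out raw counts.

    RNA: per-cell library normalization, effect = log2 of the group-mean
    ratio (with pseudocount). ATAC: TF-IDF values, effect = mean difference.
    Zero-variance features get p = 1 by convention.
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if modality == "rna":
        x = np.asarray(dataset.rna_counts.todense(), dtype=float)
        lib = x.sum(axis=1, keepdims=True)
        lib = np.where(lib > 0, lib, 1.0)
        vals = x / lib
        names = dataset.gene_names
    elif modality == "atac":
        vals = tfidf_transform(dataset.atac_binary)
        names = dataset.region_names
    else:
        raise ValueError("modality must be 'rna' or 'atac'")
    va, vb = vals[group_a], vals[group_b]
    pvals = np.ones(vals.shape[1])
    for j in range(vals.shape[1]):
        col = np.concatenate([va[:, j], vb[:, j]])
        if np.allclose(col, col[0]):
            continue  # zero variance: p = 1
        pvals[j] = mannwhitneyu(va[:, j], vb[:, j],
                                alternative="two-sided", method="auto").pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    pseudo = 1e-4
    if modality == "rna":
        effect = np.log2(va.mean(axis=0) + pseudo) - np.log2(vb.mean(axis=0)
                                                             + pseudo)
    else:
        effect = va.mean(axis=0) - vb.mean(axis=0)
    names = names or [f"f{i}" for i in range(vals.shape[1])]
    table = pd.DataFrame({
        "feature": names,
        "heldout_effect": effect,
        "pvalue": pvals,
        "qvalue": qvals,
        "is_de_heldout": qvals <= fdr_target,
    })
    return DiffResult(table=table)


def concordance(model_result: DiffResult, heldout_result: DiffResult,
                bf_thresholds=(0.5, 1.0, 2.0), fdr_thresholds=(0.05,),
                signed: bool = False) -> dict:
    """Overlap and hypergeometric fold enrichment between the two routes.

    For each (BF threshold, held-out FDR threshold) pair: the fraction of
    model hits confirmed by the held-out test, the fold enrichment of the
    overlap over the independence expectation, and its hypergeometric
    p-value. Also reports the Pearson correlation of effect sizes.

    With ``signed=False`` (vanilla mode, where the null sits at BF = 0) a
    model hit is |BF| >= threshold; with ``signed=True`` (change mode, where
    the null drives BF strongly negative) a hit is BF >= threshold.
    """
    mt = model_result.table
    ht = heldout_result.table
    if not (mt["feature"] == ht["feature"]).all():
        raise ValueError("feature sets must match")
    n = len(mt)
    rows = []
    for bf_t in bf_thresholds:
        bf = mt["bayes_factor"].to_numpy()
        model_hits = (bf >= bf_t) if signed else (np.abs(bf) >= bf_t)
        for q_t in fdr_thresholds:
            held_hits = ht["qvalue"].to_numpy() <= q_t
            k = int((model_hits & held_hits).sum())
            a, b = int(model_hits.sum()), int(held_hits.sum())
            expected = a * b / n if n else 0.0
            enrich = k / expected if expected > 0 else np.nan
            pval = hypergeom.sf(k - 1, n, a, b) if min(a, b) > 0 else 1.0
            overlap = k / a if a else np.nan
            rows.append({"bf_threshold": bf_t, "fdr_threshold": q_t,
                         "n_model": a, "n_heldout": b, "n_overlap": k,
                         "overlap_fraction": overlap,
                         "fold_enrichment": enrich, "pvalue": float(pval)})
    eff = pearsonr(mt["effect"], ht["heldout_effect"])
    return {"curve": pd.DataFrame(rows),
            "effect_pearson": float(eff.statistic)}
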