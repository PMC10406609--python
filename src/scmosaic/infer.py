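"""Post-training queries: latent coordinates, cross-modal imputation and
Monte-Carlo uncertainty.

Imputation draws latent samples from each cell's fused posterior (n = 15 by
default), decodes each sample, and summarizes per feature by the mean and
standard deviation across draws — the standard deviation is the model's
uncertainty about the imputed value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .data import MultiomicDataset
from .model import MosaicVAE

__all__ = ["ImputationResult", "get_latent", "impute",
           "uncertainty_error_relation"]


@dataclass
class ImputationResult:
    mean: np.ndarray              # (n_cells, n_features)
    sd: np.ndarray                # (n_cells, n_features)
    n_samples: int
    modality: str
    extra: dict | None = None     # protein: background/foreground components


def get_latent(dataset: MultiomicDataset, model: MosaicVAE,
               mode: str = "fused"):
    """Latent coordinates per cell.

    mode='fused' returns the fused posterior mean, one row per cell.
    mode='per_modality' returns (coords, cell_index, modality) with one row
    per observed modality per cell, as used by rank-distance evaluation.
    """
    state = model.encode(dataset)
    if mode == "fused":
        return state.fused_mean
    if mode != "per_modality":
        raise ValueError("mode must be 'fused' or 'per_modality'")
    rows, cells, mods = [], [], []
    from .data import MODALITIES
    for mi, m in enumerate(MODALITIES):
        if m not in state.means:
            continue
        obs = np.where(state.mask[:, mi])[0]
        rows.append(state.means[m][obs])
        cells.extend(obs.tolist())
        mods.extend([m] * len(obs))
    return np.vstack(rows), np.array(cells), np.array(mods)


def impute(dataset: MultiomicDataset, model: MosaicVAE, target_modality: str,
           n_samples: int = 15, seed: int = 0,
           transfer_batch: str | None = None) -> ImputationResult:
    """Impute a modality for every cell from its fused latent posterior.

    RNA is returned as normalized frequencies rho (rows on the simplex), ATAC
    as biological accessibility probabilities p, protein as the denoised
    foreground mean (1-pi)*l*alpha*beta with the mixture components stored in
    ``extra``. Decoding uses each cell's own batch unless ``transfer_batch``
    names a batch to decode all cells under.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if target_modality not in model.decoders:
        raise ValueError(f"model has no decoder for {target_modality!r}")
    state = model.encode(dataset)
    mu, var = state.fused_mean, state.fused_variance
    if transfer_batch is None:
        codes = dataset.batch_codes
    else:
        codes = np.full(dataset.n_cells,
                        model.batch_vocab.index(transfer_batch))
    rng = np.random.default_rng(seed)
    draws = []
    extra_draws: dict[str, list] = {}
    for _ in range(n_samples):
        z = mu + np.sqrt(var) * rng.standard_normal(mu.shape)
        dec = model.decode(z, codes)
        if target_modality == "rna":
            draws.append(dec.rho)
        elif target_modality == "atac":
            draws.append(dec.atac_p)
        else:
            ell = _protein_ell(dataset)
            fg = (1.0 - dec.protein_pi) * ell[:, None] * dec.protein_alpha \
                * dec.protein_beta
            draws.append(fg)
            extra_draws.setdefault("pi", []).append(dec.protein_pi)
            extra_draws.setdefault("background_mean", []).append(
                ell[:, None] * dec.protein_beta)
            extra_draws.setdefault("foreground_mean", []).append(
                ell[:, None] * dec.protein_alpha * dec.protein_beta)
    stack = np.stack(draws)
    extra = None
    if extra_draws:
        extra = {k: np.stack(v).mean(axis=0) for k, v in extra_draws.items()}
    return ImputationResult(mean=stack.mean(axis=0),
                            sd=stack.std(axis=0, ddof=0),
                            n_samples=n_samples, modality=target_modality,
                            extra=extra)


def _protein_ell(dataset: MultiomicDataset) -> np.ndarray:
    lib = np.asarray(dataset.protein_counts.sum(axis=1)).ravel()
    obs = dataset.modality_mask[:, 2]
    scale = lib[obs].mean() if obs.any() and lib[obs].mean() > 0 else 1.0
    out = np.where(lib > 0, lib, scale) / scale
    return out


def uncertainty_error_relation(imputed: ImputationResult,
                               observed: np.ndarray,
                               n_bins: int = 10) -> dict:
    """Mean squared imputation error binned by uncertainty decile.

    Pools all (cell, feature) entries, splits them into ``n_bins`` quantile
    bins of the Monte-Carlo standard deviation, and reports the mean squared
    error (imputed - observed)^2 per bin plus the Spearman correlation between
    bin rank and bin error — positive correlation means the model's stated
    uncertainty tracks its actual error.
    """
    if imputed.mean.shape != np.asarray(observed).shape:
        raise ValueError("shape mismatch between imputed and observed")
    sd = imputed.sd.ravel()
    err = (imputed.mean.ravel() - np.asarray(observed, float).ravel()) ** 2
    if np.allclose(sd, sd[0]):
        return {"bin_sd": np.array([sd.mean()]),
                "bin_mse": np.array([err.mean()]),
                "spearman": np.nan, "n_bins": 1}
    edges = np.quantile(sd, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-12
    which = np.clip(np.searchsorted(edges, sd, side="right") - 1, 0, n_bins - 1)
    bin_sd = np.array([sd[which == b].mean() for b in range(n_bins)
                       if (which == b).any()])
    bin_mse = np.array([err[which == b].mean() for b in range(n_bins)
                        if (which == b).any()])
    rho = spearmanr(np.arange(len(bin_mse)), bin_mse).statistic
    return {"bin_sd": bin_sd, "bin_mse": bin_mse,
            "spearman": float(rho), "n_bins": len(bin_mse)}
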