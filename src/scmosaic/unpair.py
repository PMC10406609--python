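"""Benchmark designs: artificial unpairing, population ablation and mosaic
availability patterns.

Artificial unpairing takes a fully paired dataset and replaces a random
fraction f of cells by single-modality copies (two copies for RNA+ATAC data,
three for tri-modal data), which preserves ground-truth pairing for
evaluation: both derived entries descend from the same source cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import MODALITIES, MultiomicDataset

__all__ = ["UnpairingPlan", "unpair_two_way", "unpair_three_way",
           "ablate_population", "mosaic_patterns", "composition_fractions"]

_MOD_IDX = {m: i for i, m in enumerate(MODALITIES)}


@dataclass
class UnpairingPlan:
    fraction: float
    mode: str
    seed: int = 0
    target_population: str | None = None


def _mask_only(mask_row_template: int, n: int) -> np.ndarray:
    out = np.zeros((n, 3), dtype=bool)
    out[:, mask_row_template] = True
    return out


def _stack(dataset: MultiomicDataset, keep_idx, parts) -> MultiomicDataset:
    """Assemble a derived dataset from kept cells plus single-modality parts.

    ``parts`` is a list of (source_idx, modality) in output order after the
    kept block. Returns (dataset, provenance) where provenance maps each
    derived entry to its source cell index.
    """
    keep_idx = np.asarray(keep_idx, dtype=int)
    blocks_rna, blocks_atac, blocks_prot = [dataset.rna_counts[keep_idx]], \
        [dataset.atac_counts[keep_idx]], [dataset.protein_counts[keep_idx]]
    masks = [dataset.modality_mask[keep_idx]]
    batches = [dataset.batch[keep_idx]]
    barcodes = [dataset.barcodes[i] for i in keep_idx]
    provenance = list(keep_idx)
    suffix = {"rna": ":RNA", "atac": ":ATAC", "protein": ":PROT"}
    for src_idx, modality in parts:
        src_idx = np.asarray(src_idx, dtype=int)
        n = len(src_idx)
        mi = _MOD_IDX[modality]
        blocks_rna.append(dataset.rna_counts[src_idx] if modality == "rna"
                          else sp.csr_matrix((n, dataset.n_genes)))
        blocks_atac.append(dataset.atac_counts[src_idx] if modality == "atac"
                           else sp.csr_matrix((n, dataset.n_regions)))
        blocks_prot.append(dataset.protein_counts[src_idx]
                           if modality == "protein"
                           else sp.csr_matrix((n, dataset.n_proteins)))
        masks.append(_mask_only(mi, n))
        batches.append(dataset.batch[src_idx])
        barcodes.extend(dataset.barcodes[i] + suffix[modality] for i in src_idx)
        provenance.extend(src_idx.tolist())
    derived = MultiomicDataset(
        rna_counts=sp.vstack(blocks_rna),
        atac_counts=sp.vstack(blocks_atac),
        protein_counts=sp.vstack(blocks_prot),
        batch=np.concatenate(batches),
        modality_mask=np.vstack(masks),
        gene_names=list(dataset.gene_names),
        region_names=list(dataset.region_names),
        protein_names=list(dataset.protein_names),
        barcodes=barcodes,
        batch_vocab=list(dataset.batch_vocab),
    )
    return derived, np.asarray(provenance)


def unpair_two_way(dataset: MultiomicDataset, fraction: float, seed: int = 0):
    """Replace floor(f*N) random paired cells by an RNA-only and an ATAC-only
    copy each. Returns (derived dataset, provenance array); total entries
    N + floor(f*N)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not (dataset.modality_mask[:, 0] & dataset.modality_mask[:, 1]).all():
        raise ValueError("two-way unpairing requires fully RNA+ATAC-paired input")
    n = dataset.n_cells
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=int(np.floor(fraction * n)),
                                replace=False))
    keep = np.setdiff1d(np.arange(n), chosen)
    return _stack(dataset, keep, [(chosen, "rna"), (chosen, "atac")])


def unpair_three_way(dataset: MultiomicDataset, fraction: float, seed: int = 0):
    """Replace floor(f*N) random tri-modal cells by three single-modality
    copies each; total entries N + 2*floor(f*N)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if not dataset.modality_mask.all():
        raise ValueError("three-way unpairing requires fully tri-modal input")
    n = dataset.n_cells
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n, size=int(np.floor(fraction * n)),
                                replace=False))
    keep = np.setdiff1d(np.arange(n), chosen)
    return _stack(dataset, keep,
                  [(chosen, "rna"), (chosen, "atac"), (chosen, "protein")])


def ablate_population(dataset: MultiomicDataset, population_labels,
                      population, modality: str):
    """Mask one modality for every cell of a named population.

    Cells left with no observed modality are dropped. Returns
    (derived dataset, kept-index array).
    """
    labels = np.asarray(population_labels)
    if len(labels) != dataset.n_cells:
        raise ValueError("labels must cover all cells")
    if population is None:  # empty population: no-op
        in_pop = np.zeros(dataset.n_cells, dtype=bool)
    else:
        in_pop = labels == population
        if not in_pop.any():
            raise ValueError(f"unknown population {population!r}")
    mask = dataset.modality_mask.copy()
    mask[in_pop, _MOD_IDX[modality]] = False
    keep = mask.any(axis=1)
    out = MultiomicDataset(
        rna_counts=dataset.rna_counts[keep],
        atac_counts=dataset.atac_counts[keep],
        protein_counts=dataset.protein_counts[keep],
        batch=dataset.batch[keep],
        modality_mask=mask[keep],
        gene_names=list(dataset.gene_names),
        region_names=list(dataset.region_names),
        protein_names=list(dataset.protein_names),
        barcodes=[b for b, k in zip(dataset.barcodes, keep) if k],
        batch_vocab=list(dataset.batch_vocab),
    )
    return out, np.where(keep)[0]


_PATTERNS = {
    "rna": (True, False, False), "atac": (False, True, False),
    "protein": (False, False, True), "rna+atac": (True, True, False),
    "rna+protein": (True, False, True), "atac+protein": (False, True, True),
    "rna+atac+protein": (True, True, True),
}


def mosaic_patterns(dataset: MultiomicDataset, pattern_spec: dict[str, float],
                    seed: int = 0) -> MultiomicDataset:
    """Partition a tri-modal dataset across modality-availability patterns.

    ``pattern_spec`` maps subset names ('rna', 'rna+atac', ...) to fractions
    summing to 1; cells are shuffled and assigned to patterns in blocks whose
    sizes match the fractions up to rounding.
    """
    keys = list(pattern_spec)
    unknown = set(keys) - set(_PATTERNS)
    if unknown:
        raise ValueError(f"unknown pattern names: {sorted(unknown)}")
    fr = np.array([pattern_spec[k] for k in keys], float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("pattern fractions must sum to 1")
    if not dataset.modality_mask.all():
        raise ValueError("mosaic_patterns requires tri-modal input")
    n = dataset.n_cells
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    bounds = np.round(np.cumsum(fr) * n).astype(int)
    mask = np.zeros((n, 3), dtype=bool)
    start = 0
    for key, stop in zip(keys, bounds):
        mask[perm[start:stop]] = _PATTERNS[key]
        start = stop
    mask[perm[start:]] = _PATTERNS[keys[-1]]  # rounding remainder
    return MultiomicDataset(
        rna_counts=dataset.rna_counts, atac_counts=dataset.atac_counts,
        protein_counts=dataset.protein_counts, batch=dataset.batch,
        modality_mask=mask, gene_names=list(dataset.gene_names),
        region_names=list(dataset.region_names),
        protein_names=list(dataset.protein_names),
        barcodes=list(dataset.barcodes), batch_vocab=list(dataset.batch_vocab))


def composition_fractions(counts: dict[str, int]) -> dict[str, float]:
    """Percentage composition of a combined dataset from per-source counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must be positive")
    return {k: 100.0 * v / total for k, v in counts.items()}
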