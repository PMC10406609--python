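"""Multi-omic dataset container.

A :class:`MultiomicDataset` holds per-modality sparse count matrices on a
shared cell axis, a per-cell batch covariate and a per-cell modality mask
stating which assays were actually measured for that cell. RNA and protein
counts are kept raw; ATAC fragment counts are kept raw too but the model
consumes them as binary detection indicators (count > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MODALITIES = ("rna", "atac", "protein")


def _csr(x) -> sp.csr_matrix:
    m = sp.csr_matrix(x)
    m.eliminate_zeros()
    return m


@dataclass
class MultiomicDataset:
    """Cells × features count matrices for up to three modalities.

    Parameters
    ----------
    rna_counts, atac_counts, protein_counts
        Sparse (or dense) nonnegative integer matrices with cells as rows.
        A modality absent from the experiment entirely may be an empty
        matrix with zero columns.
    batch
        Per-cell categorical covariate (technology, sample, ...).
    modality_mask
        Boolean (n_cells, 3) array: columns (has_rna, has_atac, has_protein).
    """

    rna_counts: sp.csr_matrix
    atac_counts: sp.csr_matrix
    protein_counts: sp.csr_matrix
    batch: np.ndarray
    modality_mask: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    region_names: list[str] = field(default_factory=list)
    protein_names: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)
    batch_vocab: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.rna_counts = _csr(self.rna_counts)
        self.atac_counts = _csr(self.atac_counts)
        self.protein_counts = _csr(self.protein_counts)
        self.batch = np.asarray(self.batch)
        self.modality_mask = np.asarray(self.modality_mask, dtype=bool)
        n = self.n_cells
        if self.modality_mask.shape != (n, 3):
            raise ValueError("modality_mask must be (n_cells, 3)")
        for attr, name in (("rna_counts", "rna"), ("atac_counts", "atac"),
                           ("protein_counts", "protein")):
            m = getattr(self, attr)
            if m.shape[0] != n:
                if m.nnz == 0:  # absent modality: normalize to (n, n_features)
                    setattr(self, attr, sp.csr_matrix((n, m.shape[1])))
                else:
                    raise ValueError(f"{name} matrix cell axis mismatch")
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"negative counts in {name}")
        if not self.batch_vocab:
            self.batch_vocab = sorted({str(b) for b in self.batch})
        if not self.barcodes:
            self.barcodes = [f"cell{i}" for i in range(n)]
        if not self.modality_mask.any(axis=1).all():
            raise ValueError("every cell must have at least one observed modality")
        if len(self.batch) != n:
            raise ValueError("batch vector length mismatch")

    # ------------------------------------------------------------- properties
    @property
    def n_cells(self) -> int:
        return self.modality_mask.shape[0]

    @property
    def n_genes(self) -> int:
        return self.rna_counts.shape[1]

    @property
    def n_regions(self) -> int:
        return self.atac_counts.shape[1]

    @property
    def n_proteins(self) -> int:
        return self.protein_counts.shape[1]

    @property
    def batch_codes(self) -> np.ndarray:
        lut = {b: i for i, b in enumerate(self.batch_vocab)}
        try:
            return np.array([lut[str(b)] for b in self.batch], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown batch category {e}") from None

    @property
    def atac_binary(self) -> sp.csr_matrix:
        b = self.atac_counts.copy()
        b.data = (b.data > 0).astype(np.float64)
        return b

    def modality_pattern(self) -> np.ndarray:
        """Integer code 1..7 for the observed-modality subset of each cell."""
        m = self.modality_mask.astype(int)
        return m[:, 0] * 4 + m[:, 1] * 2 + m[:, 2]

    def subset(self, idx: np.ndarray) -> "MultiomicDataset":
        idx = np.asarray(idx)
        return MultiomicDataset(
            rna_counts=self.rna_counts[idx],
            atac_counts=self.atac_counts[idx],
            protein_counts=self.protein_counts[idx],
            batch=self.batch[idx],
            modality_mask=self.modality_mask[idx],
            gene_names=list(self.gene_names),
            region_names=list(self.region_names),
            protein_names=list(self.protein_names),
            barcodes=[self.barcodes[i] for i in idx],
            batch_vocab=list(self.batch_vocab),
        )

    def cells_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "barcode": self.barcodes,
            "batch": [str(b) for b in self.batch],
            "has_rna": self.modality_mask[:, 0],
            "has_atac": self.modality_mask[:, 1],
            "has_protein": self.modality_mask[:, 2],
        })
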