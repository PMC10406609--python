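"""Dataset bundle reader/writer and feature utilities.

A bundle is a directory with one subdirectory per modality (``rna``, ``atac``,
``protein``), each holding ``matrix.mtx`` (MatrixMarket coordinate, cells as
columns, the 10X convention), ``features.tsv`` and ``barcodes.tsv`` (no
header), plus a top-level ``cells.tsv`` (header: barcode, batch, has_rna,
has_atac, has_protein) and a ``manifest.json`` with format version and
sha256 checksums used to verify integrity on load.
"""

from __future__ import annotations

import hashlib
import json
import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import MODALITIES, MultiomicDataset

__all__ = ["write_bundle", "read_bundle", "intersect_features",
           "filter_features"]

_FORMAT_VERSION = 1


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _feature_names(dataset: MultiomicDataset, modality: str) -> list[str]:
    return {"rna": dataset.gene_names, "atac": dataset.region_names,
            "protein": dataset.protein_names}[modality]


def _matrix(dataset: MultiomicDataset, modality: str) -> sp.csr_matrix:
    return {"rna": dataset.rna_counts, "atac": dataset.atac_counts,
            "protein": dataset.protein_counts}[modality]


def write_bundle(dataset: MultiomicDataset, path: str) -> None:
    """Write a dataset to a bundle directory (atomic: manifest written last,
    after all data files are flushed to disk)."""
    os.makedirs(path, exist_ok=True)
    files: dict[str, str] = {}
    for mi, modality in enumerate(MODALITIES):
        mat = _matrix(dataset, modality)
        if mat.shape[1] == 0 or not dataset.modality_mask[:, mi].any():
            continue
        sub = os.path.join(path, modality)
        os.makedirs(sub, exist_ok=True)
        obs = dataset.modality_mask[:, mi]
        mtx_path = os.path.join(sub, "matrix.mtx")
        scipy.io.mmwrite(mtx_path, sp.coo_matrix(mat[obs].T), field="integer")
        names = _feature_names(dataset, modality) \
            or [f"f{i}" for i in range(mat.shape[1])]
        with open(os.path.join(sub, "features.tsv"), "w") as fh:
            fh.write("\n".join(names) + "\n")
        with open(os.path.join(sub, "barcodes.tsv"), "w") as fh:
            fh.write("\n".join(b for b, o in zip(dataset.barcodes, obs) if o)
                     + "\n")
        for fn in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            rel = f"{modality}/{fn}"
            files[rel] = _sha256(os.path.join(path, rel))
    cells = dataset.cells_dataframe()
    cells_path = os.path.join(path, "cells.tsv")
    cells.to_csv(cells_path, sep="\t", index=False)
    files["cells.tsv"] = _sha256(cells_path)
    for rel in files:  # fsync data files before committing the manifest
        with open(os.path.join(path, rel), "rb") as fh:
            os.fsync(fh.fileno())
    manifest = {"format_version": _FORMAT_VERSION, "files": files,
                "batch_vocab": list(dataset.batch_vocab)}
    tmp = os.path.join(path, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.flush()
        os.fsync(fh.fileno())
    os.replace(tmp, os.path.join(path, "manifest.json"))


def read_bundle(path: str, verify_checksums: bool = True) -> MultiomicDataset:
    """Load a bundle directory into a :class:`MultiomicDataset`.

    Cells listed in cells.tsv but missing from a modality's barcodes get
    mask = False for that modality. Checksum mismatches, malformed matrices
    and duplicate barcodes raise explicit errors.
    """
    manifest_path = os.path.join(path, "manifest.json")
    if not os.path.exists(manifest_path):
        raise FileNotFoundError("bundle manifest.json missing")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if verify_checksums:
        for rel, digest in manifest["files"].items():
            fp = os.path.join(path, rel)
            if not os.path.exists(fp):
                raise FileNotFoundError(f"bundle file missing: {rel}")
            if _sha256(fp) != digest:
                raise ValueError(f"checksum mismatch for {rel}")
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t")
    barcodes = cells["barcode"].astype(str).tolist()
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in cells.tsv")
    n = len(barcodes)
    pos = {b: i for i, b in enumerate(barcodes)}

    mats: dict[str, sp.csr_matrix] = {}
    feats: dict[str, list[str]] = {}
    mask = np.zeros((n, 3), dtype=bool)
    for mi, modality in enumerate(MODALITIES):
        sub = os.path.join(path, modality)
        if not os.path.isdir(sub):
            mats[modality] = sp.csr_matrix((n, 0))
            feats[modality] = []
            continue
        try:
            m = scipy.io.mmread(os.path.join(sub, "matrix.mtx"))
        except Exception as e:
            raise ValueError(f"malformed MTX for {modality}: {e}") from e
        m = sp.csr_matrix(m).T  # stored features x cells -> cells x features
        with open(os.path.join(sub, "features.tsv")) as fh:
            fnames = [ln.strip() for ln in fh if ln.strip()]
        with open(os.path.join(sub, "barcodes.tsv")) as fh:
            bnames = [ln.strip() for ln in fh if ln.strip()]
        if len(set(bnames)) != len(bnames):
            raise ValueError(f"duplicate barcodes in {modality}")
        if m.shape != (len(bnames), len(fnames)):
            raise ValueError(f"matrix shape mismatch in {modality} "
                             f"(possible truncation)")
        full = sp.lil_matrix((n, len(fnames)))
        rows = [pos[b] for b in bnames if b in pos]
        present = [b in pos for b in bnames]
        if not all(present):
            missing = [b for b in bnames if b not in pos]
            raise ValueError(f"{modality} barcodes absent from cells.tsv: "
                             f"{missing[:3]}...")
        full[rows] = m
        mats[modality] = sp.csr_matrix(full)
        feats[modality] = fnames
        mask[rows, mi] = True

    # cells.tsv flags are authoritative but can only switch off observed data
    for mi, col in enumerate(("has_rna", "has_atac", "has_protein")):
        if col in cells.columns:
            mask[:, mi] &= cells[col].astype(bool).to_numpy()
    batch_vocab = manifest.get("batch_vocab") or sorted(
        cells["batch"].astype(str).unique())
    return MultiomicDataset(
        rna_counts=mats["rna"], atac_counts=mats["atac"],
        protein_counts=mats["protein"],
        batch=cells["batch"].astype(str).to_numpy(),
        modality_mask=mask,
        gene_names=feats["rna"], region_names=feats["atac"],
        protein_names=feats["protein"], barcodes=barcodes,
        batch_vocab=batch_vocab)


def intersect_features(*datasets: MultiomicDataset) -> list[MultiomicDataset]:
    """Restrict every dataset to the per-modality exact-name intersection.

    Feature order is canonicalized lexicographically. Region names are
    matched as exact "chrom:start-end" strings; no interval-overlap logic.
    An empty intersection in a modality both sides carry raises an error.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    out = []
    shared: dict[str, list[str]] = {}
    for modality, getter in (("rna", lambda d: d.gene_names),
                             ("atac", lambda d: d.region_names),
                             ("protein", lambda d: d.protein_names)):
        carrying = [d for d in datasets if getter(d)]
        if len(carrying) < 2:
            shared[modality] = getter(carrying[0]) if carrying else []
            continue
        common = set(getter(carrying[0]))
        for d in carrying[1:]:
            common &= set(getter(d))
        if not common:
            raise ValueError(f"empty feature intersection for {modality}")
        shared[modality] = sorted(common)
    for d in datasets:
        def _sel(mat, names, want):
            if not names or not want:
                return mat[:, :0], list(want)
            lut = {f: i for i, f in enumerate(names)}
            cols = [lut[f] for f in want]
            return sp.csr_matrix(mat[:, cols]), list(want)

        rna, genes = _sel(d.rna_counts, d.gene_names, shared["rna"])
        atac, regions = _sel(d.atac_counts, d.region_names, shared["atac"])
        prot, prots = _sel(d.protein_counts, d.protein_names, shared["protein"])
        out.append(MultiomicDataset(
            rna_counts=rna, atac_counts=atac, protein_counts=prot,
            batch=d.batch, modality_mask=d.modality_mask,
            gene_names=genes, region_names=regions, protein_names=prots,
            barcodes=list(d.barcodes), batch_vocab=list(d.batch_vocab)))
    return out


def filter_features(dataset: MultiomicDataset,
                    min_cell_fraction: float = 0.01) -> MultiomicDataset:
    """Drop features detected (count > 0) in fewer than the given fraction of
    the cells observing that modality."""
    if not 0.0 <= min_cell_fraction < 1.0:
        raise ValueError("min_cell_fraction must be in [0, 1)")

    def _keep(mat: sp.csr_matrix, obs: np.ndarray) -> np.ndarray:
        if mat.shape[1] == 0 or not obs.any():
            return np.ones(mat.shape[1], dtype=bool)
        det = np.asarray((mat[obs] > 0).sum(axis=0)).ravel() / obs.sum()
        return det >= min_cell_fraction

    kr = _keep(dataset.rna_counts, dataset.modality_mask[:, 0])
    ka = _keep(dataset.atac_counts, dataset.modality_mask[:, 1])
    kp = _keep(dataset.protein_counts, dataset.modality_mask[:, 2])
    return MultiomicDataset(
        rna_counts=dataset.rna_counts[:, kr],
        atac_counts=dataset.atac_counts[:, ka],
        protein_counts=dataset.protein_counts[:, kp],
        batch=dataset.batch, modality_mask=dataset.modality_mask,
        gene_names=[f for f, k in zip(dataset.gene_names, kr) if k],
        region_names=[f for f, k in zip(dataset.region_names, ka) if k],
        protein_names=[f for f, k in zip(dataset.protein_names, kp) if k],
        barcodes=list(dataset.barcodes),
        batch_vocab=list(dataset.batch_vocab))
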