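"""Synthetic tri-modal single-cell data drawn from the model's own
generative process, with full ground truth.

Cells live in a latent space with one centroid per cell type; fixed random
two-layer maps (not linear, so a fitted model cannot trivially memorize the
generator) decode the latent position into gene frequencies (softmax),
region accessibilities (sigmoid) and protein foreground intensities. Counts
are then sampled exactly as the model assumes: negative binomial RNA counts
with per-cell library sizes, Bernoulli peak detections damped by region- and
cell-specific detection factors, and background/foreground negative-binomial
mixtures for proteins. Batch effects enter as per-batch additive shifts on
the decoded logits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import MultiomicDataset

__all__ = ["SimConfig", "GroundTruth", "simulate", "default_fixture",
           "simulate_de_pair"]


@dataclass
class SimConfig:
    """Generator settings; defaults define the repository's standard fixture."""

    n_cells: int = 2000
    n_genes: int = 200
    n_regions: int = 500
    n_proteins: int = 20
    n_types: int = 4
    n_batches: int = 2
    latent_dim: int = 10
    cluster_separation: float = 3.0     # centroid scale vs unit within-type sd
    batch_effect: float = 0.3           # sd of per-batch logit shifts
    rna_depth_mean: float = 2000.0      # mean per-cell RNA library size
    rna_depth_sigma: float = 0.3        # lognormal sd of library size
    rna_dispersion_mean: float = 10.0   # per-gene inverse dispersion scale
    atac_region_beta: tuple[float, float] = (4.0, 2.0)   # r_j ~ Beta(a, b)
    atac_cell_beta: tuple[float, float] = (8.0, 2.0)     # l_c^A ~ Beta(a, b)
    protein_background_mean: float = 8.0
    protein_foreground_scale: float = 6.0  # multiplier over background
    protein_pi_background: float = 0.4
    protein_dispersion: float = 5.0
    de_fraction: float = 0.0            # planted DE genes per non-reference type
    de_fold: float = 4.0
    map_hidden: int = 32                # width of the random decoder maps
    seed: int = 0

    def __post_init__(self):
        if self.n_types > self.n_cells:
            raise ValueError("more cell types than cells")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        for name in ("n_cells", "n_genes", "n_regions", "n_proteins",
                     "n_types", "n_batches", "latent_dim"):
            if getattr(self, name) < 1 and name not in ("n_genes", "n_regions",
                                                        "n_proteins"):
                raise ValueError(f"{name} must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        d = json.loads(s)
        for k in ("atac_region_beta", "atac_cell_beta"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruth:
    latent: np.ndarray                 # (n, latent_dim)
    type_labels: np.ndarray            # (n,)
    rho: np.ndarray | None = None      # (n, G) true gene frequencies
    rna_depth: np.ndarray | None = None
    rna_theta: np.ndarray | None = None
    atac_p: np.ndarray | None = None   # (n, J) true accessibility
    atac_r: np.ndarray | None = None
    atac_ell: np.ndarray | None = None
    protein_foreground: np.ndarray | None = None
    protein_pi: np.ndarray | None = None
    de_genes: np.ndarray = field(default_factory=lambda: np.array([], int))
    de_regions: np.ndarray = field(default_factory=lambda: np.array([], int))


def _random_map(rng: np.random.Generator, d_in: int, d_hidden: int,
                d_out: int, scale: float = 1.0):
    """Fixed random two-layer tanh map latent -> feature logits."""
    w1 = rng.normal(0, 1.0 / np.sqrt(d_in), size=(d_in, d_hidden))
    b1 = rng.normal(0, 0.3, size=d_hidden)
    w2 = rng.normal(0, scale / np.sqrt(d_hidden), size=(d_hidden, d_out))
    b2 = rng.normal(0, 0.5, size=d_out)

    def f(z: np.ndarray) -> np.ndarray:
        return np.tanh(z @ w1 + b1) @ w2 + b2

    return f


def _sample_nb(rng, mean, theta):
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate(config: SimConfig) -> tuple[MultiomicDataset, GroundTruth]:
    """Draw one dataset plus its ground truth from the generative process."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_cells, cfg.latent_dim

    types = rng.integers(0, cfg.n_types, size=n)
    batches = rng.integers(0, cfg.n_batches, size=n)
    centroids = rng.normal(0, cfg.cluster_separation, size=(cfg.n_types, d))
    latent = centroids[types] + rng.standard_normal((n, d))

    gt = GroundTruth(latent=latent, type_labels=types)
    rna = sp.csr_matrix((n, cfg.n_genes))
    atac = sp.csr_matrix((n, cfg.n_regions))
    prot = sp.csr_matrix((n, cfg.n_proteins))

    if cfg.n_genes:
        f_rna = _random_map(rng, d, cfg.map_hidden, cfg.n_genes, scale=2.0)
        logits = f_rna(latent)
        logits += rng.normal(0, cfg.batch_effect,
                             size=(cfg.n_batches, cfg.n_genes))[batches]
        if cfg.de_fraction > 0:
            n_de = int(round(cfg.de_fraction * cfg.n_genes))
            de_genes = rng.choice(cfg.n_genes, size=n_de, replace=False)
            gt.de_genes = np.sort(de_genes)
            signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
            for k in range(1, cfg.n_types):
                logits[np.ix_(types == k, de_genes)] += signs * np.log(cfg.de_fold)
        rho = np.exp(logits - logits.max(axis=1, keepdims=True))
        rho /= rho.sum(axis=1, keepdims=True)
        depth = rng.lognormal(np.log(cfg.rna_depth_mean), cfg.rna_depth_sigma,
                              size=n)
        theta = rng.lognormal(np.log(cfg.rna_dispersion_mean), 0.3,
                              size=cfg.n_genes)
        counts = _sample_nb(rng, depth[:, None] * rho, theta[None, :])
        rna = sp.csr_matrix(counts)
        gt.rho, gt.rna_depth, gt.rna_theta = rho, depth, theta

    if cfg.n_regions:
        f_atac = _random_map(rng, d, cfg.map_hidden, cfg.n_regions, scale=3.0)
        logits = f_atac(latent)
        logits += rng.normal(0, cfg.batch_effect,
                             size=(cfg.n_batches, cfg.n_regions))[batches]
        p = 1.0 / (1.0 + np.exp(-logits))
        r = rng.beta(*cfg.atac_region_beta, size=cfg.n_regions)
        ell = rng.beta(*cfg.atac_cell_beta, size=n)
        y = rng.random((n, cfg.n_regions)) < ell[:, None] * p * r[None, :]
        atac = sp.csr_matrix(y.astype(np.int64))
        gt.atac_p, gt.atac_r, gt.atac_ell = p, r, ell

    if cfg.n_proteins:
        f_prot = _random_map(rng, d, cfg.map_hidden, cfg.n_proteins, scale=1.5)
        fg_logit = f_prot(latent)
        fg_logit += rng.normal(0, cfg.batch_effect,
                               size=(cfg.n_batches, cfg.n_proteins))[batches]
        bg_mean = rng.lognormal(np.log(cfg.protein_background_mean), 0.2,
                                size=cfg.n_proteins)
        alpha = 1.0 + cfg.protein_foreground_scale * np.logaddexp(0, fg_logit) \
            / np.log(2.0) / 4.0
        fg_mean = alpha * bg_mean[None, :]
        pi = np.full((n, cfg.n_proteins), cfg.protein_pi_background)
        is_bg = rng.random((n, cfg.n_proteins)) < pi
        th = cfg.protein_dispersion
        counts = np.where(is_bg,
                          _sample_nb(rng, np.broadcast_to(bg_mean, fg_mean.shape), th),
                          _sample_nb(rng, fg_mean, th))
        prot = sp.csr_matrix(counts)
        gt.protein_foreground, gt.protein_pi = fg_mean, pi

    mask = np.ones((n, 3), dtype=bool)
    mask[:, 0] = cfg.n_genes > 0
    mask[:, 1] = cfg.n_regions > 0
    mask[:, 2] = cfg.n_proteins > 0
    dataset = MultiomicDataset(
        rna_counts=rna, atac_counts=atac, protein_counts=prot,
        batch=np.array([f"batch{b}" for b in batches]),
        modality_mask=mask,
        gene_names=[f"gene{i}" for i in range(cfg.n_genes)],
        region_names=[f"chr1:{1000 * i}-{1000 * i + 500}"
                      for i in range(cfg.n_regions)],
        protein_names=[f"prot{i}" for i in range(cfg.n_proteins)],
        barcodes=[f"cell{i:05d}" for i in range(n)],
        batch_vocab=[f"batch{b}" for b in range(cfg.n_batches)],
    )
    return dataset, gt


def default_fixture() -> tuple[MultiomicDataset, GroundTruth]:
    """The repository's standard deterministic bundle: 2,000 cells, 200 genes,
    500 regions, 20 proteins, 4 types, 2 batches, seed 0."""
    return simulate(SimConfig())


def simulate_de_pair(n_cells: int = 600, n_genes: int = 60, n_de: int = 20,
                     fold: float = 4.0, depth: float = 2000.0,
                     map_scale: float = 0.5,
                     seed: int = 0) -> tuple[MultiomicDataset, GroundTruth]:
    """Two-population RNA-only benchmark with exactly-null background genes.

    Both populations share one latent centroid (separation 0), so without the
    planted offsets every gene would be exchangeable between groups; the DE
    signal is purely the +-log(fold) logit offsets at ``n_de`` genes, half up-
    and half down-regulated to keep library composition balanced.
    """
    rng = np.random.default_rng(seed)
    d = 10
    types = rng.integers(0, 2, size=n_cells)
    latent = rng.standard_normal((n_cells, d))
    f_rna = _random_map(rng, d, 32, n_genes, scale=map_scale)
    logits = f_rna(latent)
    rho = np.exp(logits - logits.max(axis=1, keepdims=True))
    rho /= rho.sum(axis=1, keepdims=True)
    de_genes = rng.choice(n_genes, size=n_de, replace=False)
    # assign up-/down-regulation so the total probability mass moved up
    # equals the mass moved down (up-mass*(fold-1) = down-mass*(1-1/fold)),
    # keeping the softmax renormalization ~1 and non-planted genes ~exactly
    # null instead of inheriting a compositional fold change
    m = rho.mean(axis=0)[de_genes]
    order = de_genes[np.argsort(-m)]
    mass = dict(zip(de_genes, m))
    up, down = [], []
    u_mass = d_mass = 0.0
    for g in order:
        if u_mass * (fold - 1.0) <= d_mass * (1.0 - 1.0 / fold):
            up.append(g)
            u_mass += mass[g]
        else:
            down.append(g)
            d_mass += mass[g]
    factors = np.ones(n_genes)
    factors[np.array(up)] = fold
    if down:
        # exact expected-mass balance: keep the up factor at `fold` and solve
        # u_mass*(fold-1) = d_mass*(1-f_down) for the down factor
        f_down = max(1.0 - u_mass * (fold - 1.0) / d_mass, 1.0 / (fold * 4))
        factors[np.array(down)] = f_down
    rho_de = rho.copy()
    rho_de[types == 1] = rho[types == 1] * factors[None, :]
    rho_de[types == 1] /= rho_de[types == 1].sum(axis=1, keepdims=True)
    rho = rho_de
    lib = rng.lognormal(np.log(depth), 0.3, size=n_cells)
    theta = rng.lognormal(np.log(10.0), 0.3, size=n_genes)
    counts = _sample_nb(rng, lib[:, None] * rho, theta[None, :])
    mask = np.zeros((n_cells, 3), dtype=bool)
    mask[:, 0] = True
    dataset = MultiomicDataset(
        rna_counts=sp.csr_matrix(counts),
        atac_counts=sp.csr_matrix((n_cells, 0)),
        protein_counts=sp.csr_matrix((n_cells, 0)),
        batch=np.array(["batch0"] * n_cells),
        modality_mask=mask,
        gene_names=[f"gene{i}" for i in range(n_genes)],
        barcodes=[f"cell{i:05d}" for i in range(n_cells)],
        batch_vocab=["batch0"],
    )
    gt = GroundTruth(latent=latent, type_labels=types, rho=rho,
                     rna_depth=lib, rna_theta=theta,
                     de_genes=np.sort(de_genes))
    return dataset, gt
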