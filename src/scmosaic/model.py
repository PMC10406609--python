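"""Deep generative model for mosaic single-cell multi-omics.

The model embeds cells in a shared D-dimensional latent space learned jointly
from RNA counts, chromatin accessibility and surface-protein counts, for cells
carrying any nonempty subset of the three assays.

Generative model, per cell c:

* RNA:      x_cg ~ NegBin(mean = l_c^R * rho_cg, inverse dispersion theta_g),
  where rho_c. lies on the gene simplex (decoded by softmax) and l_c^R is the
  observed per-cell total count.
* ATAC:     y_cj ~ Bernoulli(l_c^A * p_cj * r_j), with p_cj the decoded
  biological accessibility, r_j a learned region-specific detection factor and
  l_c^A a cell-specific detection factor in (0,1).
* Protein:  x_cp ~ pi1 * NegBin(l_c^P * beta, theta^b)
                 + (1 - pi1) * NegBin(l_c^P * alpha * beta, theta^f),
  a background/foreground mixture modelling ambient antibody signal.

Each observed modality gets its own diagonal-Gaussian encoder posterior
q(z^m | x_m, s); the per-modality posteriors are fused by a convex combination
(equal, global-learned, or per-cell-learned weights) into one latent state used
to decode every modality. A symmetric-KL (Jeffreys) or MMD penalty pulls the
modality-specific posteriors of multi-modal cells together.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln as _gammaln

from ._autograd import Tensor, concat, logsumexp, no_grad, softmax
from ._nn import MLP, Linear, Module
from .data import MODALITIES, MultiomicDataset

_EPS_PROB = 1e-7
_MIN_VAR = 1e-4


# ======================================================================
# Likelihoods (public, numpy; validated). The training path re-implements
# the same formulas on autodiff tensors (see _nb_ll_t etc. below).
# ======================================================================

def nb_log_pmf(x, mean, inv_dispersion):
    """Log-pmf of the negative binomial in mean/inverse-dispersion form.

    Parameterized so that E[X] = mean and Var[X] = mean + mean^2 /
    inv_dispersion; inv_dispersion -> infinity recovers the Poisson.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mean, dtype=np.float64)
    theta = np.asarray(inv_dispersion, dtype=np.float64)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mean and inv_dispersion must be positive")
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("x must be a nonnegative integer count")
    return (_gammaln(x + theta) - _gammaln(theta) - _gammaln(x + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + x * (np.log(mu) - np.log(theta + mu)))


def bernoulli_log_pmf(y, q):
    """Log-pmf of a Bernoulli detection indicator y in {0,1}, q in (0,1)."""
    y = np.asarray(y, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must lie strictly inside (0, 1)")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("y must be binary")
    return y * np.log(q) + (1.0 - y) * np.log1p(-q)


def protein_mixture_log_pmf(x, pi_background, background_mean, foreground_mean,
                            theta_background, theta_foreground):
    """Two-component negative-binomial mixture log-pmf for protein counts.

    ``pi_background`` weighs the background (ambient) component; the
    foreground component models specific binding. Computed with log-sum-exp.
    """
    pi = np.asarray(pi_background, dtype=np.float64)
    if np.any((pi <= 0) | (pi >= 1)):
        raise ValueError("pi_background must lie strictly inside (0, 1)")
    lp_b = np.log(pi) + nb_log_pmf(x, background_mean, theta_background)
    lp_f = np.log1p(-pi) + nb_log_pmf(x, foreground_mean, theta_foreground)
    return np.logaddexp(lp_b, lp_f)


def kl_diag_gaussian_to_standard(mu, var):
    """KL( N(mu, diag var) || N(0, I) ), summed over dimensions."""
    mu = np.asarray(mu, dtype=np.float64)
    var = np.asarray(var, dtype=np.float64)
    return 0.5 * np.sum(mu**2 + var - np.log(var) - 1.0, axis=-1)


def symm_kl_diag_gaussians(mu_a, var_a, mu_b, var_b):
    """Jeffreys divergence KL(a||b) + KL(b||a) for diagonal Gaussians."""
    mu_a, var_a = np.asarray(mu_a, float), np.asarray(var_a, float)
    mu_b, var_b = np.asarray(mu_b, float), np.asarray(var_b, float)
    d2 = (mu_a - mu_b) ** 2
    kl_ab = 0.5 * np.sum(np.log(var_b / var_a) + (var_a + d2) / var_b - 1.0, axis=-1)
    kl_ba = 0.5 * np.sum(np.log(var_a / var_b) + (var_b + d2) / var_a - 1.0, axis=-1)
    return kl_ab + kl_ba


def mmd_rbf(samples_a, samples_b, bandwidth: float | None = None):
    """Unbiased RBF-kernel MMD^2 estimate between two sample sets.

    Bandwidth defaults to the median heuristic over pooled pairwise distances.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)

    def _sq(u, v):
        return (np.sum(u**2, 1)[:, None] + np.sum(v**2, 1)[None, :]
                - 2.0 * u @ v.T)

    if bandwidth is None:
        pooled = np.vstack([a, b])
        d2 = _sq(pooled, pooled)
        med = np.median(d2[np.triu_indices_from(d2, k=1)])
        bandwidth = np.sqrt(max(med, 1e-12) / 2.0)
    g = 1.0 / (2.0 * bandwidth**2)
    kaa = np.exp(-g * _sq(a, a))
    kbb = np.exp(-g * _sq(b, b))
    kab = np.exp(-g * _sq(a, b))
    na, nb = len(a), len(b)
    term_a = (kaa.sum() - np.trace(kaa)) / (na * (na - 1))
    term_b = (kbb.sum() - np.trace(kbb)) / (nb * (nb - 1))
    return term_a + term_b - 2.0 * kab.mean()


# ======================================================================
# Value containers
# ======================================================================

@dataclass
class MixingWeights:
    """How per-modality posteriors are combined into the fused latent.

    scheme 'equal': w = 1/|observed|; 'global': one learned weight per
    modality, shared by all cells; 'per_cell': a learned map from each
    modality's posterior mean to a per-cell logit. Weights are renormalized
    over the modalities observed in each cell.
    """

    scheme: str = "equal"
    global_weights: np.ndarray | None = None  # length 3, simplex
    per_cell_weights: np.ndarray | None = None  # (n_cells, 3)

    def resolve(self, mask: np.ndarray) -> np.ndarray:
        """Per-cell weight matrix (n, 3) renormalized over observed modalities."""
        mask = np.asarray(mask, dtype=float)
        if self.scheme == "equal":
            w = mask.copy()
        elif self.scheme == "global":
            if self.global_weights is None:
                raise ValueError("global scheme needs global_weights")
            w = mask * np.asarray(self.global_weights, float)[None, :]
        elif self.scheme == "per_cell":
            if self.per_cell_weights is None:
                raise ValueError("per_cell scheme needs per_cell_weights")
            w = mask * np.asarray(self.per_cell_weights, float)
        else:
            raise ValueError(f"unknown mixing scheme {self.scheme!r}")
        if np.any(w < 0):
            raise ValueError("mixing weights must be nonnegative")
        tot = w.sum(axis=1, keepdims=True)
        if np.any(tot <= 0):
            raise ValueError("each cell needs positive total weight")
        return w / tot


@dataclass
class LatentState:
    """Per-modality diagonal-Gaussian posteriors and their fused combination."""

    means: dict[str, np.ndarray]       # modality -> (n, D)
    variances: dict[str, np.ndarray]   # modality -> (n, D)
    mask: np.ndarray                   # (n, 3) observed flags
    fused_mean: np.ndarray | None = None
    fused_variance: np.ndarray | None = None
    weights: np.ndarray | None = None  # (n, 3) resolved mixing weights

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if m in self.means]


@dataclass
class DecodedParams:
    """Generative parameters decoded from a fused latent state."""

    rho: np.ndarray | None = None           # (n, G) gene simplex
    atac_p: np.ndarray | None = None        # (n, J) biological accessibility
    atac_r: np.ndarray | None = None        # (J,) region detection factor
    atac_ell: np.ndarray | None = None      # (n,) cell detection factor
    theta: np.ndarray | None = None         # (G,) RNA inverse dispersion
    protein_pi: np.ndarray | None = None    # (n, P) background weight
    protein_beta: np.ndarray | None = None  # (n, P) background mean scale
    protein_alpha: np.ndarray | None = None # (n, P) foreground correction
    protein_theta_bg: np.ndarray | None = None  # (P,)
    protein_theta_fg: np.ndarray | None = None  # (P,)


@dataclass
class ModelConfig:
    """Architecture and objective hyperparameters; JSON-round-trippable."""

    latent_dim: int = 20
    n_hidden: int = 128
    n_layers: int = 2
    dropout: float = 0.1
    penalty: str = "symmkl"          # or "mmd"
    penalty_weight: float = 1.0
    mmd_samples: int = 32
    mixing: str = "equal"            # or "global", "per_cell"
    adversarial_weight: float = 0.0
    adversarial_grouping: str = "modality"  # or "batch"
    use_layernorm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.penalty not in ("symmkl", "mmd"):
            raise ValueError("penalty must be 'symmkl' or 'mmd'")
        if self.mixing not in ("equal", "global", "per_cell"):
            raise ValueError("unknown mixing scheme")
        if min(self.penalty_weight, self.adversarial_weight, self.dropout) < 0:
            raise ValueError("weights must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


# ======================================================================
# Public fusion / penalty operations on LatentState (numpy)
# ======================================================================

_MOD_IDX = {m: i for i, m in enumerate(MODALITIES)}


def fuse_latents(state: LatentState, weights: MixingWeights) -> LatentState:
    """Fuse per-modality posteriors into one diagonal Gaussian per cell.

    Means and variances are combined with the same convex weights,
    renormalized over each cell's observed modalities; a single observed
    modality therefore passes through unchanged.
    """
    w = weights.resolve(state.mask)
    n = state.mask.shape[0]
    d = next(iter(state.means.values())).shape[1]
    fmu = np.zeros((n, d))
    fvar = np.zeros((n, d))
    for m in state.modalities:
        wm = w[:, _MOD_IDX[m]][:, None]
        fmu += wm * state.means[m]
        fvar += wm * state.variances[m]
    state.fused_mean = fmu
    state.fused_variance = fvar
    state.weights = w
    return state


def consistency_penalty(state: LatentState, kind: str = "symmkl",
                        n_samples: int = 64, seed: int = 0) -> np.ndarray:
    """Per-cell divergence between modality posteriors, summed over pairs.

    Cells with fewer than two observed modalities contribute exactly 0.
    symmKL uses the diagonal-Gaussian closed form; MMD draws ``n_samples``
    per posterior and applies the unbiased RBF estimator.
    """
    n = state.mask.shape[0]
    out = np.zeros(n)
    mods = state.modalities
    rng = np.random.default_rng(seed)
    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            both = state.mask[:, _MOD_IDX[a]] & state.mask[:, _MOD_IDX[b]]
            if not both.any():
                continue
            if kind == "symmkl":
                pen = symm_kl_diag_gaussians(
                    state.means[a][both], state.variances[a][both],
                    state.means[b][both], state.variances[b][both])
                out[both] += pen
            elif kind == "mmd":
                idx = np.where(both)[0]
                for c in idx:
                    sa = (state.means[a][c]
                          + np.sqrt(state.variances[a][c])
                          * rng.standard_normal((n_samples, len(state.means[a][c]))))
                    sb = (state.means[b][c]
                          + np.sqrt(state.variances[b][c])
                          * rng.standard_normal((n_samples, len(state.means[b][c]))))
                    out[c] += max(mmd_rbf(sa, sb), 0.0)
            else:
                raise ValueError("kind must be 'symmkl' or 'mmd'")
    return out


# ======================================================================
# The variational autoencoder
# ======================================================================

class _Encoder(Module):
    """Per-modality encoder: counts ++ batch one-hot -> (mu, var) heads."""

    def __init__(self, n_in: int, n_batches: int, cfg: ModelConfig,
                 rng: np.random.Generator, with_ell_head: bool = False):
        self.trunk = MLP(n_in + n_batches, cfg.n_hidden, cfg.n_layers, rng,
                         dropout=cfg.dropout, use_layernorm=cfg.use_layernorm)
        self.mu_head = Linear(cfg.n_hidden, cfg.latent_dim, rng)
        self.var_head = Linear(cfg.n_hidden, cfg.latent_dim, rng)
        self.ell_head = Linear(cfg.n_hidden, 1, rng) if with_ell_head else None
        self.weight_head = Linear(cfg.n_hidden, 1, rng)  # per_cell mixing logit

    def __call__(self, x: Tensor, rng=None, training=False):
        h = self.trunk(x, rng, training)
        mu = self.mu_head(h)
        var = self.var_head(h).softplus() + _MIN_VAR
        ell = self.ell_head(h).sigmoid() if self.ell_head is not None else None
        wlogit = self.weight_head(h)
        return mu, var, ell, wlogit


class _Decoder(Module):
    def __init__(self, n_out_heads: dict[str, int], n_batches: int,
                 cfg: ModelConfig, rng: np.random.Generator):
        self.trunk = MLP(cfg.latent_dim + n_batches, cfg.n_hidden, cfg.n_layers,
                         rng, dropout=cfg.dropout, use_layernorm=cfg.use_layernorm)
        self.heads = {k: Linear(cfg.n_hidden, n, rng) for k, n in n_out_heads.items()}
        self._head_list = list(self.heads.values())  # for parameter discovery

    def __call__(self, z: Tensor, rng=None, training=False) -> dict[str, Tensor]:
        h = self.trunk(z, rng, training)
        return {k: head(h) for k, head in self.heads.items()}


class AdversarialClassifier(Module):
    """Two-hidden-layer classifier (width 32) from the fused latent to group
    probabilities; trained to predict the adversarial grouping, while the
    model is trained to defeat it."""

    def __init__(self, latent_dim: int, n_groups: int, rng: np.random.Generator):
        self.trunk = MLP(latent_dim, 32, 2, rng, dropout=0.0, use_layernorm=False)
        self.head = Linear(32, n_groups, rng)
        self.n_groups = n_groups

    def logits(self, z: Tensor) -> Tensor:
        return self.head(self.trunk(z))

    def predict_proba(self, z: np.ndarray) -> np.ndarray:
        with no_grad():
            return softmax(self.logits(Tensor(z)), axis=1).data

    def cross_entropy(self, z: Tensor, labels: np.ndarray) -> Tensor:
        lg = self.logits(z)
        lse = logsumexp(lg, axis=1, keepdims=True)
        logp = lg - lse
        onehot = np.zeros(lg.shape)
        onehot[np.arange(len(labels)), labels] = 1.0
        return -(logp * Tensor(onehot)).sum(axis=1).mean()


class MosaicVAE(Module):
    """Multimodal VAE over RNA / ATAC / protein with mosaic availability."""

    def __init__(self, config: ModelConfig, n_genes: int, n_regions: int,
                 n_proteins: int, batch_vocab: list[str],
                 gene_names=None, region_names=None, protein_names=None):
        self.config = config
        self.n_genes, self.n_regions, self.n_proteins = n_genes, n_regions, n_proteins
        self.batch_vocab = list(batch_vocab)
        self.gene_names = list(gene_names or [])
        self.region_names = list(region_names or [])
        self.protein_names = list(protein_names or [])
        nb = len(self.batch_vocab)
        rng = np.random.default_rng(config.seed)

        self.encoders: dict[str, _Encoder] = {}
        self.decoders: dict[str, _Decoder] = {}
        if n_genes:
            self.encoders["rna"] = _Encoder(n_genes, nb, config, rng)
            self.decoders["rna"] = _Decoder({"logits": n_genes}, nb, config, rng)
            self.log_theta = Tensor(np.zeros(n_genes), requires_grad=True)
        if n_regions:
            self.encoders["atac"] = _Encoder(n_regions, nb, config, rng,
                                             with_ell_head=True)
            self.decoders["atac"] = _Decoder({"logits": n_regions}, nb, config, rng)
            self.r_logit = Tensor(np.zeros(n_regions), requires_grad=True)
        if n_proteins:
            self.encoders["protein"] = _Encoder(n_proteins, nb, config, rng)
            self.decoders["protein"] = _Decoder(
                {"log_beta": n_proteins, "alpha_raw": n_proteins,
                 "pi_logit": n_proteins}, nb, config, rng)
            self.log_theta_bg = Tensor(np.zeros(n_proteins), requires_grad=True)
            self.log_theta_fg = Tensor(np.zeros(n_proteins), requires_grad=True)
        if len(self.encoders) < 1:
            raise ValueError("model needs at least one modality with features")
        # global mixing logits (used by the 'global' scheme)
        self.mix_logits = Tensor(np.zeros(3), requires_grad=True)
        self._enc_list = list(self.encoders.values())
        self._dec_list = list(self.decoders.values())

    # ------------------------------------------------------------------ inputs
    def _batch_onehot(self, batch_codes: np.ndarray) -> np.ndarray:
        if np.any(batch_codes >= len(self.batch_vocab)) or np.any(batch_codes < 0):
            raise KeyError("unknown batch category code")
        oh = np.zeros((len(batch_codes), len(self.batch_vocab)))
        oh[np.arange(len(batch_codes)), batch_codes] = 1.0
        return oh

    @staticmethod
    def _modality_input(dataset: MultiomicDataset, modality: str,
                        idx: np.ndarray) -> np.ndarray:
        if modality == "rna":
            return np.log1p(np.asarray(dataset.rna_counts[idx].todense()))
        if modality == "atac":
            return np.asarray(dataset.atac_binary[idx].todense())
        return np.log1p(np.asarray(dataset.protein_counts[idx].todense()))

    # ------------------------------------------------------------------ encode
    def _encode_t(self, dataset: MultiomicDataset, idx: np.ndarray,
                  rng=None, training=False):
        """Tensor-valued posteriors for the training path."""
        idx = np.asarray(idx)
        codes = dataset.batch_codes[idx]
        oh = self._batch_onehot(codes)
        out: dict[str, tuple[Tensor, Tensor, Tensor | None, Tensor]] = {}
        for m, enc in self.encoders.items():
            x = np.concatenate([self._modality_input(dataset, m, idx), oh], axis=1)
            out[m] = enc(Tensor(x), rng, training)
        return out, oh

    def encode(self, dataset: MultiomicDataset, idx=None) -> LatentState:
        """Posterior parameters for each cell's observed modalities.

        Deterministic (dropout off); cells missing a modality get no posterior
        entry recorded in the mask, and the fused state equals the single
        observed posterior when only one assay is present.
        """
        if idx is None:
            idx = np.arange(dataset.n_cells)
        idx = np.asarray(idx)
        mask = dataset.modality_mask[idx]
        if not mask.any(axis=1).all():
            raise ValueError("cell with no observed modality")
        with no_grad():
            enc_out, _ = self._encode_t(dataset, idx)
        means, variances = {}, {}
        for m, (mu, var, _ell, _w) in enc_out.items():
            means[m] = mu.data
            variances[m] = var.data
        # drop mask bits for modalities the model does not carry
        eff_mask = mask.copy()
        for m in MODALITIES:
            if m not in means:
                eff_mask[:, _MOD_IDX[m]] = False
        state = LatentState(means=means, variances=variances, mask=eff_mask)
        return fuse_latents(state, self.mixing_weights(enc_out, eff_mask))

    def mixing_weights(self, enc_out=None, mask=None) -> MixingWeights:
        cfg = self.config
        if cfg.mixing == "equal":
            return MixingWeights("equal")
        if cfg.mixing == "global":
            w = np.exp(self.mix_logits.data)
            return MixingWeights("global", global_weights=w / w.sum())
        # per_cell: logits from each encoder's weight head
        n = mask.shape[0]
        logits = np.full((n, 3), -np.inf)
        for m, (_mu, _var, _ell, wlogit) in enc_out.items():
            logits[:, _MOD_IDX[m]] = wlogit.data[:, 0]
        logits = np.where(mask, logits, -np.inf)
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w = np.where(mask, w, 0.0)
        return MixingWeights("per_cell", per_cell_weights=w)

    # ------------------------------------------------------------------ decode
    def decode(self, z: np.ndarray, batch_codes: np.ndarray,
               atac_ell: np.ndarray | None = None) -> DecodedParams:
        """Generative parameters from latent coordinates (deterministic)."""
        with no_grad():
            heads = self._decode_t(Tensor(np.asarray(z, float)),
                                   self._batch_onehot(np.asarray(batch_codes)))
        out = DecodedParams()
        if "rna" in heads:
            out.rho = softmax(heads["rna"]["logits"], axis=1).data
            out.theta = np.exp(self.log_theta.data)
        if "atac" in heads:
            out.atac_p = heads["atac"]["logits"].sigmoid().data
            out.atac_r = _sigmoid_np(self.r_logit.data)
            out.atac_ell = atac_ell
        if "protein" in heads:
            out.protein_beta = np.exp(np.clip(heads["protein"]["log_beta"].data,
                                              -12, 12))
            out.protein_alpha = np.logaddexp(0.0, heads["protein"]["alpha_raw"].data)
            out.protein_pi = _sigmoid_np(heads["protein"]["pi_logit"].data)
            out.protein_theta_bg = np.exp(self.log_theta_bg.data)
            out.protein_theta_fg = np.exp(self.log_theta_fg.data)
        return out

    def _decode_t(self, z: Tensor, oh: np.ndarray, rng=None, training=False):
        zin = concat([z, Tensor(oh)], axis=1)
        return {m: dec(zin, rng, training) for m, dec in self.decoders.items()}

    # -------------------------------------------------------------------- ELBO
    def elbo(self, dataset: MultiomicDataset, idx=None, kl_weight: float = 1.0,
             rng: np.random.Generator | None = None, training: bool = False,
             sample_seed: int | None = 0, adversary=None,
             adv_labels: np.ndarray | None = None):
        """Per-minibatch loss decomposition.

        Returns a dict of Tensor scalars: reconstruction NLL per modality,
        KL-to-prior per modality, the consistency penalty, the (optional)
        adversarial term, and their weighted total (all means over the
        minibatch). A cell's masked modality contributes exactly zero to
        every component.
        """
        if idx is None:
            idx = np.arange(dataset.n_cells)
        idx = np.asarray(idx)
        if len(idx) == 0:
            raise ValueError("empty minibatch")
        n = len(idx)
        mask = dataset.modality_mask[idx].astype(float)
        # hide modalities the model does not carry
        for m in MODALITIES:
            if m not in self.encoders:
                mask[:, _MOD_IDX[m]] = 0.0
        enc_out, oh = self._encode_t(dataset, idx, rng, training)

        # fused latent: convex combination of posteriors over observed modalities
        w = self._mixing_weight_tensors(enc_out, mask)
        fmu, fvar = None, None
        for m, (mu, var, _ell, _wl) in enc_out.items():
            wm = w[m]
            fmu = mu * wm if fmu is None else fmu + mu * wm
            fvar = var * wm if fvar is None else fvar + var * wm
        if rng is not None:
            eps_rng = rng
        elif sample_seed is not None:
            eps_rng = np.random.default_rng(sample_seed)
        else:  # deterministic evaluation at the posterior mean
            eps_rng = None
        if eps_rng is None:
            z = fmu
            eps_rng = np.random.default_rng(0)  # only reached by MMD sampling
        else:
            eps = eps_rng.standard_normal(fmu.shape)
            z = fmu + (fvar ** 0.5) * Tensor(eps)
        self._last_fused_mean = fmu.data  # reused by the adversary's own step

        heads = self._decode_t(z, oh, rng, training)
        comps: dict[str, Tensor] = {}

        # ---- reconstruction, masked per modality
        if "rna" in heads:
            x = np.asarray(dataset.rna_counts[idx].todense(), dtype=float)
            lib = x.sum(axis=1, keepdims=True)
            lib = np.where(lib > 0, lib, 1.0)
            rho = softmax(heads["rna"]["logits"], axis=1)
            mu_nb = rho * Tensor(lib)
            theta = self.log_theta.exp()
            ll = _nb_ll_t(x, mu_nb, theta).sum(axis=1)
            comps["recon_rna"] = -(ll * Tensor(mask[:, 0])).sum() * (1.0 / n)
        if "atac" in heads:
            y = np.asarray(dataset.atac_binary[idx].todense())
            p = heads["atac"]["logits"].sigmoid()
            r = self.r_logit.sigmoid()
            ell = enc_out["atac"][2]  # (n, 1) sigmoid head
            q = (p * r * ell).clip_min(_EPS_PROB) * (1.0 - 2 * _EPS_PROB) + _EPS_PROB
            ll = (Tensor(y) * q.log() + Tensor(1.0 - y) * (1.0 - q).log()).sum(axis=1)
            comps["recon_atac"] = -(ll * Tensor(mask[:, 1])).sum() * (1.0 / n)
        if "protein" in heads:
            x = np.asarray(dataset.protein_counts[idx].todense(), dtype=float)
            lib = x.sum(axis=1, keepdims=True)
            ell_p = np.where(lib > 0, lib, 1.0)
            ell_p = ell_p / max(ell_p[mask[:, 2] > 0].mean(), 1.0) \
                if (mask[:, 2] > 0).any() else ell_p
            beta = heads["protein"]["log_beta"] .exp()
            alpha = heads["protein"]["alpha_raw"].softplus()
            pi = heads["protein"]["pi_logit"].sigmoid() * (1 - 2e-6) + 1e-6
            mu_b = (beta * Tensor(ell_p)).clip_min(1e-8)
            mu_f = (alpha * beta * Tensor(ell_p)).clip_min(1e-8)
            th_b, th_f = self.log_theta_bg.exp(), self.log_theta_fg.exp()
            lp_b = pi.log() + _nb_ll_t(x, mu_b, th_b)
            lp_f = (1.0 - pi).log() + _nb_ll_t(x, mu_f, th_f)
            ll = _logaddexp_t(lp_b, lp_f).sum(axis=1)
            comps["recon_protein"] = -(ll * Tensor(mask[:, 2])).sum() * (1.0 / n)

        # ---- KL to the N(0, I) prior, per observed modality posterior
        for m, (mu, var, _ell, _wl) in enc_out.items():
            kl = 0.5 * ((mu * mu + var - var.log()).sum(axis=1) - mu.shape[1])
            comps[f"kl_{m}"] = (kl * Tensor(mask[:, _MOD_IDX[m]])).sum() * (1.0 / n)

        # ---- consistency penalty over modality pairs observed together
        comps["penalty"] = self._penalty_t(enc_out, mask, n, eps_rng)

        # ---- adversarial term: the model is rewarded for confusing the
        # classifier, so its cross-entropy enters with a negative sign
        if adversary is not None and adv_labels is not None \
                and len(np.unique(adv_labels)) >= 2:
            comps["adversarial"] = adversary.cross_entropy(fmu, adv_labels)
        else:
            comps["adversarial"] = Tensor(0.0)

        total = None
        for k, v in comps.items():
            v_w = v
            if k.startswith("kl_"):
                v_w = v * kl_weight
            elif k == "penalty":
                v_w = v * self.config.penalty_weight
            elif k == "adversarial":
                v_w = v * (-self.config.adversarial_weight)
            total = v_w if total is None else total + v_w
        comps["total"] = total
        for k, v in comps.items():
            if not np.all(np.isfinite(np.asarray(v.data))):
                raise FloatingPointError(f"non-finite ELBO component: {k}")
        return comps

    def _mixing_weight_tensors(self, enc_out, mask) -> dict[str, Tensor]:
        cfg = self.config
        mods = list(enc_out.keys())
        if cfg.mixing == "equal":
            m = np.stack([mask[:, _MOD_IDX[x]] for x in mods], axis=1)
            w = m / m.sum(axis=1, keepdims=True)
            return {x: Tensor(w[:, i][:, None]) for i, x in enumerate(mods)}
        if cfg.mixing == "global":
            cols = [_MOD_IDX[x] for x in mods]
            ew = self.mix_logits[cols].exp()  # (k,)
            mt = [Tensor(mask[:, c][:, None]) for c in cols]
            terms = [ew[i:i + 1].reshape(1, 1) * mt[i] for i in range(len(mods))]
            tot = terms[0]
            for t in terms[1:]:
                tot = tot + t
            return {x: terms[i] / tot for i, x in enumerate(mods)}
        # per_cell: softmax over observed modalities of the weight-head logits
        exps = []
        for i, x in enumerate(mods):
            wl = enc_out[x][3]  # (n, 1)
            shifted = wl - Tensor(np.max(wl.data))  # constant shift, stable
            exps.append(shifted.exp() * Tensor(mask[:, _MOD_IDX[x]][:, None]))
        tot = exps[0]
        for t in exps[1:]:
            tot = tot + t
        return {x: exps[i] / tot for i, x in enumerate(mods)}

    def _penalty_t(self, enc_out, mask, n, eps_rng) -> Tensor:
        mods = list(enc_out.keys())
        total = Tensor(0.0)
        for i, a in enumerate(mods):
            for b in mods[i + 1:]:
                both = mask[:, _MOD_IDX[a]] * mask[:, _MOD_IDX[b]]
                if not both.any():
                    continue
                mu_a, var_a = enc_out[a][0], enc_out[a][1]
                mu_b, var_b = enc_out[b][0], enc_out[b][1]
                if self.config.penalty == "symmkl":
                    d2 = (mu_a - mu_b) * (mu_a - mu_b)
                    kl_ab = 0.5 * (((var_b / var_a).log()
                                    + (var_a + d2) / var_b).sum(axis=1)
                                   - mu_a.shape[1])
                    kl_ba = 0.5 * (((var_a / var_b).log()
                                    + (var_b + d2) / var_a).sum(axis=1)
                                   - mu_a.shape[1])
                    pen = kl_ab + kl_ba
                    total = total + (pen * Tensor(both)).sum() * (1.0 / n)
                else:  # mmd on reparameterized samples, cells pooled
                    k = self.config.mmd_samples
                    rows = np.where(both > 0)[0]
                    eps_a = eps_rng.standard_normal((len(rows), k, mu_a.shape[1]))
                    eps_b = eps_rng.standard_normal((len(rows), k, mu_a.shape[1]))
                    sa = _sample_rows(mu_a, var_a, rows, eps_a)
                    sb = _sample_rows(mu_b, var_b, rows, eps_b)
                    total = total + _mmd_t(sa, sb) * (len(rows) / n)
        return total

    # ------------------------------------------------------------- persistence
    def save(self, path: str) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        meta = json.dumps({
            "config": json.loads(self.config.to_json()),
            "n_genes": self.n_genes, "n_regions": self.n_regions,
            "n_proteins": self.n_proteins, "batch_vocab": self.batch_vocab,
            "gene_names": self.gene_names, "region_names": self.region_names,
            "protein_names": self.protein_names,
        })
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "MosaicVAE":
        with np.load(path) as z:
            meta = json.loads(bytes(z["_meta"]).decode())
            model = cls(ModelConfig(**meta["config"]), meta["n_genes"],
                        meta["n_regions"], meta["n_proteins"],
                        meta["batch_vocab"], meta["gene_names"],
                        meta["region_names"], meta["protein_names"])
            for i, p in enumerate(model.parameters()):
                p.data[...] = z[f"param_{i}"]
        return model


# ---------------------------------------------------------------------- helpers

def _sigmoid_np(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, float)))


def _nb_ll_t(x: np.ndarray, mu: Tensor, theta: Tensor) -> Tensor:
    """Negative binomial log-likelihood on tensors; x is a constant array."""
    xt = Tensor(x)
    xpt = xt + theta
    return (xpt.gammaln() - theta.gammaln() - Tensor(_gammaln(x + 1.0))
            + theta * (theta.log() - (theta + mu).log())
            + xt * (mu.clip_min(1e-12).log() - (theta + mu).log()))


def _logaddexp_t(a: Tensor, b: Tensor) -> Tensor:
    m = np.maximum(a.data, b.data)
    mt = Tensor(m)
    return mt + ((a - mt).exp() + (b - mt).exp()).log()


def _sample_rows(mu: Tensor, var: Tensor, rows: np.ndarray,
                 eps: np.ndarray) -> Tensor:
    """Reparameterized samples (len(rows)*k, D) from selected posterior rows."""
    k, d = eps.shape[1], eps.shape[2]
    mu_r = mu.take_rows(rows)
    sd_r = (var.take_rows(rows)) ** 0.5
    out = []
    for j in range(k):
        out.append(mu_r + sd_r * Tensor(eps[:, j, :]))
    return concat(out, axis=0)


def _mmd_t(a: Tensor, b: Tensor) -> Tensor:
    """Biased RBF MMD^2 on tensors with median-heuristic bandwidth (constant)."""
    d2_ab = _pair_sq(a, b)
    with no_grad():
        pooled = np.vstack([a.data, b.data])
        dd = (np.sum(pooled**2, 1)[:, None] + np.sum(pooled**2, 1)[None, :]
              - 2 * pooled @ pooled.T)
        med = np.median(dd[np.triu_indices_from(dd, k=1)])
    g = 1.0 / max(med, 1e-12)
    kaa = ((_pair_sq(a, a)) * (-g)).exp().mean()
    kbb = ((_pair_sq(b, b)) * (-g)).exp().mean()
    kab = (d2_ab * (-g)).exp().mean()
    return (kaa + kbb - kab * 2.0).clip_min(0.0)


def _transpose(t: Tensor) -> Tensor:
    data = t.data.T

    def backward(g):
        t._accum(g.T)

    return Tensor._make(data, (t,), backward)


def _pair_sq(u: Tensor, v: Tensor) -> Tensor:
    u2 = (u * u).sum(axis=1, keepdims=True)          # (n, 1)
    v2 = (v * v).sum(axis=1, keepdims=True)          # (m, 1)
    cross = u @ _transpose(v)                         # (n, m)
    return u2 + _transpose(v2) + cross * (-2.0)
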