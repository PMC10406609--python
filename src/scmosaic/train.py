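"""Training loop: AdamW, KL warm-up, validation split, early stopping and the
adversarial mixing classifier.

The schedule follows the reference protocol for this model family: AdamW with
learning rate 1e-4 and weight decay 1e-3, minibatches of 128 cells, a 90/10
train/validation split, up to 500 epochs with early stopping after 50 epochs
without improvement of the validation reconstruction loss, and a linear KL
warm-up over the first 50 epochs (weight i/50 at epoch i).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._autograd import Tensor
from ._nn import AdamW
from .data import MultiomicDataset
from .model import AdversarialClassifier, ModelConfig, MosaicVAE

__all__ = ["TrainConfig", "TrainState", "split_train_validation",
           "kl_warmup_weight", "adversarial_step", "fit"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 500
    patience: int = 50
    validation_fraction: float = 0.10
    kl_warmup_epochs: int = 50
    adversarial_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if min(self.learning_rate, self.weight_decay, self.adversarial_lr) <= 0:
            raise ValueError("rates must be positive")


@dataclass
class TrainState:
    epoch: int = 0
    history: list[dict] = field(default_factory=list)
    best_validation: float = np.inf
    best_epoch: int = -1
    stopped_early: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def split_train_validation(dataset: MultiomicDataset, fraction: float,
                           seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Simple random split into disjoint, exhaustive train/validation indices.

    The validation size is round(fraction * N), floored at 1.
    """
    n = dataset.n_cells
    if n < 10:
        raise ValueError("need at least 10 cells to split")
    n_val = max(1, int(round(fraction * n)))
    if n_val >= n:
        raise ValueError("validation fraction leaves no training cells")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def kl_warmup_weight(epoch: int, warmup_epochs: int = 50) -> float:
    """Linear warm-up: epoch/warmup for the first `warmup_epochs`, then 1."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    return min(epoch / warmup_epochs, 1.0)


def _group_labels(dataset: MultiomicDataset, grouping: str) -> np.ndarray:
    if grouping == "batch":
        return dataset.batch_codes
    if grouping == "modality":
        pats = dataset.modality_pattern()
        _, codes = np.unique(pats, return_inverse=True)
        return codes
    raise ValueError("adversarial grouping must be 'modality' or 'batch'")


def adversarial_step(adversary: AdversarialClassifier, adv_opt: AdamW,
                     fused: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One classifier update on detached latents.

    Returns (classifier cross-entropy after the forward pass, adversarial
    penalty value = the same cross-entropy, which the model maximizes).
    Minibatches with a single group contribute nothing.
    """
    if len(np.unique(labels)) < 2:
        return 0.0, 0.0
    adv_opt.zero_grad()
    ce = adversary.cross_entropy(Tensor(fused), labels)
    ce.backward()
    adv_opt.step()
    return float(ce.data), float(ce.data)


def fit(dataset: MultiomicDataset, model_config: ModelConfig,
        train_config: TrainConfig, verbose: bool = False
        ) -> tuple[MosaicVAE, TrainState]:
    """Train a :class:`MosaicVAE` on a mosaic multi-omic dataset.

    Validation reconstruction loss (negative log-likelihood of the observed
    modalities, penalty terms excluded) drives early stopping; the best
    parameters are restored on exit. Fully reproducible from the two seeds on
    a single thread.
    """
    mc = model_config
    # disable modalities without features or without any observing cell
    n_genes = dataset.n_genes if dataset.modality_mask[:, 0].any() else 0
    n_regions = dataset.n_regions if dataset.modality_mask[:, 1].any() else 0
    n_proteins = dataset.n_proteins if dataset.modality_mask[:, 2].any() else 0
    model = MosaicVAE(mc, n_genes, n_regions, n_proteins, dataset.batch_vocab,
                      dataset.gene_names, dataset.region_names,
                      dataset.protein_names)
    train_idx, val_idx = split_train_validation(
        dataset, train_config.validation_fraction, train_config.seed)
    opt = AdamW(model.parameters(), lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)

    adversary = adv_opt = None
    adv_labels_all = None
    if mc.adversarial_weight > 0:
        labels = _group_labels(dataset, mc.adversarial_grouping)
        n_groups = int(labels.max()) + 1
        if n_groups >= 2:
            adversary = AdversarialClassifier(
                mc.latent_dim, n_groups, np.random.default_rng(mc.seed + 1))
            adv_opt = AdamW(adversary.parameters(), lr=train_config.adversarial_lr,
                            weight_decay=0.0)
            adv_labels_all = labels

    rng = np.random.default_rng(train_config.seed)
    state = TrainState()
    best_params = [p.data.copy() for p in model.parameters()]
    bad_epochs = 0
    bs = train_config.batch_size

    for epoch in range(1, train_config.max_epochs + 1):
        klw = kl_warmup_weight(epoch, train_config.kl_warmup_epochs)
        order = rng.permutation(train_idx)
        ep_log: dict[str, float] = {}
        n_steps = 0
        for start in range(0, len(order), bs):
            mb = order[start:start + bs]
            if len(mb) < 2:
                continue
            opt.zero_grad()
            if adversary is not None:
                adversary.zero_grad()
            labels_mb = adv_labels_all[mb] if adversary is not None else None
            try:
                comps = model.elbo(dataset, mb, kl_weight=klw, rng=rng,
                                   training=True, adversary=adversary,
                                   adv_labels=labels_mb)
            except FloatingPointError:
                state.stopped_early = True
                if verbose:
                    print(f"epoch {epoch}: non-finite loss, aborting")
                _restore(model, best_params)
                return model, state
            comps["total"].backward()
            opt.step()
            if adversary is not None:
                adversarial_step(adversary, adv_opt, model._last_fused_mean,
                                 labels_mb)
            for k, v in comps.items():
                ep_log[k] = ep_log.get(k, 0.0) + float(np.asarray(v.data))
            n_steps += 1
        for k in ep_log:
            ep_log[k] /= max(n_steps, 1)

        val_recon = _validation_reconstruction(model, dataset, val_idx, bs)
        ep_log["val_recon"] = val_recon
        ep_log["epoch"] = epoch
        state.history.append(ep_log)
        state.epoch = epoch
        if verbose:
            print(f"epoch {epoch}: train total {ep_log.get('total', 0):.3f} "
                  f"val recon {val_recon:.3f}")
        if val_recon < state.best_validation:
            state.best_validation = val_recon
            state.best_epoch = epoch
            best_params = [p.data.copy() for p in model.parameters()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= train_config.patience:
                state.stopped_early = True
                break

    _restore(model, best_params)
    return model, state


def _restore(model: MosaicVAE, params: list[np.ndarray]) -> None:
    for p, saved in zip(model.parameters(), params):
        p.data[...] = saved


def _validation_reconstruction(model: MosaicVAE, dataset: MultiomicDataset,
                               val_idx: np.ndarray, batch_size: int) -> float:
    """Mean per-cell NLL of observed modalities on the validation set.

    Uses the posterior-mean latent (no sampling) so the criterion is
    deterministic across epochs.
    """
    total = 0.0
    n = 0
    from ._autograd import no_grad
    with no_grad():
        for start in range(0, len(val_idx), batch_size):
            mb = val_idx[start:start + batch_size]
            comps = model.elbo(dataset, mb, kl_weight=0.0, sample_seed=None,
                               rng=None)
            recon = sum(float(np.asarray(v.data))
                        for k, v in comps.items() if k.startswith("recon_"))
            total += recon * len(mb)
            n += len(mb)
    return total / max(n, 1)
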