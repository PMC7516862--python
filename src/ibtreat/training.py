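"""Seeded optimisation loop: Adam, temperature annealing, early stopping.

Teacher forcing is used throughout: the outcome head always receives the
observed treatment during training. Validation is evaluated with noise-free
hard codes at the final temperature, and the returned parameters are the
snapshot with the lowest validation total loss (ties broken by the earlier
epoch). All stochasticity — splitting, batching, Gumbel and embedding noise,
initialisation — derives from the single configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSplitError, InvalidArgumentError, TrainingDivergedError
from .model import LatentConfig, ModelParams
from .objective import LossComponents, hard_loss, ib_loss_graph
from .simulate import ObservationalDataset


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser and schedule settings.

    Defaults follow the study conditions: Adam with learning rate 0.001 and a
    60/10/30 train/validation/test split. ``lam`` is the relevance multiplier
    (its default 13.0 sits on the saturated part of the information curve).
    """

    learning_rate: float = 0.001
    epochs: int = 300
    batch_size: int = 128
    lam: float = 13.0
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)
    outcome_family: str = "gaussian"
    patience: int = 50
    grad_clip: float = 5.0
    lr_decay: float = 1.0  # geometric per-epoch factor on the learning rate
    allow_empty_splits: bool = False

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise InvalidArgumentError("learning_rate must be positive")
        if self.batch_size < 1:
            raise InvalidArgumentError("batch_size must be >= 1")
        if self.lam < 0:
            raise InvalidArgumentError("lambda must be non-negative")
        if not 0 < self.lr_decay <= 1.0:
            raise InvalidArgumentError("lr_decay must be in (0, 1]")
        f = self.split_fractions
        if len(f) != 3 or any(v < 0 for v in f) or abs(sum(f) - 1.0) > 1e-9:
            raise InvalidArgumentError(
                "split_fractions must be 3 non-negative values summing to 1"
            )


@dataclass
class TrainHistory:
    """Per-epoch loss traces and the annealing schedule actually used."""

    train: list[LossComponents] = field(default_factory=list)
    validation: list[LossComponents] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    steps: int = 0
    best_epoch: int = -1


def split_dataset(dataset: ObservationalDataset,
                  fractions: tuple[float, float, float], seed: int,
                  allow_empty: bool = False):
    """Disjoint, exhaustive, seeded train/validation/test partition.

    Raises DegenerateSplitError when the training split would lack treated or
    control units. Empty validation/test splits are only allowed when
    ``allow_empty`` is set.
    """
    if dataset.n < 10:
        raise InvalidArgumentError("need at least 10 records to split")
    f = tuple(fractions)
    if len(f) != 3 or any(v < 0 for v in f) or abs(sum(f) - 1.0) > 1e-9:
        raise InvalidArgumentError("invalid split fractions")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n)
    n_train = int(round(f[0] * dataset.n))
    n_val = int(round(f[1] * dataset.n))
    idx_train = perm[:n_train]
    idx_val = perm[n_train:n_train + n_val]
    idx_test = perm[n_train + n_val:]
    if (idx_val.size == 0 or idx_test.size == 0) and not allow_empty:
        raise DegenerateSplitError(
            "empty validation/test split; pass allow_empty to permit this"
        )
    t_train = dataset.t[idx_train]
    if idx_train.size == 0 or t_train.sum() == 0 or t_train.sum() == t_train.size:
        raise DegenerateSplitError("training split lacks treated or control units")
    return dataset.subset(idx_train), dataset.subset(idx_val), dataset.subset(idx_test)


class _Adam:
    def __init__(self, tensors, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(t.data) for t in tensors]
        self.v = [np.zeros_like(t.data) for t in tensors]
        self.step_count = 0

    def step(self, grad_clip: float | None):
        grads = [t.grad if t.grad is not None else np.zeros_like(t.data)
                 for t in self.tensors]
        if grad_clip is not None:
            norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
            if norm > grad_clip:
                grads = [g * (grad_clip / norm) for g in grads]
        self.step_count += 1
        b1t = 1.0 - self.b1**self.step_count
        b2t = 1.0 - self.b2**self.step_count
        for t, g, m, v in zip(self.tensors, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            t.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit(dataset: ObservationalDataset, train_config: TrainConfig,
        latent_config: LatentConfig) -> tuple[ModelParams, TrainHistory]:
    """Train the bottleneck model; returns best-validation parameters.

    The dataset is split according to the config; test records never reach a
    parameter update. If the validation split is empty (allowed only with
    ``allow_empty_splits``), model selection falls back to the training loss.
    """
    cfg = train_config
    train, val, _test = split_dataset(dataset, cfg.split_fractions, cfg.seed,
                                      allow_empty=cfg.allow_empty_splits)
    family = dataset.outcome_family
    if cfg.outcome_family != family:
        raise InvalidArgumentError(
            f"config outcome_family {cfg.outcome_family!r} does not match "
            f"dataset family {family!r}"
        )

    master = np.random.SeedSequence(cfg.seed)
    init_seed, shuffle_seed, noise_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )
    params = ModelParams.init(
        d1=train.x1.shape[1], d2=train.x2.shape[1],
        latent=latent_config, outcome_family=family, seed=init_seed,
    )
    params.set_standardisation(train.x1, train.x2)
    if family == "gaussian":
        params.outcome_logvar.data = np.asarray(
            np.log(max(float(np.var(train.y)), 1e-6))
        )

    opt = _Adam(params.tensors(), cfg.learning_rate)
    shuffler = np.random.default_rng(shuffle_seed)
    noise_rng = np.random.default_rng(noise_seed)
    history = TrainHistory()
    best = (np.inf, -1, None)  # (val total, epoch, snapshot)
    n_train = train.n

    for epoch in range(cfg.epochs):
        tau = latent_config.temperature_at(epoch)
        opt.lr = cfg.learning_rate * cfg.lr_decay**epoch
        order = shuffler.permutation(n_train)
        epoch_comps = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_seed = int(noise_rng.integers(0, 2**31))
            total, comps = ib_loss_graph(
                params, train.x1[idx], train.x2[idx], train.t[idx],
                train.y[idx], cfg.lam, tau, batch_seed,
            )
            if not np.isfinite(total.data):
                raise TrainingDivergedError(epoch)
            for tsr in params.tensors():
                tsr.zero_grad()
            total.backward()
            opt.step(cfg.grad_clip)
            epoch_comps.append(comps)
            history.steps += 1

        train_comp = LossComponents(
            kl_branch1=float(np.mean([c.kl_branch1 for c in epoch_comps])),
            kl_branch2=float(np.mean([c.kl_branch2 for c in epoch_comps])),
            nll_outcome=float(np.mean([c.nll_outcome for c in epoch_comps])),
            nll_treatment=float(np.mean([c.nll_treatment for c in epoch_comps])),
            lam=cfg.lam,
            total=float(np.mean([c.total for c in epoch_comps])),
        )
        eval_split = val if val.n > 0 else train
        val_comp = hard_loss(params, eval_split.x1, eval_split.x2,
                             eval_split.t, eval_split.y, cfg.lam)
        history.train.append(train_comp)
        history.validation.append(val_comp)
        history.temperature.append(tau)

        if val_comp.total < best[0]:  # strict: ties keep the earlier epoch
            best = (val_comp.total, epoch, params.copy())
        elif epoch - best[1] >= cfg.patience:
            break

    history.best_epoch = best[1]
    return best[2], history
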