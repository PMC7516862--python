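"""Encoder branches, discrete latent codes, and the two-headed outcome decoder.

The model compresses two covariate blocks into one categorical code each via
Gumbel-softmax relaxation. Each category owns a learned Gaussian embedding
(mean and scale); the continuous representation z fed to the decoder is the
relaxation-weighted mixture of the component means (training) or the selected
component mean (evaluation). The decoder follows the two-headed
counterfactual-regression layout: a shared representation z with separate
outcome heads for the treated and control arms, plus a treatment head used to
keep the joint distribution over (t, y, z) identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, elu, log_softmax
from .errors import InvalidArgumentError, ShapeError

CHECKPOINT_SCHEMA_VERSION = 1
SCALE_FLOOR = 1e-3  # additive floor on component scales (kept strictly positive)
DEFAULT_HIDDEN = 64
DEFAULT_DEPTH = 3


# --------------------------------------------------------------------------
# configuration and parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LatentConfig:
    """Sizes and temperature schedule of the discrete latent space.

    k1, k2 : number of mixture components (categories) per encoder branch.
    embed_dim : dimension of each component's Gaussian embedding.
    temperature_init/final : Gumbel-softmax temperature annealed geometrically
        over ``anneal_epochs`` epochs, then held at the final value.
    """

    k1: int = 4
    k2: int = 4
    embed_dim: int = 3
    temperature_init: float = 1.0
    temperature_final: float = 0.5
    anneal_epochs: int = 100

    def __post_init__(self):
        if self.k1 < 1 or self.k2 < 1 or self.embed_dim < 1:
            raise InvalidArgumentError("k1, k2 and embed_dim must all be >= 1")
        if not (0 < self.temperature_final <= self.temperature_init):
            raise InvalidArgumentError(
                "need 0 < temperature_final <= temperature_init"
            )
        if self.anneal_epochs < 1:
            raise InvalidArgumentError("anneal_epochs must be >= 1")

    def temperature_at(self, epoch: int) -> float:
        frac = min(epoch / self.anneal_epochs, 1.0)
        ratio = self.temperature_final / self.temperature_init
        return self.temperature_init * ratio**frac


@dataclass
class LatentCode:
    """One encoder branch's output for a batch (or a single record).

    probs : softmax of the encoder logits (categorical posterior).
    gumbels : the Gumbel(0,1) noise used for the sample.
    relaxed : temperature-relaxed simplex sample.
    hard : one-hot of argmax(logits + gumbels).
    z : continuous embedding (mixture of component means).
    """

    probs: np.ndarray
    gumbels: np.ndarray
    relaxed: np.ndarray
    hard: np.ndarray
    z: np.ndarray


def _mlp_init(rng: np.random.Generator, d_in: int, d_out: int,
              hidden: int, depth: int) -> list[tuple[Tensor, Tensor]]:
    layers = []
    sizes = [d_in] + [hidden] * depth + [d_out]
    for a, b in zip(sizes[:-1], sizes[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
        layers.append((Tensor(w, requires_grad=True),
                       Tensor(np.zeros(b), requires_grad=True)))
    return layers


def _mlp_forward(layers: list[tuple[Tensor, Tensor]], x: Tensor) -> Tensor:
    h = x
    for i, (w, b) in enumerate(layers):
        h = h @ w + b
        if i < len(layers) - 1:
            h = elu(h)
    return h


@dataclass
class ModelParams:
    """All trainable parameters plus frozen standardisation statistics."""

    latent: LatentConfig
    outcome_family: str  # "gaussian" | "bernoulli"
    encoder1: list
    encoder2: list
    means1: Tensor  # (k1, embed_dim)
    logscales1: Tensor
    means2: Tensor  # (k2, embed_dim)
    logscales2: Tensor
    head_treatment: list  # f1: z -> logit
    head_treated: list  # f2: z -> outcome (treated arm)
    head_control: list  # f3: z -> outcome (control arm)
    outcome_logvar: Tensor  # scalar, gaussian family only
    x1_mean: np.ndarray = field(default=None)
    x1_std: np.ndarray = field(default=None)
    x2_mean: np.ndarray = field(default=None)
    x2_std: np.ndarray = field(default=None)

    @classmethod
    def init(cls, d1: int, d2: int, latent: LatentConfig,
             outcome_family: str = "gaussian", seed: int = 0,
             hidden: int = DEFAULT_HIDDEN, depth: int = DEFAULT_DEPTH) -> "ModelParams":
        if outcome_family not in ("gaussian", "bernoulli"):
            raise InvalidArgumentError(f"unknown outcome family {outcome_family!r}")
        if d1 < 1 or d2 < 1:
            raise InvalidArgumentError("both covariate blocks must be non-empty")
        rng = np.random.default_rng(seed)
        e = latent.embed_dim
        return cls(
            latent=latent,
            outcome_family=outcome_family,
            encoder1=_mlp_init(rng, d1, latent.k1, hidden, depth),
            encoder2=_mlp_init(rng, d2, latent.k2, hidden, depth),
            means1=Tensor(rng.normal(0.0, 1.0, size=(latent.k1, e)), requires_grad=True),
            logscales1=Tensor(np.full((latent.k1, e), -2.0), requires_grad=True),
            means2=Tensor(rng.normal(0.0, 1.0, size=(latent.k2, e)), requires_grad=True),
            logscales2=Tensor(np.full((latent.k2, e), -2.0), requires_grad=True),
            head_treatment=_mlp_init(rng, 2 * e, 1, hidden, depth),
            head_treated=_mlp_init(rng, 2 * e, 1, hidden, depth),
            head_control=_mlp_init(rng, 2 * e, 1, hidden, depth),
            outcome_logvar=Tensor(0.0, requires_grad=True),
            x1_mean=np.zeros(d1), x1_std=np.ones(d1),
            x2_mean=np.zeros(d2), x2_std=np.ones(d2),
        )

    # -- plumbing ---------------------------------------------------------

    def tensors(self) -> list[Tensor]:
        out = []
        for net in (self.encoder1, self.encoder2, self.head_treatment,
                    self.head_treated, self.head_control):
            for w, b in net:
                out.extend([w, b])
        out.extend([self.means1, self.logscales1, self.means2, self.logscales2,
                    self.outcome_logvar])
        return out

    def copy(self) -> "ModelParams":
        def copy_net(net):
            return [(Tensor(w.data.copy(), requires_grad=True),
                     Tensor(b.data.copy(), requires_grad=True)) for w, b in net]

        return ModelParams(
            latent=self.latent, outcome_family=self.outcome_family,
            encoder1=copy_net(self.encoder1), encoder2=copy_net(self.encoder2),
            means1=Tensor(self.means1.data.copy(), requires_grad=True),
            logscales1=Tensor(self.logscales1.data.copy(), requires_grad=True),
            means2=Tensor(self.means2.data.copy(), requires_grad=True),
            logscales2=Tensor(self.logscales2.data.copy(), requires_grad=True),
            head_treatment=copy_net(self.head_treatment),
            head_treated=copy_net(self.head_treated),
            head_control=copy_net(self.head_control),
            outcome_logvar=Tensor(self.outcome_logvar.data.copy(), requires_grad=True),
            x1_mean=self.x1_mean.copy(), x1_std=self.x1_std.copy(),
            x2_mean=self.x2_mean.copy(), x2_std=self.x2_std.copy(),
        )

    def set_standardisation(self, x1: np.ndarray, x2: np.ndarray) -> None:
        """Freeze feature standardisation statistics from training covariates."""
        self.x1_mean = x1.mean(axis=0)
        self.x1_std = np.where(x1.std(axis=0) > 1e-12, x1.std(axis=0), 1.0)
        self.x2_mean = x2.mean(axis=0)
        self.x2_std = np.where(x2.std(axis=0) > 1e-12, x2.std(axis=0), 1.0)

    def to_dict(self) -> dict:
        def net_to_list(net):
            return [[w.data.tolist(), b.data.tolist()] for w, b in net]

        return {
            "schema_version": CHECKPOINT_SCHEMA_VERSION,
            "latent": {
                "k1": self.latent.k1, "k2": self.latent.k2,
                "embed_dim": self.latent.embed_dim,
                "temperature_init": self.latent.temperature_init,
                "temperature_final": self.latent.temperature_final,
                "anneal_epochs": self.latent.anneal_epochs,
            },
            "outcome_family": self.outcome_family,
            "encoder1": net_to_list(self.encoder1),
            "encoder2": net_to_list(self.encoder2),
            "means1": self.means1.data.tolist(),
            "logscales1": self.logscales1.data.tolist(),
            "means2": self.means2.data.tolist(),
            "logscales2": self.logscales2.data.tolist(),
            "head_treatment": net_to_list(self.head_treatment),
            "head_treated": net_to_list(self.head_treated),
            "head_control": net_to_list(self.head_control),
            "outcome_logvar": float(self.outcome_logvar.data),
            "x1_mean": self.x1_mean.tolist(), "x1_std": self.x1_std.tolist(),
            "x2_mean": self.x2_mean.tolist(), "x2_std": self.x2_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        if d.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise InvalidArgumentError(
                f"unsupported checkpoint schema version {d.get('schema_version')!r}"
            )

        def net_from_list(lst):
            return [(Tensor(np.array(w), requires_grad=True),
                     Tensor(np.array(b), requires_grad=True)) for w, b in lst]

        return cls(
            latent=LatentConfig(**d["latent"]),
            outcome_family=d["outcome_family"],
            encoder1=net_from_list(d["encoder1"]),
            encoder2=net_from_list(d["encoder2"]),
            means1=Tensor(np.array(d["means1"]), requires_grad=True),
            logscales1=Tensor(np.array(d["logscales1"]), requires_grad=True),
            means2=Tensor(np.array(d["means2"]), requires_grad=True),
            logscales2=Tensor(np.array(d["logscales2"]), requires_grad=True),
            head_treatment=net_from_list(d["head_treatment"]),
            head_treated=net_from_list(d["head_treated"]),
            head_control=net_from_list(d["head_control"]),
            outcome_logvar=Tensor(d["outcome_logvar"], requires_grad=True),
            x1_mean=np.array(d["x1_mean"]), x1_std=np.array(d["x1_std"]),
            x2_mean=np.array(d["x2_mean"]), x2_std=np.array(d["x2_std"]),
        )

    # -- branch helpers ----------------------------------------------------

    def branch(self, which: int):
        """Return (encoder, means, logscales, standardise) for branch 1 or 2."""
        if which == 1:
            return (self.encoder1, self.means1, self.logscales1,
                    (self.x1_mean, self.x1_std))
        if which == 2:
            return (self.encoder2, self.means2, self.logscales2,
                    (self.x2_mean, self.x2_std))
        raise InvalidArgumentError("branch must be 1 or 2")


# --------------------------------------------------------------------------
# Gumbel-softmax
# --------------------------------------------------------------------------


def gumbel_softmax(logits: np.ndarray, temperature: float,
                   noise: np.ndarray) -> np.ndarray:
    """Temperature-relaxed categorical sample on the probability simplex.

    w_i = exp((logits_i + g_i)/tau) / sum_j exp((logits_j + g_j)/tau), with the
    Gumbel(0,1) noise supplied by the caller for determinism. As tau -> 0 the
    output converges to the one-hot of argmax(logits + noise).
    """
    logits = np.asarray(logits, dtype=np.float64)
    noise = np.asarray(noise, dtype=np.float64)
    if not temperature > 0:
        raise InvalidArgumentError("temperature must be positive")
    if not (np.all(np.isfinite(logits)) and np.all(np.isfinite(noise))):
        raise InvalidArgumentError("logits and noise must be finite")
    if logits.shape != noise.shape:
        raise ShapeError(f"logits {logits.shape} vs noise {noise.shape}")
    scaled = (logits + noise) / temperature
    scaled = scaled - scaled.max(axis=-1, keepdims=True)
    w = np.exp(scaled)
    return w / w.sum(axis=-1, keepdims=True)


def sample_gumbel(rng: np.random.Generator, shape) -> np.ndarray:
    u = rng.uniform(low=np.finfo(np.float64).tiny, high=1.0, size=shape)
    return -np.log(-np.log(u))


# --------------------------------------------------------------------------
# tensor-graph forward passes (shared by public API and the training loss)
# --------------------------------------------------------------------------


def branch_forward(params: ModelParams, which: int, x_block: np.ndarray,
                   temperature: float, gumbels: np.ndarray,
                   embed_noise: np.ndarray | None):
    """Differentiable branch pass: returns (log_probs, relaxed_w, z) Tensors.

    ``embed_noise`` of shape (n, embed_dim) activates the reparameterised
    Gaussian embedding noise (training); None gives the noiseless mixture.
    """
    encoder, means, logscales, (mu, sd) = params.branch(which)
    x_std = (np.asarray(x_block, dtype=np.float64) - mu) / sd
    logits = _mlp_forward(encoder, Tensor(x_std))
    logp = log_softmax(logits, axis=-1)
    w = ((logits + Tensor(gumbels)) * (1.0 / temperature))
    w = log_softmax(w, axis=-1).exp()
    z = w @ means
    if embed_noise is not None:
        scales = logscales.exp() + SCALE_FLOOR
        z = z + Tensor(embed_noise) * (w @ scales)
    return logp, w, z


def _head_scalar(net, z: Tensor) -> Tensor:
    out = _mlp_forward(net, z)
    return out.reshape(out.shape[0])


def encode(x_block: np.ndarray, branch: int, params: ModelParams,
           temperature: float, seed: int = 0, hard: bool = False) -> LatentCode:
    """Encode one covariate block into a discrete latent code.

    With ``hard=True`` (evaluation) z is the selected component mean; with
    ``hard=False`` (training-style) z is the relaxed mixture plus Gaussian
    embedding noise. Pure function of (input, params, temperature, seed).
    """
    x = np.atleast_2d(np.asarray(x_block, dtype=np.float64))
    single = np.asarray(x_block).ndim == 1
    encoder, means, logscales, (mu, sd) = params.branch(branch)
    d_expected = encoder[0][0].shape[0]
    if x.shape[1] != d_expected:
        raise ShapeError(
            f"branch {branch} expects {d_expected} columns, got {x.shape[1]}"
        )
    if not temperature > 0:
        raise InvalidArgumentError("temperature must be positive")
    k = means.shape[0]
    rng = np.random.default_rng(seed)
    gumbels = sample_gumbel(rng, (x.shape[0], k))
    embed_noise = rng.standard_normal((x.shape[0], means.shape[1]))

    logp, w, _ = branch_forward(params, branch, x, temperature, gumbels, None)
    logits = logp.data  # log-softmax preserves argmax and softmax
    probs = np.exp(logits)
    relaxed = w.data
    hard_idx = np.argmax(logits + gumbels, axis=-1)
    hard_onehot = np.eye(k)[hard_idx]
    if hard:
        z = means.data[hard_idx]
    else:
        scales = np.exp(logscales.data) + SCALE_FLOOR
        z = relaxed @ means.data + embed_noise * (relaxed @ scales)

    def maybe_squeeze(a):
        return a[0] if single else a

    return LatentCode(
        probs=maybe_squeeze(probs), gumbels=maybe_squeeze(gumbels),
        relaxed=maybe_squeeze(relaxed), hard=maybe_squeeze(hard_onehot),
        z=maybe_squeeze(z),
    )


def hard_assignments(params: ModelParams, x_block: np.ndarray,
                     branch: int) -> np.ndarray:
    """Noise-free maximum-probability category per record (cluster labels)."""
    x = np.atleast_2d(np.asarray(x_block, dtype=np.float64))
    encoder, _, _, (mu, sd) = params.branch(branch)
    if x.shape[1] != encoder[0][0].shape[0]:
        raise ShapeError(
            f"branch {branch} expects {encoder[0][0].shape[0]} columns, "
            f"got {x.shape[1]}"
        )
    logits = _mlp_forward(encoder, Tensor((x - mu) / sd)).data
    return np.argmax(logits, axis=-1)


@dataclass
class OutcomePrediction:
    """Decoded outcome distribution: mean and variance.

    Gaussian family: mean is the selected head's output, variance = exp(s).
    Bernoulli family: mean is the event probability, variance = p(1-p).
    """

    mean: np.ndarray
    variance: np.ndarray


def decode_outcome(z: np.ndarray, t, params: ModelParams) -> OutcomePrediction:
    """Predict the outcome under treatment arm t via the two-headed decoder.

    mean(z, t) = t*f_treated(z) + (1-t)*f_control(z).
    """
    z_arr = np.atleast_2d(np.asarray(z, dtype=np.float64))
    single = np.asarray(z).ndim == 1
    t_arr = np.asarray(t)
    if not np.all(np.isin(t_arr, (0, 1))):
        raise InvalidArgumentError("treatment must be binary 0/1")
    t_vec = np.broadcast_to(t_arr.astype(np.float64), (z_arr.shape[0],))
    f2 = _head_scalar(params.head_treated, Tensor(z_arr)).data
    f3 = _head_scalar(params.head_control, Tensor(z_arr)).data
    raw = t_vec * f2 + (1.0 - t_vec) * f3
    if params.outcome_family == "gaussian":
        mean = raw
        var = np.full_like(mean, np.exp(float(params.outcome_logvar.data)))
    else:
        mean = 0.5 * (1.0 + np.tanh(0.5 * raw))
        var = mean * (1.0 - mean)
    if single:
        return OutcomePrediction(mean=mean[0], variance=var[0])
    return OutcomePrediction(mean=mean, variance=var)


def decode_treatment(z: np.ndarray, params: ModelParams) -> np.ndarray:
    """Propensity of treatment given the latent embedding: sigma(f1(z))."""
    z_arr = np.atleast_2d(np.asarray(z, dtype=np.float64))
    single = np.asarray(z).ndim == 1
    logit = _head_scalar(params.head_treatment, Tensor(z_arr)).data
    p = 0.5 * (1.0 + np.tanh(0.5 * logit))
    return p[0] if single else p
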