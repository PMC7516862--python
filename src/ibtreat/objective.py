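"""The compression/relevance trade-off objective.

Minimised form: KL1 + KL2 + lambda * (NLL_outcome + NLL_treatment), where the
two KL terms are variational upper bounds on the mutual information between
each covariate block and its discrete code (posterior-vs-prior KL averaged
over the batch), and the two negative log-likelihood terms form a lower bound
on the relevance I(Z; (Y, T)) up to the constant entropy H(y, t), which is
dropped because it does not depend on any parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, softplus
from .errors import InfiniteKLError, InvalidArgumentError, ShapeError
from .model import (
    LatentCode,
    ModelParams,
    _head_scalar,
    branch_forward,
    decode_outcome,
    decode_treatment,
    hard_assignments,
    sample_gumbel,
)

LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class LossComponents:
    """Additive pieces of the objective, all in nats.

    total = kl_branch1 + kl_branch2 + lam * (nll_outcome + nll_treatment).
    """

    kl_branch1: float
    kl_branch2: float
    nll_outcome: float
    nll_treatment: float
    lam: float
    total: float

    def __post_init__(self):
        if self.kl_branch1 < -1e-9 or self.kl_branch2 < -1e-9:
            raise InvalidArgumentError("compression KL terms must be non-negative")


def compression_kl(posterior_probs: np.ndarray, prior_probs: np.ndarray) -> float:
    """KL(q || p) in nats for categorical distributions, with 0*log(0/p) = 0.

    Raises InfiniteKLError where the prior has zero mass but the posterior
    does not (the divergence would be infinite).
    """
    q = np.asarray(posterior_probs, dtype=np.float64)
    p = np.asarray(prior_probs, dtype=np.float64)
    if q.shape != p.shape:
        raise ShapeError(f"posterior {q.shape} vs prior {p.shape}")
    for name, v in (("posterior", q), ("prior", p)):
        if np.any(v < -1e-9) or not np.allclose(v.sum(axis=-1), 1.0, atol=1e-6):
            raise InvalidArgumentError(f"{name} is not on the probability simplex")
    if np.any((p <= 0) & (q > 0)):
        raise InfiniteKLError("prior has zero mass where the posterior has mass")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(q > 0, q * (np.log(np.where(q > 0, q, 1.0)) - np.log(p)), 0.0)
    return float(terms.sum(axis=-1)) if q.ndim == 1 else terms.sum(axis=-1)


def _gaussian_nll(y: np.ndarray, mean, logvar) -> float:
    resid2 = (y - mean) ** 2
    return 0.5 * float(np.mean(LOG_2PI + logvar + resid2 * np.exp(-logvar)))


def _bernoulli_nll(target: np.ndarray, prob: np.ndarray) -> float:
    p = np.clip(prob, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p)))


def relevance_terms(batch, params: ModelParams, latent_samples) -> tuple[float, float]:
    """Teacher-forced relevance terms from given latent embeddings.

    ``batch`` is (x, t, y) with x unused here (the embeddings already encode
    it); ``latent_samples`` is a list of LatentCode (one per record, with the
    concatenated z) or an (n, 2*embed_dim) array. Returns
    (-mean log p(y|t,z), -mean log p(t|z)).
    """
    _, t, y = batch
    t = np.asarray(t, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if t.size == 0:
        raise InvalidArgumentError("empty batch")
    if isinstance(latent_samples, (list, tuple)) and latent_samples and isinstance(
        latent_samples[0], LatentCode
    ):
        z = np.stack([c.z for c in latent_samples])
    else:
        z = np.atleast_2d(np.asarray(latent_samples, dtype=np.float64))
    if z.shape[0] != t.size:
        raise ShapeError("one latent sample per record is required")

    pred = decode_outcome(z, t.astype(int), params)
    if params.outcome_family == "gaussian":
        nll_y = _gaussian_nll(y, pred.mean, float(params.outcome_logvar.data))
    else:
        nll_y = _bernoulli_nll(y, pred.mean)
    prop = decode_treatment(z, params)
    nll_t = _bernoulli_nll(t, prop)
    return nll_y, nll_t


def _kl_to_prior(logp: Tensor, prior: np.ndarray) -> Tensor:
    """Batch-mean KL(q || prior) from a log-softmax Tensor (differentiable)."""
    q = logp.exp()
    return (q * (logp - Tensor(np.log(prior)))).sum(axis=-1).mean()


def ib_loss_graph(params: ModelParams, x1, x2, t, y, lam: float,
                  temperature: float, seed: int,
                  prior1: np.ndarray | None = None,
                  prior2: np.ndarray | None = None):
    """Differentiable loss graph; returns (total Tensor, LossComponents).

    All sampling noise (Gumbel and embedding) derives from ``seed`` so the
    loss is a deterministic, differentiable function of the parameters —
    repeated calls with identical arguments rebuild the identical graph.
    """
    if lam < 0:
        raise InvalidArgumentError("lambda must be non-negative")
    x1 = np.atleast_2d(np.asarray(x1, dtype=np.float64))
    x2 = np.atleast_2d(np.asarray(x2, dtype=np.float64))
    t = np.asarray(t, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = x1.shape[0]
    if n == 0:
        raise InvalidArgumentError("empty batch")
    k1, k2 = params.latent.k1, params.latent.k2
    e = params.latent.embed_dim
    if prior1 is None:
        prior1 = np.full(k1, 1.0 / k1)
    if prior2 is None:
        prior2 = np.full(k2, 1.0 / k2)
    if np.any(np.asarray(prior1) <= 0) or np.any(np.asarray(prior2) <= 0):
        raise InfiniteKLError("priors must have strictly positive entries")

    rng = np.random.default_rng(seed)
    g1 = sample_gumbel(rng, (n, k1))
    g2 = sample_gumbel(rng, (n, k2))
    eps1 = rng.standard_normal((n, e))
    eps2 = rng.standard_normal((n, e))

    logp1, _, z1 = branch_forward(params, 1, x1, temperature, g1, eps1)
    logp2, _, z2 = branch_forward(params, 2, x2, temperature, g2, eps2)
    kl1 = _kl_to_prior(logp1, np.asarray(prior1, dtype=np.float64))
    kl2 = _kl_to_prior(logp2, np.asarray(prior2, dtype=np.float64))

    z = concat([z1, z2], axis=-1)
    t_const = Tensor(t)
    # teacher forcing: the outcome head is selected by the observed treatment
    f2 = _head_scalar(params.head_treated, z)
    f3 = _head_scalar(params.head_control, z)
    raw = t_const * f2 + (1.0 - t_const) * f3
    if params.outcome_family == "gaussian":
        s = params.outcome_logvar
        resid2 = (Tensor(y) - raw) ** 2
        nll_y = (resid2 * (-s).exp() + s + LOG_2PI).mean() * 0.5
    else:
        sign = Tensor(1.0 - 2.0 * y)
        nll_y = softplus(sign * raw).mean()
    t_logit = _head_scalar(params.head_treatment, z)
    nll_t = softplus(Tensor(1.0 - 2.0 * t) * t_logit).mean()

    total = kl1 + kl2 + lam * (nll_y + nll_t)
    comps = LossComponents(
        kl_branch1=float(kl1.data), kl_branch2=float(kl2.data),
        nll_outcome=float(nll_y.data), nll_treatment=float(nll_t.data),
        lam=float(lam), total=float(total.data),
    )
    return total, comps


def ib_loss(batch, params: ModelParams, lam: float, temperature: float,
            seed: int, prior1=None, prior2=None) -> LossComponents:
    """Evaluate the full objective on a batch (x1, x2, t, y); no gradients."""
    x1, x2, t, y = batch
    _, comps = ib_loss_graph(params, x1, x2, t, y, lam, temperature, seed,
                             prior1, prior2)
    return comps


def hard_loss(params: ModelParams, x1, x2, t, y, lam: float,
              prior1=None, prior2=None) -> LossComponents:
    """Objective evaluated with noise-free hard codes (validation metric).

    KL terms still use the full categorical posteriors; the relevance terms
    use the deterministically selected component-mean embeddings.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=np.float64))
    x2 = np.atleast_2d(np.asarray(x2, dtype=np.float64))
    t = np.asarray(t, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x1.shape[0] == 0:
        raise InvalidArgumentError("empty batch")
    k1, k2 = params.latent.k1, params.latent.k2
    if prior1 is None:
        prior1 = np.full(k1, 1.0 / k1)
    if prior2 is None:
        prior2 = np.full(k2, 1.0 / k2)

    probs1 = branch_posteriors(params, 1, x1)
    probs2 = branch_posteriors(params, 2, x2)
    kl1 = float(np.mean(compression_kl(probs1, np.broadcast_to(prior1, probs1.shape))))
    kl2 = float(np.mean(compression_kl(probs2, np.broadcast_to(prior2, probs2.shape))))

    v1 = hard_assignments(params, x1, 1)
    v2 = hard_assignments(params, x2, 2)
    z = np.concatenate([params.means1.data[v1], params.means2.data[v2]], axis=-1)
    nll_y, nll_t = relevance_terms((None, t, y), params, z)
    total = kl1 + kl2 + lam * (nll_y + nll_t)
    return LossComponents(kl1, kl2, nll_y, nll_t, float(lam), total)


def branch_posteriors(params: ModelParams, which: int, x_block) -> np.ndarray:
    """Categorical posterior probabilities for every record (noise-free)."""
    logp, _, _ = branch_forward(
        params, which, np.atleast_2d(np.asarray(x_block, dtype=np.float64)),
        1.0, np.zeros((np.atleast_2d(x_block).shape[0],
                       params.latent.k1 if which == 1 else params.latent.k2)),
        None,
    )
    return np.exp(logp.data)
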