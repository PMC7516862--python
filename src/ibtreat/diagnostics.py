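"""Information curves, cluster audits, component sweeps and light baselines.

The compression axis of an information curve is reported as the converged
KL sum (the variational upper bound the objective actually controls); the
treatment-information axis uses an exact plug-in estimator on the discrete
hard codes, so there is no variational slack on the diagnostic side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidArgumentError, ShapeError
from .estimation import ace_error, average_causal_effect
from .model import LatentConfig, ModelParams, hard_assignments
from .objective import hard_loss
from .training import TrainConfig, fit, split_dataset

logger = logging.getLogger("ibtreat")


@dataclass
class InfoCurvePoint:
    """One converged fit summarised on the held-out split (all in nats).

    mi_zx : KL-sum bound on the compression I(Z; X).
    mi_zt : plug-in mutual information between the hard code and treatment.
    mi_zyt : relevance lower bound, up to the dropped constant H(y, t)
        (reported as the negative held-out NLL sum, so larger is better).
    """

    lam: float
    mi_zx: float
    mi_zt: float
    mi_zyt: float


def plugin_mutual_information(codes, labels) -> float:
    """Plug-in MI (nats) of the empirical joint of two discrete vectors."""
    c = np.asarray(codes).ravel()
    l = np.asarray(labels).ravel()
    if c.size != l.size or c.size == 0:
        raise ShapeError("codes and labels must be equal-length and non-empty")
    _, ci = np.unique(c, return_inverse=True)
    _, li = np.unique(l, return_inverse=True)
    joint = np.zeros((ci.max() + 1, li.max() + 1))
    np.add.at(joint, (ci, li), 1.0)
    joint /= joint.sum()
    pc = joint.sum(axis=1, keepdims=True)
    pl = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (pc @ pl)[mask])))


def _derive_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2**31))


def joint_hard_codes(params: ModelParams, x1, x2) -> np.ndarray:
    """Single integer label per record for the (v1, v2) pair."""
    v1 = hard_assignments(params, x1, 1)
    v2 = hard_assignments(params, x2, 2)
    return v1 * params.latent.k2 + v2


def information_curve(dataset, lambda_grid, train_config: TrainConfig,
                      latent_config: LatentConfig) -> list[InfoCurvePoint]:
    """One fresh fit per relevance multiplier, summarised on the test split."""
    grid = list(lambda_grid)
    if not grid or any(lam < 0 for lam in grid):
        raise InvalidArgumentError("lambda grid must be non-empty and non-negative")
    points = []
    for i, lam in enumerate(grid):
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            epochs=train_config.epochs, batch_size=train_config.batch_size,
            lam=float(lam), seed=_derive_seed(train_config.seed, i),
            split_fractions=train_config.split_fractions,
            outcome_family=train_config.outcome_family,
            patience=train_config.patience, grad_clip=train_config.grad_clip,
        )
        try:
            params, _ = fit(dataset, cfg, latent_config)
        except Exception as exc:
            raise RuntimeError(f"information-curve fit failed at lambda={lam}") from exc
        _, _, test = split_dataset(dataset, cfg.split_fractions, cfg.seed)
        comps = hard_loss(params, test.x1, test.x2, test.t, test.y, lam=float(lam))
        mi_zt = plugin_mutual_information(
            joint_hard_codes(params, test.x1, test.x2), test.t
        )
        points.append(InfoCurvePoint(
            lam=float(lam),
            mi_zx=comps.kl_branch1 + comps.kl_branch2,
            mi_zt=mi_zt,
            mi_zyt=-(comps.nll_outcome + comps.nll_treatment),
        ))
    return points


def cluster_composition(params: ModelParams, dataset, attribute) -> pd.DataFrame:
    """Per-cluster proportions of a categorical audit attribute.

    Rows are the non-empty (v1, v2) classes (empty classes are flagged in the
    ``empty`` attribute of the frame, not emitted as NaN rows); columns are
    attribute levels and sum to one per row.
    """
    attr = np.asarray(attribute)
    if attr.size != dataset.n:
        raise ShapeError("attribute length must equal dataset size")
    codes = joint_hard_codes(params, dataset.x1, dataset.x2)
    levels = np.unique(attr)
    rows = []
    present = np.unique(codes)
    for code in present:
        mask = codes == code
        props = [float(np.mean(attr[mask] == lvl)) for lvl in levels]
        rows.append([int(code // params.latent.k2), int(code % params.latent.k2),
                     int(mask.sum())] + props)
    frame = pd.DataFrame(
        rows, columns=["v1", "v2", "n"] + [str(lvl) for lvl in levels]
    )
    all_codes = set(range(params.latent.k1 * params.latent.k2))
    frame.attrs["empty"] = sorted(all_codes - set(int(c) for c in present))
    return frame


def sweep_components(dataset, truth, k_grid, train_config: TrainConfig,
                     embed_dim: int = 3) -> list[tuple[int, float]]:
    """Out-of-sample average-effect error as the component count varies."""
    results = []
    for i, k in enumerate(k_grid):
        latent = LatentConfig(k1=int(k), k2=int(k), embed_dim=embed_dim)
        cfg = TrainConfig(
            learning_rate=train_config.learning_rate,
            epochs=train_config.epochs, batch_size=train_config.batch_size,
            lam=train_config.lam, seed=_derive_seed(train_config.seed, i),
            split_fractions=train_config.split_fractions,
            outcome_family=train_config.outcome_family,
            patience=train_config.patience, grad_clip=train_config.grad_clip,
        )
        params, _ = fit(dataset, cfg, latent)
        _, _, test = split_dataset(dataset, cfg.split_fractions, cfg.seed)
        est = average_causal_effect(params, test)
        results.append((int(k), ace_error(est.ace, truth.true_ace)))
    return results


# --------------------------------------------------------------------------
# light regression baselines
# --------------------------------------------------------------------------


def _design(x: np.ndarray) -> np.ndarray:
    return sm.add_constant(x, has_constant="add")


def _ols_params(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients with an automatic tiny-ridge fallback."""
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.warning("singular design; applying ridge 1e-6 fallback")
        return np.linalg.solve(X.T @ X + 1e-6 * np.eye(X.shape[1]), X.T @ y)
    return sm.OLS(y, X).fit().params


def baseline_ace(method: str, dataset) -> float:
    """Average-effect estimate from a simple reference method.

    naive : difference in mean observed outcomes between arms.
    ols1  : coefficient of T in one least-squares fit of Y on (X, T).
    ols2  : two separate arm-wise least-squares fits, averaged over all x.
    """
    t = dataset.t.astype(bool)
    if t.sum() == 0 or (~t).sum() == 0:
        raise InvalidArgumentError("both treatment arms must be non-empty")
    y = dataset.y
    x = dataset.x if hasattr(dataset, "x") else dataset.x2
    if method == "naive":
        return float(y[t].mean() - y[~t].mean())
    if method == "ols1":
        X = _design(np.column_stack([x, t.astype(float)]))
        return float(_ols_params(X, y)[-1])
    if method == "ols2":
        Xd = _design(x)
        beta_t = _ols_params(Xd[t], y[t])
        beta_c = _ols_params(Xd[~t], y[~t])
        return float(np.mean(Xd @ beta_t - Xd @ beta_c))
    raise InvalidArgumentError(f"unknown baseline method {method!r}")


def baseline_standard_error(method: str, dataset, n_boot: int = 200,
                            seed: int = 0) -> float:
    """Approximate standard error of a baseline estimate.

    naive uses the Welch two-sample formula; the regression baselines use a
    seeded nonparametric bootstrap.
    """
    t = dataset.t.astype(bool)
    y = dataset.y
    if method == "naive":
        return float(np.sqrt(y[t].var(ddof=1) / t.sum()
                             + y[~t].var(ddof=1) / (~t).sum()))
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        sub = dataset.subset(idx)
        if sub.t.sum() == 0 or sub.t.sum() == sub.n:
            continue
        reps.append(baseline_ace(method, sub))
    return float(np.std(reps, ddof=1))
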