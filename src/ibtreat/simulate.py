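"""Seeded generators of confounded observational data with known truth.

Three designs are provided:

* ``gen_confounded_linear`` — a discrete low-dimensional confounder drives
  both treatment assignment (through a logistic selection rule) and the
  outcome level, with Gaussian covariates that carry the confounder in both
  covariate blocks. Ground-truth potential outcomes are recorded exactly.
* ``gen_ihdp_like`` — a randomised design over ~26 covariates that is
  de-randomised by removing a fraction of treated units in one binary
  subgroup, emulating the minority-treated-arm structure of the classic
  infant-intervention benchmark (747 subjects, 139 treated, 608 control).
  The response surface here is our own documented linear + subgroup
  interaction; fidelity to any published simulated surface is a non-goal.
* ``gen_twins_like`` — a binary-outcome design with a 0-9 ordinal gestation
  confounder and the published treatment-assignment mechanism
  t | x, z ~ Bern(sigma(w_o' x + w_h (z/10 - 0.1))), w_o ~ N(0, 0.1 I),
  w_h ~ N(5, 0.1); one twin of each pair is observed. Covariates other than
  the confounder are synthetic stand-ins for the natality fields.

All randomness in a generator derives from its single ``seed`` via
``numpy.random.default_rng``; regeneration with the same seed is bitwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AbsentBlockError,
    DegenerateDesignError,
    InvalidArgumentError,
)


def _sigma(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ObservationalDataset:
    """Tabular observational study: covariates, binary treatment, outcome.

    ``x1_columns`` is the block systematically missing at test time;
    ``x2_columns`` is always observed. ``attributes`` holds optional audit
    labels (e.g. a planted subgroup) that are not model inputs.
    """

    x: np.ndarray
    t: np.ndarray
    y: np.ndarray
    column_names: list[str]
    x1_columns: tuple[int, ...]
    x2_columns: tuple[int, ...]
    outcome_family: str = "gaussian"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.t = np.asarray(self.t)
        self.y = np.asarray(self.y, dtype=np.float64)
        n, d = self.x.shape
        if self.t.shape != (n,) or self.y.shape != (n,):
            raise InvalidArgumentError("x, t, y lengths are inconsistent")
        if not np.all(np.isin(self.t, (0, 1))):
            raise InvalidArgumentError("treatment vector must be binary 0/1")
        self.t = self.t.astype(np.int64)
        self.x1_columns = tuple(int(c) for c in self.x1_columns)
        self.x2_columns = tuple(int(c) for c in self.x2_columns)
        if set(self.x1_columns) & set(self.x2_columns):
            raise InvalidArgumentError("x1 and x2 column sets overlap")
        if set(self.x1_columns) | set(self.x2_columns) != set(range(d)):
            raise InvalidArgumentError("x1 and x2 columns must cover all columns")
        if len(self.column_names) != d:
            raise InvalidArgumentError("column_names length mismatch")
        if np.isnan(self.x[:, list(self.x2_columns)]).any():
            raise InvalidArgumentError("NaN found in always-observed x2 columns")
        if self.outcome_family not in ("gaussian", "bernoulli"):
            raise InvalidArgumentError(
                f"unknown outcome family {self.outcome_family!r}"
            )

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def d(self) -> int:
        return self.x.shape[1]

    @property
    def x1(self) -> np.ndarray:
        return self.x[:, list(self.x1_columns)]

    @property
    def x2(self) -> np.ndarray:
        return self.x[:, list(self.x2_columns)]

    def subset(self, idx) -> "ObservationalDataset":
        idx = np.asarray(idx)
        return ObservationalDataset(
            x=self.x[idx], t=self.t[idx], y=self.y[idx],
            column_names=list(self.column_names),
            x1_columns=self.x1_columns, x2_columns=self.x2_columns,
            outcome_family=self.outcome_family,
            attributes={k: np.asarray(v)[idx] for k, v in self.attributes.items()},
        )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator (never shown to the model)."""

    y0: np.ndarray
    y1: np.ndarray
    true_ace: float
    confounder: np.ndarray
    regime: str  # "observational" | "interventional"

    def __post_init__(self):
        self.y0 = np.asarray(self.y0, dtype=np.float64)
        self.y1 = np.asarray(self.y1, dtype=np.float64)
        assert abs(self.true_ace - float(np.mean(self.y1 - self.y0))) < 1e-12

    def subset(self, idx) -> "SyntheticTruth":
        idx = np.asarray(idx)
        y0, y1 = self.y0[idx], self.y1[idx]
        return SyntheticTruth(y0, y1, float(np.mean(y1 - y0)),
                              np.asarray(self.confounder)[idx], self.regime)


@dataclass
class MissingBlockView:
    """Evaluation-time view of a dataset with the x1 block withheld.

    The withheld columns are flagged absent — not imputed or zero-filled;
    accessing ``x1`` raises. ``reattach()`` restores the original dataset
    bitwise.
    """

    base: ObservationalDataset
    removed_columns: tuple[int, ...]

    @property
    def n(self) -> int:
        return self.base.n

    @property
    def t(self) -> np.ndarray:
        return self.base.t

    @property
    def y(self) -> np.ndarray:
        return self.base.y

    @property
    def x2(self) -> np.ndarray:
        return self.base.x2

    @property
    def x2_columns(self):
        return self.base.x2_columns

    @property
    def outcome_family(self):
        return self.base.outcome_family

    @property
    def attributes(self):
        return self.base.attributes

    @property
    def x1(self) -> np.ndarray:
        if self.removed_columns:
            raise AbsentBlockError(
                "the x1 covariate block is systematically missing in this view"
            )
        return self.base.x1

    def reattach(self) -> ObservationalDataset:
        return self.base


def apply_systematic_missingness(dataset: ObservationalDataset,
                                 x1_columns) -> MissingBlockView:
    """Return a test-time view with the given x1 columns flagged absent."""
    cols = tuple(int(c) for c in x1_columns)
    declared = set(dataset.x1_columns)
    bad = [c for c in cols if c not in declared]
    if bad:
        raise InvalidArgumentError(
            f"columns {bad} are not in the declared x1 block and cannot be removed"
        )
    return MissingBlockView(base=dataset, removed_columns=cols)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------


def gen_confounded_linear(
    n: int = 2000,
    d: int = 10,
    n_confounder_levels: int = 4,
    effect_size: float = 1.0,
    confounding_strength: float = 2.0,
    noise_sd: float = 1.0,
    randomised: bool = False,
    seed: int = 0,
) -> tuple[ObservationalDataset, SyntheticTruth]:
    """Discrete-confounder design with level-separated Gaussian covariates.

    A confounder c is uniform on {0, ..., L-1}. Covariate j is
    a_j * (c - c_bar) + N(0, 1) with fixed unit-scale loadings a_j, so both
    covariate halves identify the confounder. Treatment is Bern(0.5) when
    ``randomised`` else Bern(sigma(confounding_strength * (c - c_bar))).
    Potential outcomes: y0 = (c - c_bar) + N(0, noise_sd^2),
    y1 = y0 + effect_size, so the true average effect is exactly
    ``effect_size``.
    """
    if n < 20 or d < 2:
        raise InvalidArgumentError("need n >= 20 and d >= 2")
    if n_confounder_levels < 2:
        raise InvalidArgumentError("need at least 2 confounder levels")
    if noise_sd <= 0:
        raise InvalidArgumentError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    levels = n_confounder_levels
    c = rng.integers(0, levels, size=n)
    c_centered = c - (levels - 1) / 2.0

    # fixed loadings with alternating sign, scaled so that EACH covariate
    # half separates adjacent confounder levels by ~4 sigma: the confounder
    # is measured (strong ignorability), not hidden in covariate noise
    signs = np.where(np.arange(d) % 2 == 0, 1.0, -1.0)
    loadings = signs * (1.5 + 0.6 * (np.arange(d) % 3) / 2.0)
    x = c_centered[:, None] * loadings[None, :] + rng.standard_normal((n, d))

    if randomised:
        t = rng.binomial(1, 0.5, size=n)
        regime = "interventional"
    else:
        p_t = _sigma(confounding_strength * c_centered)
        t = rng.binomial(1, p_t)
        regime = "observational"

    y0 = c_centered + rng.normal(0.0, noise_sd, size=n)
    y1 = y0 + effect_size
    y = np.where(t == 1, y1, y0)

    half = d // 2
    ds = ObservationalDataset(
        x=x, t=t, y=y,
        column_names=[f"x{j}" for j in range(d)],
        x1_columns=tuple(range(half)),
        x2_columns=tuple(range(half, d)),
        outcome_family="gaussian",
        attributes={"confounder": c},
    )
    truth = SyntheticTruth(y0=y0, y1=y1, true_ace=float(np.mean(y1 - y0)),
                           confounder=c, regime=regime)
    return ds, truth


def gen_ihdp_like(
    n: int = 900,
    d: int = 26,
    removal_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[ObservationalDataset, SyntheticTruth]:
    """Randomised design de-randomised by removing treated units of a subgroup.

    Starts from a trial with treatment probability 1/3 over ``n`` units and a
    binary subgroup attribute s (prevalence 0.65, emulating an ethnicity
    flag); ``removal_fraction`` of the treated units with s = 1 are dropped,
    which at the defaults yields roughly 130 treated vs 600 control — the
    minority-treated-arm proportions of the benchmark (139 treated / 608
    control out of 747). Outcomes are continuous test scores from a linear
    surface with a subgroup-dependent treatment effect.
    """
    if not 0 <= removal_fraction < 1:
        raise InvalidArgumentError("removal_fraction must be in [0, 1)")
    if n < 50 or d < 4:
        raise InvalidArgumentError("need n >= 50 and d >= 4")
    rng = np.random.default_rng(seed)
    s = rng.binomial(1, 0.65, size=n)
    n_cont = d - d // 3
    x_cont = rng.standard_normal((n, n_cont)) + 0.8 * s[:, None] * np.where(
        np.arange(n_cont) % 2 == 0, 1.0, -0.5
    )
    x_bin = rng.binomial(1, np.where(s[:, None] == 1, 0.7, 0.3),
                         size=(n, d - n_cont)).astype(np.float64)
    x = np.concatenate([x_cont, x_bin], axis=1)

    t = rng.binomial(1, 1.0 / 3.0, size=n)

    beta = rng.normal(0.0, 0.5, size=d)
    base = x @ beta + 1.5 * s
    tau = 4.0 - 1.0 * s  # subgroup-dependent effect of the intervention
    y0 = base + rng.normal(0.0, 1.0, size=n)
    y1 = y0 + tau

    # de-randomise: drop a fraction of treated units in subgroup s = 1
    keep = np.ones(n, dtype=bool)
    drop_pool = np.flatnonzero((t == 1) & (s == 1))
    n_drop = int(round(removal_fraction * drop_pool.size))
    if n_drop > 0:
        keep[rng.choice(drop_pool, size=n_drop, replace=False)] = False
    if not np.any(t[keep] == 1):
        raise DegenerateDesignError("removal emptied the treated arm")

    x, t, s, y0, y1 = x[keep], t[keep], s[keep], y0[keep], y1[keep]
    y = np.where(t == 1, y1, y0)

    half = d // 2
    ds = ObservationalDataset(
        x=x, t=t, y=y,
        column_names=[f"x{j}" for j in range(d)],
        x1_columns=tuple(range(half)),
        x2_columns=tuple(range(half, d)),
        outcome_family="gaussian",
        attributes={"subgroup": s},
    )
    regime = "interventional" if removal_fraction == 0 else "observational"
    truth = SyntheticTruth(y0=y0, y1=y1, true_ace=float(np.mean(y1 - y0)),
                           confounder=s, regime=regime)
    return ds, truth


def gen_twins_like(
    n_pairs: int = 1000,
    d: int = 46,
    seed: int = 0,
    w_h_loc: float = 5.0,
    w_o_scale: float | None = None,
) -> tuple[ObservationalDataset, SyntheticTruth]:
    """Binary-mortality twin design with an ordinal gestation confounder.

    z (column 0) is an ordinal 0-9 gestation-decile confounder; mortality risk
    decreases with z and is slightly lower for the heavier twin (t = 1).
    Treatment follows t | x, z ~ Bern(sigma(w_o' x + w_h (z/10 - 0.1))) with
    w_o ~ N(0, 0.1 I) over the standardised auxiliary covariates and
    w_h ~ N(5, 0.1). ``w_h_loc`` and ``w_o_scale`` exist to switch the
    mechanism off in tests (0 gives Bern(0.5) exactly).
    """
    if n_pairs < 10:
        raise InvalidArgumentError("need at least 10 twin pairs")
    if d < 2:
        raise InvalidArgumentError("need at least 2 covariates")
    rng = np.random.default_rng(seed)
    n = n_pairs
    z = rng.binomial(9, 0.55, size=n)

    n_aux = d - 1
    # auxiliary covariates: half carry the confounder weakly, half are noise
    aux = rng.standard_normal((n, n_aux))
    carry = np.arange(n_aux) % 2 == 0
    aux[:, carry] += 0.3 * ((z - 4.5) / 2.0)[:, None]
    aux_std = (aux - aux.mean(axis=0)) / np.where(aux.std(axis=0) > 0,
                                                  aux.std(axis=0), 1.0)

    var_scale = 0.1 if w_o_scale is None else w_o_scale
    w_o = rng.normal(0.0, np.sqrt(var_scale), size=n_aux) if var_scale > 0 \
        else np.zeros(n_aux)
    w_h = rng.normal(w_h_loc, np.sqrt(0.1)) if w_h_loc != 0 else 0.0
    index = aux_std @ w_o + w_h * (z / 10.0 - 0.1)
    p_t = _sigma(index)
    t = rng.binomial(1, p_t)

    # z-dependent mortality; the heavier twin carries slightly lower risk
    logit0 = -2.0 - 0.35 * (z - 4.5)
    logit1 = logit0 - 0.25
    y0 = rng.binomial(1, _sigma(logit0)).astype(np.float64)
    y1 = rng.binomial(1, _sigma(logit1)).astype(np.float64)
    y = np.where(t == 1, y1, y0)  # one twin per pair is observed

    x = np.concatenate([z[:, None].astype(np.float64), aux], axis=1)
    half = max(1, d // 2)
    ds = ObservationalDataset(
        x=x, t=t, y=y,
        column_names=["gestat10"] + [f"x{j}" for j in range(1, d)],
        x1_columns=tuple(range(half)),  # includes the gestation confounder
        x2_columns=tuple(range(half, d)),
        outcome_family="bernoulli",
        attributes={"gestat10": z},
    )
    truth = SyntheticTruth(y0=y0, y1=y1, true_ace=float(np.mean(y1 - y0)),
                           confounder=z, regime="observational")
    return ds, truth
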