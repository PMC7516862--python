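"""Subgroup-specific and average causal effects on the discrete latent space.

Each pair of hard codes (v1, v2) defines an equivalence class with embedding
z = concat(mean1[v1], mean2[v2]). The class-specific causal effect (the
average effect restricted to that class) is the difference between the two
decoder heads at z; the average causal effect is the occupancy-weighted mean
of class effects. When the x1 block is missing at test time, v2 is still
encoded from x2 and v1 is integrated over a Laplace-smoothed conditional
p(v1 | v2) tabulated on the training data, giving fractional occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError
from .model import ModelParams, decode_outcome, hard_assignments


@dataclass
class ClusterJointTable:
    """Hard co-assignment counts on training data and smoothed p(v1 | v2).

    ``counts`` is k1 x k2; ``cond`` has k2 rows, each a simplex over v1,
    Laplace-smoothed with pseudo-count 1.
    """

    counts: np.ndarray
    cond: np.ndarray

    @property
    def k1(self) -> int:
        return self.counts.shape[0]

    @property
    def k2(self) -> int:
        return self.counts.shape[1]


@dataclass
class CausalEstimates:
    """Per-class effects with occupancy weights and the aggregated average.

    Invariant: ace == sum(occupancy * sce) and occupancy sums to one.
    ``n_per_cluster`` counts records by their modal class assignment.
    """

    cluster_ids: list[tuple[int, int]]
    sce: np.ndarray
    occupancy: np.ndarray
    ace: float
    n_per_cluster: np.ndarray
    missing_block: str = "none"

    def __post_init__(self):
        assert abs(self.occupancy.sum() - 1.0) < 1e-9
        assert abs(self.ace - float(self.occupancy @ self.sce)) < 1e-9


def build_cluster_table(train_dataset, params: ModelParams) -> ClusterJointTable:
    """Tabulate hard (v1, v2) co-assignments of every training record."""
    v1 = hard_assignments(params, train_dataset.x1, 1)
    v2 = hard_assignments(params, train_dataset.x2, 2)
    k1, k2 = params.latent.k1, params.latent.k2
    counts = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(counts, (v1, v2), 1)
    cond = (counts + 1.0) / (counts.sum(axis=0, keepdims=True) + k1)
    return ClusterJointTable(counts=counts, cond=cond.T)


def specific_causal_effect(params: ModelParams, cluster: tuple[int, int]) -> float:
    """Effect for one equivalence class, from the decoder at its embedding."""
    v1, v2 = cluster
    if not (0 <= v1 < params.latent.k1 and 0 <= v2 < params.latent.k2):
        raise InvalidArgumentError(f"cluster index {cluster} out of range")
    z = np.concatenate([params.means1.data[v1], params.means2.data[v2]])
    treated = decode_outcome(z, 1, params).mean
    control = decode_outcome(z, 0, params).mean
    return float(treated - control)


def _sce_grid(params: ModelParams) -> np.ndarray:
    """SCE for every (v1, v2) pair, vectorised over the decoder."""
    k1, k2 = params.latent.k1, params.latent.k2
    m1 = np.repeat(params.means1.data, k2, axis=0)
    m2 = np.tile(params.means2.data, (k1, 1))
    z = np.concatenate([m1, m2], axis=1)
    diff = decode_outcome(z, np.ones(k1 * k2, dtype=int), params).mean \
        - decode_outcome(z, np.zeros(k1 * k2, dtype=int), params).mean
    return diff.reshape(k1, k2)


def average_causal_effect(params: ModelParams, dataset,
                          cluster_table: ClusterJointTable | None = None,
                          missing_block: str = "none",
                          hard_transfer: bool = False) -> CausalEstimates:
    """Occupancy-weighted aggregation of class-specific effects.

    missing_block="none": every record is hard-encoded to (v1, v2) and
    occupancy is the empirical class frequency on ``dataset``.
    missing_block="x1": only x2 is encoded; v1 is integrated over the
    smoothed training conditional p(v1 | v2) (or, with ``hard_transfer``,
    assigned to the modal v1 of that conditional).
    """
    if missing_block not in ("none", "x1"):
        raise InvalidArgumentError("missing_block must be 'none' or 'x1'")
    k1, k2 = params.latent.k1, params.latent.k2
    n = dataset.n
    if n == 0:
        raise InvalidArgumentError("empty dataset")
    sce = _sce_grid(params)
    occupancy = np.zeros((k1, k2))
    v2 = hard_assignments(params, dataset.x2, 2)

    if missing_block == "none":
        v1 = hard_assignments(params, dataset.x1, 1)
        np.add.at(occupancy, (v1, v2), 1.0)
        occupancy /= n
        modal_v1 = v1
    else:
        if cluster_table is None:
            raise InvalidArgumentError(
                "transfer mode needs the training cluster table"
            )
        cond = cluster_table.cond  # (k2, k1)
        if hard_transfer:
            modal_v1 = np.argmax(cond[v2], axis=1)
            np.add.at(occupancy, (modal_v1, v2), 1.0)
            occupancy /= n
        else:
            for j in range(k2):
                occupancy[:, j] = cond[j] * np.sum(v2 == j)
            occupancy /= n
            modal_v1 = np.argmax(cond[v2], axis=1)

    n_per = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(n_per, (modal_v1, v2), 1)

    # flatten in a fixed (v1-major) order; keep classes with any weight
    cluster_ids = [(i, j) for i in range(k1) for j in range(k2)]
    occ_flat = occupancy.ravel()
    sce_flat = sce.ravel()
    ace = float(occ_flat @ sce_flat)
    return CausalEstimates(
        cluster_ids=cluster_ids, sce=sce_flat, occupancy=occ_flat, ace=ace,
        n_per_cluster=n_per.ravel(), missing_block=missing_block,
    )


def ace_error(estimate: float, truth: float) -> float:
    """Absolute error |estimate - truth| of an average-effect estimate."""
    if not (np.isfinite(estimate) and np.isfinite(truth)):
        raise InvalidArgumentError("estimate and truth must be finite")
    return float(abs(estimate - truth))
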