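"""Cell-type-level connectivity statistics from the innervation matrix.

For presynaptic population A and postsynaptic population B, the pair
probabilities p_ab = 1 - exp(-I_ab) aggregate into three experimentally
accessible quantities: the convergence C_b = <p_ab> over a in A (fraction of
the presynaptic population connected to postsynaptic neuron b), the
divergence D_a = <p_ab> over b in B, and the population connection
probability P_AB = <p_ab> over both.  The population synapse-count
distribution n_AB is the average of the per-pair Poisson laws, so its mean
equals the mean innervation <I_ab>.

Self-pairs (autapses, a = b) are excluded from all ensemble averages by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .innervation import (
    InnervationMatrix,
    connection_probability,
    synapse_count_distribution,
)

__all__ = [
    "PopulationStats",
    "convergence",
    "divergence",
    "population_summary",
]


def _pair_mask(matrix: InnervationMatrix, exclude_autapses: bool) -> np.ndarray:
    """Boolean (pre x post) mask of pairs entering ensemble averages."""
    mask = np.ones(matrix.shape, dtype=bool)
    if exclude_autapses:
        for r, i in enumerate(matrix.pre_ids):
            c = matrix._post_index.get(i)
            if c is not None:
                mask[r, c] = False
    return mask


def convergence(matrix: InnervationMatrix, post_id: int,
                pre_ids=None, exclude_autapses: bool = True) -> float:
    """Mean of p_ab over the presynaptic population onto one post neuron."""
    pre_ids = matrix.pre_ids if pre_ids is None else list(pre_ids)
    if not pre_ids:
        raise ValueError("presynaptic selection is empty")
    vals = [
        connection_probability(matrix.value(a, post_id))
        for a in pre_ids
        if not (exclude_autapses and a == post_id)
    ]
    if not vals:
        raise ValueError("no pairs left after autapse exclusion")
    return float(np.mean(vals))


def divergence(matrix: InnervationMatrix, pre_id: int,
               post_ids=None, exclude_autapses: bool = True) -> float:
    """Mean of p_ab over the postsynaptic population from one pre neuron."""
    post_ids = matrix.post_ids if post_ids is None else list(post_ids)
    if not post_ids:
        raise ValueError("postsynaptic selection is empty")
    vals = [
        connection_probability(matrix.value(pre_id, b))
        for b in post_ids
        if not (exclude_autapses and b == pre_id)
    ]
    if not vals:
        raise ValueError("no pairs left after autapse exclusion")
    return float(np.mean(vals))


@dataclass
class PopulationStats:
    """Aggregate connectivity statistics between two populations."""

    p_ab: float                       # grand-mean connection probability P_AB
    convergence_per_post: np.ndarray  # C_b for each b in B
    divergence_per_pre: np.ndarray    # D_a for each a in A
    n_ab: np.ndarray                  # averaged synapse-count pmf, n = 0..n_max
    synapse_range: tuple[int, int]    # 99% cumulative range of n_AB given n > 0
    n_pre: int
    n_post: int

    @property
    def convergence_mean(self) -> float:
        return float(np.mean(self.convergence_per_post))

    @property
    def convergence_sd(self) -> float:
        return float(np.std(self.convergence_per_post, ddof=1)) \
            if len(self.convergence_per_post) > 1 else 0.0

    @property
    def mean_synapses(self) -> float:
        """Mean of n_AB (equals the mean innervation <I_ab>)."""
        return float(np.dot(np.arange(len(self.n_ab)), self.n_ab))


def _conditional_range(n_ab: np.ndarray, q: float = 0.99) -> tuple[int, int]:
    """q-cumulative range of the synapse-count law conditioned on n > 0."""
    tail = n_ab[1:]
    total = tail.sum()
    if total <= 0:
        return (0, 0)
    cond = tail / total
    cum = np.cumsum(cond)
    lo = 1 + int(np.argmax(cond > 0))
    hi = 1 + int(np.searchsorted(cum, q))
    return (lo, min(hi, len(n_ab) - 1))


def population_summary(matrix: InnervationMatrix, pre_ids=None, post_ids=None,
                       exclude_autapses: bool = True,
                       range_quantile: float = 0.99) -> PopulationStats:
    """P_AB, per-neuron convergence/divergence and averaged n_AB.

    The synapse-count distribution is the elementwise average of the
    per-pair Poisson mass functions, evaluated up to the largest per-pair
    1 - 1e-9 quantile.  The reported synapse range is the
    ``range_quantile`` cumulative range of n_AB conditioned on n > 0.
    """
    sub = matrix.submatrix(pre_ids, post_ids)
    if not sub.pre_ids or not sub.post_ids:
        raise ValueError("population selections must be nonempty")
    I = sub.dense()
    mask = _pair_mask(sub, exclude_autapses)
    if not mask.any():
        raise ValueError("no pairs left after autapse exclusion")
    P = 1.0 - np.exp(-I)

    p_ab = float(P[mask].mean())
    conv = np.array([P[mask[:, c], c].mean() for c in range(P.shape[1])
                     if mask[:, c].any()])
    div = np.array([P[r, mask[r, :]].mean() for r in range(P.shape[0])
                    if mask[r, :].any()])

    n_max = max(
        (len(synapse_count_distribution(I[r, c])) - 1
         for r, c in np.argwhere(mask)),
        default=0,
    )
    pmfs = np.stack([
        synapse_count_distribution(I[r, c], n_max=n_max)
        for r, c in np.argwhere(mask)
    ])
    n_ab = pmfs.mean(axis=0)

    return PopulationStats(
        p_ab=p_ab, convergence_per_post=conv, divergence_per_pre=div,
        n_ab=n_ab, synapse_range=_conditional_range(n_ab, range_quantile),
        n_pre=len(sub.pre_ids), n_post=len(sub.post_ids),
    )


def population_report(matrix: InnervationMatrix,
                      groups: list[tuple] | None = None) -> pd.DataFrame:
    """Per cell-type-pair (and column) summary table.

    Groups default to all (pre cell type, post cell type, post column)
    combinations present in the matrix annotations.
    """
    if matrix.pre_info is None or matrix.post_info is None:
        raise ValueError("matrix lacks axis annotations")
    if groups is None:
        groups = sorted({
            (pt, qt, qc)
            for pt in matrix.pre_info["cell_type"].unique()
            for qt, qc in zip(matrix.post_info["cell_type"],
                              matrix.post_info["column_id"])
        })
    rows = []
    for pre_type, post_type, column in groups:
        pre_sel = matrix.pre_info.loc[
            matrix.pre_info["cell_type"] == pre_type, "id"].tolist()
        post_sel = matrix.post_info.loc[
            (matrix.post_info["cell_type"] == post_type)
            & (matrix.post_info["column_id"] == column), "id"].tolist()
        if not pre_sel or not post_sel:
            continue
        s = population_summary(matrix, pre_sel, post_sel)
        rows.append({
            "pre_type": pre_type, "post_type": post_type, "column": column,
            "P_AB": s.p_ab, "convergence_mean": s.convergence_mean,
            "convergence_sd": s.convergence_sd,
            "synapse_min": s.synapse_range[0],
            "synapse_max": s.synapse_range[1],
            "N_pre": s.n_pre, "N_post": s.n_post,
        })
    return pd.DataFrame(rows)
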