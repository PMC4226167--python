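"""Statistical synaptic innervation between neuron pairs.

Within a voxel, boutons and PSTs cannot be localized further (the voxel
size equals the registration precision of the reference frame), so every
PST in a voxel is equally likely to receive any bouton in that voxel.  The
probability that neuron j captures a given bouton of presynaptic type T(i)
in voxel x is

    p_j(x) = PST_j(x, T(i)) / PST_all(x, T(i)),

with PST_all the sum over all neurons' PST fields.  With B_i(x) boutons the
number of synapses is Binomial(B_i, p_j); since B_i is O(10^1..10^2) and
p_j O(10^-3), the Poisson limit applies with rate

    I~_ij(x) = B_i(x) * p_j(x),

the per-voxel expected synapse count.  Assuming independence across voxels,
the pair connection probability is p_ij = 1 - exp(-I_ij) where
I_ij = sum_x I~_ij(x) is the total innervation — the expected number of
synapses from i to j, and the entry of the dense statistical connectome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import binom, poisson

from .assembly import NetworkModel
from .density_fields import (
    DensityField,
    MetaConnectivity,
    neuron_bouton_field,
    neuron_label_fields,
    pst_field,
)

__all__ = [
    "InnervationField",
    "InnervationMatrix",
    "InnervationError",
    "target_probability",
    "innervation_field",
    "connection_probability",
    "synapse_count_distribution",
    "synapse_count_percentile",
    "binomial_synapse_count_distribution",
    "pairwise_innervation",
    "total_pst_field",
]


class InnervationError(ValueError):
    """Inconsistent innervation inputs (e.g., PST_j exceeding PST_all)."""


@dataclass
class InnervationField:
    """Per-voxel expected synapse counts from one neuron onto another."""

    pre_id: int
    post_id: int
    values: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """Total innervation I_ij (expected synapse count)."""
        return float(sum(self.values.values()))


def target_probability(pst_j: DensityField, pst_all: DensityField,
                       rel_tol: float = 1e-9) -> DensityField:
    """Per-voxel probability p_j = PST_j / PST_all (0 where PST_all = 0)."""
    out = DensityField(pst_j.grid, quantity="p_j")
    for idx, num in pst_j.items():
        denom = pst_all.get(idx)
        if denom == 0.0:
            if num > 0.0:
                raise InnervationError(
                    f"PST_j > 0 but PST_all = 0 in voxel {idx}"
                )
            continue
        if num > denom * (1.0 + rel_tol):
            raise InnervationError(
                f"PST_j ({num}) exceeds PST_all ({denom}) in voxel {idx}"
            )
        out.values[idx] = min(num / denom, 1.0)
    return out


def innervation_field(boutons_i: DensityField, p_j: DensityField,
                      pre_id: int = -1, post_id: int = -1) -> InnervationField:
    """Voxelwise product I~_ij(x) = B_i(x) * p_j(x)."""
    values = {}
    small, big = (boutons_i, p_j) if len(boutons_i.values) <= len(p_j.values) \
        else (p_j, boutons_i)
    for idx, v in small.items():
        w = big.get(idx)
        if w != 0.0 and v != 0.0:
            values[idx] = v * w
    return InnervationField(pre_id=pre_id, post_id=post_id, values=values)


def connection_probability(I_ij) -> float:
    """Pair connection probability 1 - exp(-I_ij)."""
    I_ij = np.asarray(I_ij, dtype=float)
    if np.any(I_ij < 0):
        raise InnervationError("innervation must be non-negative")
    out = 1.0 - np.exp(-I_ij)
    return float(out) if out.ndim == 0 else out


def _default_n_max(I_ij: float) -> int:
    if I_ij == 0.0:
        return 0
    return int(poisson.ppf(1.0 - 1e-9, I_ij))


def synapse_count_distribution(I_ij: float, n_max: int | None = None) -> np.ndarray:
    """Poisson synapse-count law P(n) = I^n exp(-I) / n! for n = 0..n_max.

    ``n_max`` defaults to the 1 - 1e-9 Poisson quantile.
    """
    if I_ij < 0:
        raise InnervationError("innervation must be non-negative")
    if n_max is None:
        n_max = _default_n_max(I_ij)
    return poisson.pmf(np.arange(n_max + 1), I_ij)


def synapse_count_percentile(I_ij: float, q: float) -> int:
    """Smallest n with cumulative Poisson probability >= q."""
    if I_ij == 0.0:
        return 0
    return int(poisson.ppf(q, I_ij))


def binomial_synapse_count_distribution(B: int, p: float,
                                        n_max: int | None = None) -> np.ndarray:
    """Exact Binomial(B, p) synapse-count law, for validating the Poisson
    approximation (B large, p small)."""
    if n_max is None:
        n_max = _default_n_max(B * p)
    return binom.pmf(np.arange(n_max + 1), B, p)


# ---------------------------------------------------------------------------
# network-level computation
# ---------------------------------------------------------------------------

class InnervationMatrix:
    """Sparse expected-synapse-count matrix I_ij with axis annotations.

    Rows are presynaptic neurons, columns postsynaptic neurons; an absent
    entry means no axo-dendritic overlap (I = 0).
    """

    def __init__(self, matrix: sp.spmatrix, pre_ids, post_ids,
                 pre_info: pd.DataFrame | None = None,
                 post_info: pd.DataFrame | None = None):
        self.matrix = sp.csr_matrix(matrix)
        self.pre_ids = list(pre_ids)
        self.post_ids = list(post_ids)
        if self.matrix.shape != (len(self.pre_ids), len(self.post_ids)):
            raise ValueError("matrix shape does not match axis id lists")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("innervation entries must be non-negative")
        self.pre_info = pre_info
        self.post_info = post_info
        self._pre_index = {nid: k for k, nid in enumerate(self.pre_ids)}
        self._post_index = {nid: k for k, nid in enumerate(self.post_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def value(self, pre_id: int, post_id: int) -> float:
        return float(self.matrix[self._pre_index[pre_id],
                                 self._post_index[post_id]])

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def p_dense(self) -> np.ndarray:
        """Dense matrix of pair connection probabilities 1 - exp(-I)."""
        return 1.0 - np.exp(-self.dense())

    def submatrix(self, pre_ids=None, post_ids=None) -> "InnervationMatrix":
        pre_ids = self.pre_ids if pre_ids is None else list(pre_ids)
        post_ids = self.post_ids if post_ids is None else list(post_ids)
        ri = [self._pre_index[i] for i in pre_ids]
        ci = [self._post_index[j] for j in post_ids]
        sub = self.matrix[ri][:, ci]
        pre_info = self.pre_info.loc[self.pre_info["id"].isin(pre_ids)] \
            if self.pre_info is not None else None
        post_info = self.post_info.loc[self.post_info["id"].isin(post_ids)] \
            if self.post_info is not None else None
        return InnervationMatrix(sub, pre_ids, post_ids, pre_info, post_info)

    def to_csv(self, path, include_zero: bool = False) -> None:
        """Per-pair export: pre, post, I_ij, p_ij."""
        coo = self.matrix.tocoo()
        rows = [
            {"pre": self.pre_ids[r], "post": self.post_ids[c],
             "I_ij": v, "p_ij": 1.0 - np.exp(-v)}
            for r, c, v in zip(coo.row, coo.col, coo.data)
        ]
        if include_zero:
            present = {(self.pre_ids[r], self.post_ids[c])
                       for r, c in zip(coo.row, coo.col)}
            for i in self.pre_ids:
                for j in self.post_ids:
                    if (i, j) not in present:
                        rows.append({"pre": i, "post": j, "I_ij": 0.0, "p_ij": 0.0})
        pd.DataFrame(rows, columns=["pre", "post", "I_ij", "p_ij"]).to_csv(
            path, index=False
        )


def total_pst_field(network: NetworkModel, pre_type: str,
                    meta: MetaConnectivity,
                    _label_field_cache: dict | None = None) -> DensityField:
    """PST_all(x, T(i)): summed PST field of every neuron in the network."""
    out = DensityField(network.frame.grid, quantity="PST_all")
    for n in network.neurons:
        f = _neuron_pst(network, n.id, pre_type, meta, _label_field_cache)
        for idx, v in f.items():
            out.add(idx, v)
    return out


def _neuron_pst(network: NetworkModel, neuron_id: int, pre_type: str,
                meta: MetaConnectivity,
                label_field_cache: dict | None) -> DensityField:
    morph = network.dendrite_geometry(neuron_id)
    if morph is None:
        return DensityField(network.frame.grid)
    if label_field_cache is not None and neuron_id in label_field_cache:
        fields = label_field_cache[neuron_id]
    else:
        fields = neuron_label_fields(morph, network.frame.grid)
        if label_field_cache is not None:
            label_field_cache[neuron_id] = fields
    return pst_field(fields, pre_type,
                     network.neuron(neuron_id).cell_type, meta)


def _neuron_info(network: NetworkModel, ids) -> pd.DataFrame:
    return pd.DataFrame([
        {"id": i, "cell_type": network.neuron(i).cell_type,
         "column_id": network.neuron(i).column_id,
         "inside_column": network.neuron(i).inside_column}
        for i in ids
    ])


def pairwise_innervation(network: NetworkModel, pre_ids, post_ids,
                         meta: MetaConnectivity) -> InnervationMatrix:
    """Assemble the sparse innervation matrix over selected neuron pairs.

    PST_all is computed per presynaptic cell type over the entire network
    (all neurons, not only the selected postsynaptic ones — unselected
    neurons still compete for boutons).  Bouton fields are shared between
    neurons re-using the same untransformed axon reconstruction.
    """
    pre_ids = list(pre_ids)
    post_ids = list(post_ids)
    pre_types = sorted({network.neuron(i).cell_type for i in pre_ids})

    label_cache: dict = {}
    pst_all = {t: total_pst_field(network, t, meta, label_cache)
               for t in pre_types}

    # p_j fields per (post neuron, pre type)
    p_fields: dict[tuple[int, str], DensityField] = {}
    for j in post_ids:
        for t in pre_types:
            pst_j = _neuron_pst(network, j, t, meta, label_cache)
            p_fields[(j, t)] = target_probability(pst_j, pst_all[t])

    # bouton fields, cached per (axon morphology, cell type)
    bouton_cache: dict[tuple[str, str], DensityField] = {}
    rows, cols, vals = [], [], []
    for r, i in enumerate(pre_ids):
        n = network.neuron(i)
        key = (n.axon_morphology, n.cell_type)
        if key not in bouton_cache:
            bouton_cache[key] = neuron_bouton_field(network, i)
        b_i = bouton_cache[key]
        for c, j in enumerate(post_ids):
            fld = innervation_field(b_i, p_fields[(j, n.cell_type)],
                                    pre_id=i, post_id=j)
            if fld.total > 0.0:
                rows.append(r)
                cols.append(c)
                vals.append(fld.total)

    matrix = sp.csr_matrix((vals, (rows, cols)),
                           shape=(len(pre_ids), len(post_ids)))
    return InnervationMatrix(matrix, pre_ids, post_ids,
                             pre_info=_neuron_info(network, pre_ids),
                             post_info=_neuron_info(network, post_ids))


def pair_innervation_field(network: NetworkModel, pre_id: int, post_id: int,
                           meta: MetaConnectivity) -> InnervationField:
    """Full per-voxel innervation field for a single neuron pair."""
    t = network.neuron(pre_id).cell_type
    pst_all = total_pst_field(network, t, meta)
    pst_j = _neuron_pst(network, post_id, t, meta, None)
    p_j = target_probability(pst_j, pst_all)
    b_i = neuron_bouton_field(network, pre_id)
    return innervation_field(b_i, p_j, pre_id=pre_id, post_id=post_id)
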