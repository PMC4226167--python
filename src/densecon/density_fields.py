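"""Voxelized density fields: axon length, boutons, postsynaptic targets.

Morphologies are converted into per-voxel scalar fields by clipping every
parent-child segment with the six faces of each voxel it traverses — an
exact parametric split, not a resampling.  Per sub-segment, the length and
the frustum lateral area (with linearly interpolated radii at the split
points) accrue to the containing voxel.

Presynaptic fields: the axon length in a voxel times the cell-type- and
laminar-zone-specific bouton density gives the bouton count B_i(x).

Postsynaptic fields: a neuron j offers postsynaptic target sites (PSTs) to
a presynaptic type T(i) as the sum of a spine term and a surface term,

    PST_j(x, T(i)) = sum_L l_{j,L}(x) * lambda_{T(i),T(j)}(L)
                   + sum_L a_{j,L}(x) * alpha_{T(i),T(j)}(L)

over compartment labels L (soma, apical, basal), where lambda is the
length-PST density (spines per um) and alpha the surface-PST density (PSTs
per um^2) from the meta-connectivity table.  Unknown surface densities are
fitted by requiring total boutons to balance total PSTs after collapsing
all 3D fields to depth profiles (nonnegative least squares).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .assembly import NetworkModel
from .morphology import Morphology
from .reference_frame import ReferenceFrame, VoxelGrid, laminar_zone_of

__all__ = [
    "DensityField",
    "MetaConnectivity",
    "ConfigurationError",
    "FitError",
    "FitResult",
    "clip_to_voxels",
    "bouton_field",
    "pst_field",
    "neuron_pst_field",
    "neuron_bouton_field",
    "fit_alpha_profiles",
    "fit_surface_pst",
    "collapse_balance_profiles",
    "BalanceProfiles",
]

log = logging.getLogger(__name__)

#: Postsynaptic compartment labels that can carry PSTs.
PST_LABELS = ("soma", "apical", "basal")


class ConfigurationError(ValueError):
    """Missing zone density or meta-connectivity entry."""


class FitError(ValueError):
    """Surface-PST fit cannot be solved (rank-deficient design)."""


class DensityField:
    """Sparse per-voxel scalar field (voxel index triple -> value >= 0)."""

    def __init__(self, grid: VoxelGrid, values: dict | None = None,
                 quantity: str = ""):
        self.grid = grid
        self.quantity = quantity
        self.values: dict[tuple[int, int, int], float] = dict(values or {})

    def get(self, idx, default: float = 0.0) -> float:
        return self.values.get(tuple(idx), default)

    def add(self, idx, value: float) -> None:
        idx = tuple(idx)
        self.values[idx] = self.values.get(idx, 0.0) + value

    def total(self) -> float:
        return float(sum(self.values.values()))

    def support(self):
        return self.values.keys()

    def items(self):
        return self.values.items()

    def scaled(self, factor: float) -> "DensityField":
        return DensityField(
            self.grid, {k: v * factor for k, v in self.values.items()},
            self.quantity,
        )

    def to_dense(self) -> np.ndarray:
        out = np.zeros(self.grid.dims)
        for idx, v in self.values.items():
            out[idx] = v
        return out

    def depth_profile(self) -> np.ndarray:
        """Collapse to the grid z-axis (sum over each voxel layer)."""
        out = np.zeros(self.grid.dims[2])
        for (_, _, k), v in self.values.items():
            out[k] += v
        return out

    def to_csv(self, path) -> None:
        rows = [
            {"i": i, "j": j, "k": k, "value": v}
            for (i, j, k), v in sorted(self.values.items())
        ]
        pd.DataFrame(rows, columns=["i", "j", "k", "value"]).to_csv(path, index=False)

    @classmethod
    def sum_of(cls, fields, grid=None, quantity: str = "") -> "DensityField":
        fields = list(fields)
        if grid is None:
            grid = fields[0].grid
        out = cls(grid, quantity=quantity)
        for f in fields:
            for idx, v in f.items():
                out.add(idx, v)
        return out


@dataclass(frozen=True)
class MetaConnectivity:
    """Cell-type-pair PST densities: (pre, post, label) -> (lambda, alpha).

    ``alpha`` may be None, marking a surface density still to be fitted.
    """

    entries: dict = field(default_factory=dict)

    def densities(self, pre_type: str, post_type: str, label: str):
        """(lambda, alpha) for a connection; (0, 0) if the entry is absent
        — an absent entry means the pre type cannot contact that structure.
        """
        return self.entries.get((pre_type, post_type, label), (0.0, 0.0))

    def with_alpha(self, alphas: dict) -> "MetaConnectivity":
        """Copy with unknown (None) alphas replaced from ``alphas`` keyed by
        (pre_type, post_type, label)."""
        new = {}
        for key, (lam, alpha) in self.entries.items():
            if alpha is None:
                if key not in alphas:
                    raise ConfigurationError(f"no fitted alpha for {key}")
                alpha = float(alphas[key])
            new[key] = (lam, alpha)
        return MetaConnectivity(new)

    @property
    def unknown_keys(self) -> list[tuple[str, str, str]]:
        return sorted(k for k, (_, a) in self.entries.items() if a is None)

    @classmethod
    def from_csv(cls, path) -> "MetaConnectivity":
        df = pd.read_csv(path, dtype={"pre_type": str, "post_type": str,
                                      "label": str})
        entries = {}
        for _, row in df.iterrows():
            key = (row["pre_type"], row["post_type"], row["label"])
            if key in entries:
                raise ConfigurationError(f"duplicate meta-connectivity entry {key}")
            alpha = row["alpha_per_um2"]
            alpha = None if pd.isna(alpha) else float(alpha)
            lam = float(row["lambda_per_um"])
            if lam < 0 or (alpha is not None and alpha < 0):
                raise ConfigurationError(f"negative PST density for {key}")
            entries[key] = (lam, alpha)
        return cls(entries)

    def to_csv(self, path) -> None:
        rows = [
            {"pre_type": k[0], "post_type": k[1], "label": k[2],
             "lambda_per_um": lam,
             "alpha_per_um2": "" if alpha is None else alpha}
            for k, (lam, alpha) in sorted(self.entries.items())
        ]
        pd.DataFrame(
            rows, columns=["pre_type", "post_type", "label",
                           "lambda_per_um", "alpha_per_um2"]
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segment clipping
# ---------------------------------------------------------------------------

def _segment_pieces(p0, p1, r0, r1, grid: VoxelGrid):
    """Split a segment at voxel-face crossings.

    Yields (voxel index or None, length, area) per sub-segment; ``None``
    marks pieces outside the grid.  Radii at split points are linearly
    interpolated, the area is the frustum lateral area of the piece.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    seg = p1 - p0
    seglen = float(np.linalg.norm(seg))
    if seglen == 0.0:
        return
    ts = [0.0, 1.0]
    for a in range(3):
        if seg[a] == 0.0:
            continue
        lo = (min(p0[a], p1[a]) - grid.origin[a]) / grid.spacing
        hi = (max(p0[a], p1[a]) - grid.origin[a]) / grid.spacing
        for k in range(math.floor(lo) + 1, math.ceil(hi)):
            plane = grid.origin[a] + k * grid.spacing
            t = (plane - p0[a]) / seg[a]
            if 0.0 < t < 1.0:
                ts.append(t)
    ts = sorted(ts)
    for t0, t1 in zip(ts, ts[1:]):
        if t1 - t0 < 1e-12:
            continue
        mid = p0 + 0.5 * (t0 + t1) * seg
        length = seglen * (t1 - t0)
        ra = r0 + (r1 - r0) * t0
        rb = r0 + (r1 - r0) * t1
        area = math.pi * (ra + rb) * length
        if grid.contains(mid):
            yield grid.point_to_voxel(mid), length, area
        else:
            yield None, length, area


def clip_to_voxels(m: Morphology, label: str,
                   grid: VoxelGrid) -> tuple[DensityField, DensityField]:
    """Per-voxel length (um) and lateral surface area (um^2) of a label.

    Segment pieces outside the grid are dropped with a logged warning.  A
    single-node soma contributes its sphere area to the voxel containing
    the node (and zero length), mirroring the whole-cell surface rule.
    """
    length_field = DensityField(grid, quantity=f"length_{label}_um")
    area_field = DensityField(grid, quantity=f"area_{label}_um2")

    if label == "soma":
        soma_nodes = np.flatnonzero(m.labels == "soma")
        if len(soma_nodes) == 1:
            pos = m.positions[soma_nodes[0]]
            r = m.radii[soma_nodes[0]]
            if grid.contains(pos):
                area_field.add(grid.point_to_voxel(pos), 4.0 * math.pi * r**2)
            else:
                log.warning("soma node outside grid bounds dropped")
            return length_field, area_field

    dropped = 0.0
    ch = m.edges
    sel = ch[m.labels[ch] == label]
    for child in sel:
        parent = m.parents[child]
        for idx, length, area in _segment_pieces(
            m.positions[parent], m.positions[child],
            m.radii[parent], m.radii[child], grid,
        ):
            if idx is None:
                dropped += length
            else:
                length_field.add(idx, length)
                area_field.add(idx, area)
    if dropped > 0:
        log.warning("dropped %.3f um of %s outside grid bounds", dropped, label)
    return length_field, area_field


# ---------------------------------------------------------------------------
# presynaptic (bouton) fields
# ---------------------------------------------------------------------------

def bouton_field(axon_length_field: DensityField, cell_type,
                 frame: ReferenceFrame) -> DensityField:
    """Bouton count per voxel: axon length times the zone bouton density.

    The laminar zone of a voxel is looked up at its center (voxels are
    atomic at the frame resolution).  A zone without a configured density
    for the cell type raises :class:`ConfigurationError`.
    """
    out = DensityField(axon_length_field.grid, quantity="boutons")
    densities = cell_type.bouton_density_per_zone
    for idx, length in axon_length_field.items():
        zone = laminar_zone_of(axon_length_field.grid.voxel_center(idx), frame)
        if zone not in densities:
            raise ConfigurationError(
                f"cell type {cell_type.name!r}: no bouton density for zone "
                f"{zone!r}"
            )
        out.add(idx, length * densities[zone])
    return out


def neuron_bouton_field(network: NetworkModel, neuron_id: int) -> DensityField:
    """Bouton field of a placed neuron's (untransformed) axon."""
    n = network.neuron(neuron_id)
    axon = network.axon_geometry(neuron_id)
    if axon is None:
        return DensityField(network.frame.grid, quantity="boutons")
    length_field, _ = clip_to_voxels(axon, "axon", network.frame.grid)
    return bouton_field(length_field, network.cell_types[n.cell_type],
                        network.frame)


# ---------------------------------------------------------------------------
# postsynaptic (PST) fields
# ---------------------------------------------------------------------------

def pst_field(fields_by_label: dict, pre_type: str, post_type: str,
              meta: MetaConnectivity) -> DensityField:
    """PST count per voxel from per-label (length, area) field pairs.

    ``fields_by_label`` maps a compartment label to its
    ``(length_field, area_field)`` pair.  Labels absent from the
    meta-connectivity table contribute nothing (the pre type cannot contact
    that structure); an unfitted (None) surface density is an error.
    """
    grids = [lf.grid for lf, _ in fields_by_label.values()]
    out = DensityField(grids[0] if grids else None, quantity="PSTs")
    for label, (length_field, area_field) in fields_by_label.items():
        lam, alpha = meta.densities(pre_type, post_type, label)
        if alpha is None:
            raise ConfigurationError(
                f"surface PST density for ({pre_type}, {post_type}, {label}) "
                "has not been fitted"
            )
        if lam:
            for idx, v in length_field.items():
                out.add(idx, v * lam)
        if alpha:
            for idx, v in area_field.items():
                out.add(idx, v * alpha)
    return out


def neuron_label_fields(morph: Morphology, grid: VoxelGrid) -> dict:
    """(length, area) field pairs per postsynaptic label of a morphology."""
    return {label: clip_to_voxels(morph, label, grid) for label in PST_LABELS}


def neuron_pst_field(network: NetworkModel, neuron_id: int, pre_type: str,
                     meta: MetaConnectivity) -> DensityField:
    """PST field of a placed neuron for connections from ``pre_type``."""
    morph = network.dendrite_geometry(neuron_id)
    if morph is None:
        return DensityField(network.frame.grid, quantity="PSTs")
    n = network.neuron(neuron_id)
    fields = neuron_label_fields(morph, network.frame.grid)
    return pst_field(fields, pre_type, n.cell_type, meta)


# ---------------------------------------------------------------------------
# surface-PST density fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Outcome of the depth-profile surface-PST fit."""

    alpha_by_group: dict  # (pre_class, post_type, label) -> alpha
    residual_profile: np.ndarray
    target: np.ndarray
    design: np.ndarray
    group_keys: list


def fit_alpha_profiles(target: np.ndarray, area_profiles: dict) -> FitResult:
    """Solve ``area_profiles @ alpha = target`` for alpha >= 0 (NNLS).

    ``target`` is the bouton depth profile minus the spine-PST (and any
    already-known surface-PST) depth profile; ``area_profiles`` maps each
    unknown group to its surface-area depth profile.
    """
    keys = sorted(area_profiles.keys())
    A = np.column_stack([np.asarray(area_profiles[k], dtype=float) for k in keys])
    b = np.asarray(target, dtype=float)
    if np.linalg.matrix_rank(A) < len(keys):
        raise FitError(
            f"rank-deficient design: collinear area profiles among {keys}"
        )
    x, _ = nnls(A, b)
    residual = b - A @ x
    return FitResult(
        alpha_by_group=dict(zip(keys, (float(v) for v in x))),
        residual_profile=residual, target=b, design=A, group_keys=keys,
    )


def _class_of(excitatory: bool) -> str:
    return "exc" if excitatory else "inh"


PRE_CLASSES = ("exc", "inh")


@dataclass
class BalanceProfiles:
    """Depth-collapsed terms of the bouton/PST balance equation.

    Per presynaptic class c: the bouton profile B_c(z), the known-PST
    profile S_c(z) (spines plus any already-known surface terms), and per
    tied unknown group g = (pre class, post type, label) the surface-area
    profile A_g(z).
    """

    bouton_z: dict
    known_pst_z: dict
    area_z: dict
    unknown_groups: dict  # group -> list of meta keys it covers
    nz: int


def collapse_balance_profiles(network: NetworkModel,
                              meta: MetaConnectivity) -> BalanceProfiles:
    """Collapse all 3D balance terms to depth (grid z) profiles.

    Unknown alphas are tied by (presynaptic excitatory class, postsynaptic
    cell type, label); the spine densities lambda of all pre types within a
    class must agree for each (post type, label), since the 1D profile
    cannot identify a full type-by-type tensor.
    """
    grid = network.frame.grid
    nz = grid.dims[2]

    unknown_groups: dict[tuple, list] = {}
    for (pre, post, label) in meta.unknown_keys:
        c = _class_of(network.cell_types[pre].excitatory)
        unknown_groups.setdefault((c, post, label), []).append((pre, post, label))

    pre_types_by_class: dict[str, list[str]] = {c: [] for c in PRE_CLASSES}
    for name, ct in network.cell_types.items():
        pre_types_by_class[_class_of(ct.excitatory)].append(name)

    def class_densities(c: str, post: str, label: str):
        vals = {meta.densities(pre, post, label)
                for pre in pre_types_by_class[c]}
        if len(vals) > 1:
            raise FitError(
                f"PST densities for ({post}, {label}) differ across pre types "
                f"of class {c!r}; the class-tied fit requires them equal"
            )
        return vals.pop() if vals else (0.0, 0.0)

    bouton_z = {c: np.zeros(nz) for c in PRE_CLASSES}
    for n in network.neurons:
        if n.axon_morphology is None:
            continue
        bouton_z[_class_of(n.excitatory)] += neuron_bouton_field(
            network, n.id
        ).depth_profile()

    known_z = {c: np.zeros(nz) for c in PRE_CLASSES}
    area_z: dict[tuple, np.ndarray] = {g: np.zeros(nz) for g in unknown_groups}
    for n in network.neurons:
        morph = network.dendrite_geometry(n.id)
        if morph is None:
            continue
        fields = neuron_label_fields(morph, grid)
        for label, (length_field, area_field) in fields.items():
            lz = length_field.depth_profile()
            az = area_field.depth_profile()
            for c in PRE_CLASSES:
                lam, alpha = class_densities(c, n.cell_type, label)
                known_z[c] += lam * lz
                if alpha is not None:
                    known_z[c] += alpha * az
                elif (c, n.cell_type, label) in area_z:
                    area_z[(c, n.cell_type, label)] += az

    return BalanceProfiles(bouton_z=bouton_z, known_pst_z=known_z,
                           area_z=area_z, unknown_groups=unknown_groups, nz=nz)


def fit_surface_pst(network: NetworkModel, meta: MetaConnectivity,
                    bouton_profiles: dict | None = None,
                    ) -> tuple[MetaConnectivity, FitResult]:
    """Fit unknown surface-PST densities by the bouton/PST balance.

    The total bouton count from all presynaptic neurons should match the
    total PST count; collapsing both sides to depth (grid z) profiles per
    presynaptic excitatory class gives a small nonnegative least-squares
    problem (see :func:`collapse_balance_profiles` for the tying scheme).
    ``bouton_profiles`` optionally replaces the network's own bouton depth
    profiles (keyed by pre class), e.g., with independently measured totals.
    """
    profiles = collapse_balance_profiles(network, meta)
    nz = profiles.nz
    if not profiles.unknown_groups:
        return meta, FitResult({}, np.zeros(2 * nz), np.zeros(2 * nz),
                               np.zeros((2 * nz, 0)), [])
    bouton_z = profiles.bouton_z if bouton_profiles is None else bouton_profiles

    target = np.concatenate(
        [bouton_z[c] - profiles.known_pst_z[c] for c in PRE_CLASSES]
    )
    stacked = {}
    for g, az in profiles.area_z.items():
        prof = np.zeros(len(PRE_CLASSES) * nz)
        ci = PRE_CLASSES.index(g[0])
        prof[ci * nz:(ci + 1) * nz] = az
        stacked[g] = prof

    result = fit_alpha_profiles(target, stacked)
    alphas = {
        key: result.alpha_by_group[g]
        for g, keys in profiles.unknown_groups.items()
        for key in keys
    }
    return meta.with_alpha(alphas), result
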