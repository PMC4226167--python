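"""Synthetic input generation at toy scale, plus independent oracles.

Every input kind the pipeline consumes — reference-frame tables, soma
density fields, cell-type and frequency tables, SWC morphology libraries,
meta-connectivity tables, long-range axon counts — can be generated here
from a :class:`FixtureConfig`, reproducibly under a seed.  The generated
morphologies are parametric random trees (labeled, tapering, optionally
polar), not biological reconstructions: they exercise the geometry and
bookkeeping of the pipeline, not anatomical realism.

The module also provides dense brute-force oracles (Liang-Barsky slab
clipping per segment-voxel pair, dense numpy field arithmetic, explicit
64-term motif enumeration) that recompute pipeline outputs by an
independent route for ground-truth testing.  The oracle path shares only
I/O containers with the production path.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .assembly import (
    CellTypeSpec,
    MorphologyLibrary,
    MorphologyRecord,
    NetworkModel,
    NetworkSpecification,
    PlacedNeuron,
)
from .density_fields import MetaConnectivity
from .morphology import Morphology, RigidTransform
from .reference_frame import (
    Column,
    LaminarZone,
    ReferenceFrame,
    VoxelGrid,
    laminar_zone_of,
)

__all__ = [
    "FixtureConfig",
    "make_reference_frame",
    "make_densities",
    "make_cell_types",
    "make_frequencies",
    "make_meta",
    "make_morphology",
    "make_library",
    "make_input_bundle",
    "write_input_bundle",
    "load_input_bundle",
    "GroundTruth",
    "make_ground_truth_network",
    "oracle_label_fields",
    "oracle_bouton_field",
    "oracle_innervation_matrix",
    "oracle_configuration_probabilities",
]

ZONE_NAMES = ("supragranular", "granular", "infragranular")


@dataclass
class FixtureConfig:
    """Parameters of the synthetic toy model.

    Scale defaults target a two-column network of a few hundred neurons
    that runs the full pipeline in well under a minute.  Density units are
    10^3 somata per mm^3 (8.0 yields one soma per 50 um voxel); PST and
    bouton densities sit at the magnitudes typical for cortical neuropil
    (about one spine per um dendrite, a few tenths of a bouton per um
    axon, a few tenths of a PST per um^2 surface).
    """

    n_columns: int = 2
    spacing: float = 50.0
    dims: tuple[int, int, int] = (8, 8, 8)
    column_radius: float = 90.0
    seed: int = 0

    # soma densities (10^3 / mm^3)
    exc_density: float = 8.0
    inh_density: float = 8.0

    # morphology generator
    dendrite_length: float = 400.0
    axon_length: float = 900.0
    segment_length: float = 10.0
    n_basal_branches: int = 3
    tortuosity: float = 0.25
    n_long_range_morphologies: int = 6
    long_range_count: int = 8

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.dims, dtype=float) * self.spacing

    @property
    def zone_boundaries(self) -> tuple[float, float]:
        """Depth boundaries (um): supra/gran and gran/infra."""
        ez = self.extent[2]
        return (0.25 * ez, 0.5 * ez)


# ---------------------------------------------------------------------------
# reference frame and densities
# ---------------------------------------------------------------------------

def make_reference_frame(cfg: FixtureConfig) -> ReferenceFrame:
    """Columns in a row along x, parallel vertical axes, three zones each."""
    ex, ey, ez = cfg.extent
    columns, zones = [], []
    z1, z2 = cfg.zone_boundaries
    for i in range(cfg.n_columns):
        cid = f"C{i}"
        cx = ex * (i + 0.5) / cfg.n_columns
        columns.append(Column(
            id=cid, center=np.array([cx, ey / 2.0, ez / 2.0]),
            axis=np.array([0.0, 0.0, 1.0]), radius=cfg.column_radius,
            top_depth=-ez / 2.0, bottom_depth=ez / 2.0,
        ))
        zones.extend([
            LaminarZone(cid, ZONE_NAMES[0], 0.0, z1),
            LaminarZone(cid, ZONE_NAMES[1], z1, z2),
            LaminarZone(cid, ZONE_NAMES[2], z2, ez),
        ])
    grid = VoxelGrid(origin=np.zeros(3), spacing=cfg.spacing, dims=cfg.dims)
    return ReferenceFrame(grid, columns, zones)


def make_densities(cfg: FixtureConfig,
                   frame: ReferenceFrame) -> tuple[np.ndarray, np.ndarray]:
    """Soma density fields (10^3 / mm^3): excitatory density inside the
    column cylinders and in every other septum voxel; inhibitory density on
    a sparse deterministic lattice throughout."""
    exc = np.zeros(cfg.dims)
    inh = np.zeros(cfg.dims)
    for idx in frame.grid.voxel_indices():
        center = frame.grid.voxel_center(idx)
        in_col = any(c.radial_distance(center) <= c.radius
                     for c in frame.columns)
        i, j, k = idx
        if in_col:
            exc[idx] = cfg.exc_density
        elif (i + j) % 2 == 0:
            exc[idx] = cfg.exc_density
        if (i + j + k) % 4 == 0:
            inh[idx] = cfg.inh_density
    return exc, inh


# ---------------------------------------------------------------------------
# cell types, frequencies, meta-connectivity
# ---------------------------------------------------------------------------

def make_cell_types(cfg: FixtureConfig) -> dict[str, CellTypeSpec]:
    """Three local types (one polar, one inhibitory) plus a long-range
    thalamocortical axon type concentrated in the granular zone."""
    supra, gran, infra = ZONE_NAMES
    return {
        "EXC": CellTypeSpec(
            name="EXC", excitatory=True, occupancy="both",
            bouton_density_per_zone={supra: 0.20, gran: 0.30, infra: 0.20},
        ),
        "L4SS": CellTypeSpec(
            name="L4SS", excitatory=True, rotate_polar=True,
            occupancy="column",
            bouton_density_per_zone={supra: 0.20, gran: 0.30, infra: 0.20},
        ),
        "INH": CellTypeSpec(
            name="INH", excitatory=False, occupancy="both",
            bouton_density_per_zone={supra: 0.15, gran: 0.15, infra: 0.15},
        ),
        "TC": CellTypeSpec(
            name="TC", excitatory=True, axon_only=True, occupancy="both",
            bouton_density_per_zone={supra: 0.10, gran: 0.35, infra: 0.25},
            long_range_count=cfg.long_range_count,
        ),
    }


def make_frequencies(cfg: FixtureConfig, frame: ReferenceFrame):
    """Relative frequency table: polar type only inside columns."""
    import pandas as pd
    rows = []
    for c in frame.columns:
        rows.extend([
            {"region": c.id, "inside_column": True, "cell_type": "EXC",
             "frequency": 0.5},
            {"region": c.id, "inside_column": True, "cell_type": "L4SS",
             "frequency": 0.5},
            {"region": c.id, "inside_column": True, "cell_type": "INH",
             "frequency": 1.0},
            {"region": c.id, "inside_column": False, "cell_type": "EXC",
             "frequency": 1.0},
            {"region": c.id, "inside_column": False, "cell_type": "INH",
             "frequency": 1.0},
        ])
    return pd.DataFrame(rows)


def make_meta(cfg: FixtureConfig, unknown_alpha: bool = False) -> MetaConnectivity:
    """Meta-connectivity: excitatory boutons target spines of excitatory
    neurons (length PSTs) and surfaces of inhibitory neurons (area PSTs);
    inhibitory boutons target surfaces of everyone.  ``unknown_alpha``
    blanks all surface densities for the fitting workflow."""
    lam_basal, lam_apical = 1.0, 0.8
    a_soma, a_dend = 0.4, 0.3
    entries: dict = {}
    exc_pre = ("EXC", "L4SS", "TC")
    exc_post = ("EXC", "L4SS")
    for pre in exc_pre:
        for post in exc_post:
            entries[(pre, post, "basal")] = (lam_basal, 0.0)
            entries[(pre, post, "apical")] = (lam_apical, 0.0)
        entries[(pre, "INH", "soma")] = (0.0, None if unknown_alpha else a_soma)
        entries[(pre, "INH", "basal")] = (0.0, None if unknown_alpha else a_dend)
    for post in ("EXC", "L4SS", "INH"):
        entries[("INH", post, "soma")] = (0.0, None if unknown_alpha else a_soma)
        entries[("INH", post, "basal")] = (0.0, None if unknown_alpha else a_dend)
    return MetaConnectivity(entries)


# ---------------------------------------------------------------------------
# morphology generator
# ---------------------------------------------------------------------------

def _grow_branch(rng: np.random.Generator, start: np.ndarray,
                 direction: np.ndarray, length: float, seg_len: float,
                 tortuosity: float, r_start: float, r_end: float):
    """Random-walk branch with direction persistence and linear taper.

    Returns (positions, radii) excluding the start node; segment lengths
    sum exactly to ``length`` (the last step is truncated).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pos = np.asarray(start, dtype=float).copy()
    remaining = length
    positions, radii = [], []
    grown = 0.0
    while remaining > 1e-9:
        step = min(seg_len, remaining)
        d = d + tortuosity * rng.standard_normal(3)
        d = d / np.linalg.norm(d)
        pos = pos + d * step
        grown += step
        remaining -= step
        positions.append(pos.copy())
        radii.append(r_start + (r_end - r_start) * grown / length)
    return positions, radii


def make_morphology(rng: np.random.Generator, kind: str = "dendrite",
                    soma_position=(0.0, 0.0, 0.0),
                    total_length: float | None = None,
                    polar_bearing=None,
                    cfg: FixtureConfig | None = None) -> Morphology:
    """Random labeled tree morphology.

    Kinds: ``dendrite`` (soma + basal branches + one apical trunk toward
    the pia), ``polar_dendrite`` (basal branches biased toward
    ``polar_bearing``), ``axon`` (soma root + axon arbor).  Total branch
    length is honored exactly by construction.
    """
    cfg = cfg or FixtureConfig()
    soma = np.asarray(soma_position, dtype=float)
    positions = [soma]
    radii = [5.0]
    labels = ["soma"]
    parents = [-1]

    def add_branch(direction, length, label, r0, r1, tortuosity=None):
        pts, rr = _grow_branch(
            rng, soma, direction, length, cfg.segment_length,
            cfg.tortuosity if tortuosity is None else tortuosity, r0, r1,
        )
        parent = 0
        for p, r in zip(pts, rr):
            positions.append(p)
            radii.append(r)
            labels.append(label)
            parents.append(parent)
            parent = len(positions) - 1

    if kind == "axon":
        total = total_length if total_length is not None else cfg.axon_length
        n_branches = 4
        for _ in range(n_branches):
            d = rng.standard_normal(3)
            d[2] *= 0.4  # axons spread mostly laterally in the toy model
            add_branch(d, total / n_branches, "axon", 0.5, 0.2)
    elif kind in ("dendrite", "polar_dendrite"):
        total = total_length if total_length is not None else cfg.dendrite_length
        apical_share = 0.3
        n_basal = cfg.n_basal_branches
        basal_len = total * (1.0 - apical_share) / n_basal
        for _ in range(n_basal):
            if kind == "polar_dendrite":
                b = np.asarray(polar_bearing, dtype=float)
                b = b / np.linalg.norm(b)
                d = b + 0.3 * rng.standard_normal(3)
                tort = 0.1
            else:
                d = rng.standard_normal(3)
                tort = None
            add_branch(d, basal_len, "basal", 1.2, 0.3, tortuosity=tort)
        # apical trunk toward the pia (decreasing depth, -z)
        add_branch(np.array([0.0, 0.0, -1.0]) + 0.2 * rng.standard_normal(3),
                   total * apical_share, "apical", 1.6, 0.4, tortuosity=0.1)
    else:
        raise ValueError(f"unknown morphology kind {kind!r}")

    return Morphology(np.array(positions), np.array(radii),
                      np.array(labels, dtype=object), np.array(parents))


def make_library(cfg: FixtureConfig, frame: ReferenceFrame,
                 rng: np.random.Generator,
                 cell_types: dict[str, CellTypeSpec] | None = None,
                 ) -> MorphologyLibrary:
    """Registered library: one morphology per (type, column, voxel depth).

    Depth coverage every voxel guarantees that the dendrite-selection depth
    criterion (|dz| within one voxel) always has candidates.  Local types
    get combined dendrite+axon reconstructions; the long-range type gets
    axon-only reconstructions registered at granular depth.
    """
    cell_types = cell_types or make_cell_types(cfg)
    nz = cfg.dims[2]
    records = []
    for col in frame.columns:
        for name, ct in sorted(cell_types.items()):
            if ct.long_range_count is not None:
                z1, z2 = cfg.zone_boundaries
                depth = 0.5 * (z1 + z2)
                for m_idx in range(cfg.n_long_range_morphologies):
                    soma = _registered_soma(cfg, col, depth, rng)
                    axon = make_morphology(rng, "axon", soma, cfg=cfg)
                    records.append(MorphologyRecord(
                        morphology_id=f"{name}_{col.id}_{m_idx}",
                        morphology=axon, cell_type=name, column_id=col.id,
                        soma_depth=depth,
                    ))
                continue
            if ct.axon_only:
                continue
            for k in range(nz):
                depth = (k + 0.5) * cfg.spacing
                soma = _registered_soma(cfg, col, depth, rng)
                kind = "polar_dendrite" if ct.rotate_polar else "dendrite"
                bearing = col.center - soma if ct.rotate_polar else None
                dend = make_morphology(rng, kind, soma,
                                       polar_bearing=bearing, cfg=cfg)
                axon = make_morphology(rng, "axon", soma, cfg=cfg)
                merged = _merge_morphologies(dend, axon)
                records.append(MorphologyRecord(
                    morphology_id=f"{name}_{col.id}_{k}",
                    morphology=merged, cell_type=name, column_id=col.id,
                    soma_depth=depth,
                ))
    return MorphologyLibrary(records)


def _registered_soma(cfg: FixtureConfig, col: Column, depth: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Soma position inside the column at the given pia depth, with a
    radial offset so that polar bearings are well defined."""
    angle = rng.uniform(0.0, 2.0 * np.pi)
    radial = rng.uniform(0.3, 0.6) * col.radius
    offset = radial * np.array([math.cos(angle), math.sin(angle), 0.0])
    s = col.top_depth + depth
    return col.center + s * col.axis + offset


def _merge_morphologies(a: Morphology, b: Morphology) -> Morphology:
    """Concatenate two trees sharing the same soma (b's root is dropped and
    its children re-rooted on a's root)."""
    nb = b.parents.copy()
    b_root = int(np.flatnonzero(b.parents < 0)[0])
    keep = [i for i in range(b.n_nodes) if i != b_root]
    remap = {old: len(a.positions) + new for new, old in enumerate(keep)}
    parents_b = []
    for old in keep:
        p = nb[old]
        parents_b.append(0 if p == b_root else remap[p])
    return Morphology(
        np.vstack([a.positions, b.positions[keep]]),
        np.concatenate([a.radii, b.radii[keep]]),
        np.concatenate([a.labels, b.labels[keep]]),
        np.concatenate([a.parents, np.asarray(parents_b, dtype=int)]),
    )


# ---------------------------------------------------------------------------
# input bundle
# ---------------------------------------------------------------------------

def make_input_bundle(cfg: FixtureConfig) -> NetworkSpecification:
    """In-memory bundle of all seven input kinds, reproducible under
    ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    frame = make_reference_frame(cfg)
    exc, inh = make_densities(cfg, frame)
    cell_types = make_cell_types(cfg)
    return NetworkSpecification(
        frame=frame, excitatory_density=exc, inhibitory_density=inh,
        cell_types=cell_types, frequencies=make_frequencies(cfg, frame),
        library=make_library(cfg, frame, rng, cell_types),
    )


def write_input_bundle(cfg: FixtureConfig, out_dir) -> Path:
    """Write the bundle to disk as CSV/SWC/JSON files; returns the dir."""
    from . import io as dio
    from .reference_frame import save_columns, save_zones

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = make_input_bundle(cfg)
    save_columns(spec.frame.columns, out / "columns.csv")
    save_zones(spec.frame.zones, out / "zones.csv")
    dio.save_cell_types(spec.cell_types, out / "cell_types.csv")
    dio.save_frequencies(spec.frequencies, out / "frequencies.csv")
    make_meta(cfg).to_csv(out / "meta.csv")
    dio.save_library(spec.library, out)
    np.savetxt(out / "density_exc.csv",
               spec.excitatory_density.reshape(-1), delimiter=",")
    np.savetxt(out / "density_inh.csv",
               spec.inhibitory_density.reshape(-1), delimiter=",")
    with open(out / "config.json", "w") as fh:
        json.dump({**asdict(cfg), "grid": {
            "origin": [0.0, 0.0, 0.0], "spacing": cfg.spacing,
            "dims": list(cfg.dims)}}, fh, indent=2)
    return out


def load_input_bundle(bundle_dir) -> tuple[NetworkSpecification, MetaConnectivity]:
    """Read a bundle written by :func:`write_input_bundle`."""
    from . import io as dio
    from .reference_frame import load_columns, load_zones

    d = Path(bundle_dir)
    with open(d / "config.json") as fh:
        raw = json.load(fh)
    gspec = raw.pop("grid")
    raw["dims"] = tuple(raw["dims"])
    cfg = FixtureConfig(**raw)
    grid = VoxelGrid(origin=np.asarray(gspec["origin"]),
                     spacing=gspec["spacing"], dims=tuple(gspec["dims"]))
    frame = ReferenceFrame(grid, load_columns(d / "columns.csv"),
                           load_zones(d / "zones.csv"))
    cell_types = dio.load_cell_types(d / "cell_types.csv")
    spec = NetworkSpecification(
        frame=frame,
        excitatory_density=np.loadtxt(d / "density_exc.csv",
                                      delimiter=",").reshape(cfg.dims),
        inhibitory_density=np.loadtxt(d / "density_inh.csv",
                                      delimiter=",").reshape(cfg.dims),
        cell_types=cell_types,
        frequencies=dio.load_frequencies(d / "frequencies.csv"),
        library=dio.load_library(d / "manifest.csv"),
    )
    meta = MetaConnectivity.from_csv(d / "meta.csv")
    return spec, meta


# ---------------------------------------------------------------------------
# sparse-sample saturation experiment
# ---------------------------------------------------------------------------

def convergence_vs_axon_sample(cfg: FixtureConfig, sizes=(1, 2, 3, 5),
                               n_draws: int = 4, seed: int = 0,
                               pre_type: str = "TC", post_type: str = "L4SS",
                               column_id: str = "C0"):
    """Mean convergence vs the number of long-range axon reconstructions.

    Emulates the protocol of progressively enlarging the sparse axon sample
    used for up-scaling: for each sample size k, the long-range library is
    restricted to k randomly drawn reconstructions per column (``n_draws``
    independent draws), the network is re-assembled, and the mean
    convergence from the long-range type onto the target population is
    measured.  Returns a dict ``size -> list of mean convergences``; the
    spread across draws shrinks as the sample captures the projection
    variability of the cell type.
    """
    from .assembly import build_network
    from .innervation import pairwise_innervation
    from .population_stats import population_summary

    spec = make_input_bundle(cfg)
    meta = make_meta(cfg)
    tc_records = [r for r in spec.library.records if r.cell_type == pre_type]
    other_records = [r for r in spec.library.records
                     if r.cell_type != pre_type]
    by_column: dict[str, list] = {}
    for r in tc_records:
        by_column.setdefault(r.column_id, []).append(r)

    rng = np.random.default_rng(seed)
    results: dict[int, list[float]] = {}
    for size in sizes:
        results[size] = []
        for _ in range(n_draws):
            chosen = []
            for recs in by_column.values():
                take = min(size, len(recs))
                idx = rng.choice(len(recs), size=take, replace=False)
                chosen.extend(recs[i] for i in idx)
            sub = NetworkSpecification(
                frame=spec.frame,
                excitatory_density=spec.excitatory_density,
                inhibitory_density=spec.inhibitory_density,
                cell_types=spec.cell_types, frequencies=spec.frequencies,
                library=MorphologyLibrary(other_records + chosen),
            )
            net = build_network(sub, seed=cfg.seed)
            pre = net.select(cell_type=pre_type, column_id=column_id)
            post = net.select(cell_type=post_type, column_id=column_id)
            matrix = pairwise_innervation(net, pre, post, meta)
            stats = population_summary(matrix)
            results[size].append(stats.convergence_mean)
    return results


# ---------------------------------------------------------------------------
# dense brute-force oracles
# ---------------------------------------------------------------------------

def oracle_label_fields(m: Morphology, label: str,
                        grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray]:
    """Dense per-voxel length and area of a label by slab clipping.

    For every (segment, voxel) pair within the segment's bounding box the
    parametric overlap interval is found by Liang-Barsky slab
    intersection; lengths and frustum areas accrue per voxel.  Independent
    of the production face-splitting algorithm.
    """
    length = np.zeros(grid.dims)
    area = np.zeros(grid.dims)

    if label == "soma":
        soma_nodes = np.flatnonzero(m.labels == "soma")
        if len(soma_nodes) == 1:
            pos = m.positions[soma_nodes[0]]
            if grid.contains(pos):
                area[grid.point_to_voxel(pos)] += 4.0 * math.pi * \
                    m.radii[soma_nodes[0]]**2
            return length, area

    for child in m.edges:
        if m.labels[child] != label:
            continue
        parent = m.parents[child]
        p0, p1 = m.positions[parent], m.positions[child]
        r0, r1 = m.radii[parent], m.radii[child]
        seg = p1 - p0
        seglen = float(np.linalg.norm(seg))
        if seglen == 0.0:
            continue
        lo_idx = np.maximum(
            np.floor((np.minimum(p0, p1) - grid.origin) / grid.spacing), 0
        ).astype(int)
        hi_idx = np.minimum(
            np.floor((np.maximum(p0, p1) - grid.origin) / grid.spacing),
            np.asarray(grid.dims) - 1
        ).astype(int)
        for i in range(lo_idx[0], hi_idx[0] + 1):
            for j in range(lo_idx[1], hi_idx[1] + 1):
                for k in range(lo_idx[2], hi_idx[2] + 1):
                    t0, t1 = 0.0, 1.0
                    ok = True
                    for a, idx_a in enumerate((i, j, k)):
                        lo = grid.origin[a] + idx_a * grid.spacing
                        hi = lo + grid.spacing
                        if seg[a] == 0.0:
                            if not (lo <= p0[a] < hi):
                                ok = False
                                break
                        else:
                            ta = (lo - p0[a]) / seg[a]
                            tb = (hi - p0[a]) / seg[a]
                            if ta > tb:
                                ta, tb = tb, ta
                            t0 = max(t0, ta)
                            t1 = min(t1, tb)
                            if t0 >= t1:
                                ok = False
                                break
                    if not ok:
                        continue
                    piece = seglen * (t1 - t0)
                    ra = r0 + (r1 - r0) * t0
                    rb = r0 + (r1 - r0) * t1
                    length[i, j, k] += piece
                    area[i, j, k] += math.pi * (ra + rb) * piece
    return length, area


def oracle_bouton_field(network: NetworkModel, neuron_id: int) -> np.ndarray:
    """Dense bouton field of a neuron's axon (independent route)."""
    n = network.neuron(neuron_id)
    axon = network.axon_geometry(neuron_id)
    grid = network.frame.grid
    if axon is None:
        return np.zeros(grid.dims)
    length, _ = oracle_label_fields(axon, "axon", grid)
    densities = network.cell_types[n.cell_type].bouton_density_per_zone
    out = np.zeros(grid.dims)
    for idx in grid.voxel_indices():
        if length[idx] > 0:
            zone = laminar_zone_of(grid.voxel_center(idx), network.frame)
            out[idx] = length[idx] * densities[zone]
    return out


def oracle_innervation_matrix(network: NetworkModel,
                              meta: MetaConnectivity) -> np.ndarray:
    """Dense n x n innervation matrix by brute force over all voxels."""
    grid = network.frame.grid
    n = len(network.neurons)
    pre_types = sorted({nn.cell_type for nn in network.neurons})

    pst = {}
    for j, nj in enumerate(network.neurons):
        morph = network.dendrite_geometry(nj.id)
        if morph is None:
            continue
        fields = {lab: oracle_label_fields(morph, lab, grid)
                  for lab in ("soma", "apical", "basal")}
        for t in pre_types:
            acc = np.zeros(grid.dims)
            for lab, (lf, af) in fields.items():
                lam, alpha = meta.densities(t, nj.cell_type, lab)
                acc += lam * lf + (alpha or 0.0) * af
            pst[(nj.id, t)] = acc

    pst_all = {t: np.sum([f for (j, tt), f in pst.items() if tt == t], axis=0)
               for t in pre_types}

    I = np.zeros((n, n))
    for i, ni in enumerate(network.neurons):
        B = oracle_bouton_field(network, ni.id)
        t = ni.cell_type
        denom = pst_all[t]
        for j, nj in enumerate(network.neurons):
            if (nj.id, t) not in pst:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(denom > 0, pst[(nj.id, t)] / denom, 0.0)
            I[i, j] = float(np.sum(B * p))
    return I


def oracle_configuration_probabilities(p6) -> np.ndarray:
    """Probability of each of the 64 triplet edge configurations by
    explicit enumeration (independent of the motif-class machinery)."""
    p6 = np.asarray(p6, dtype=float)
    out = np.zeros(64)
    for bits in itertools.product((0, 1), repeat=6):
        config = sum(b << i for i, b in enumerate(bits))
        prob = 1.0
        for b, p in zip(bits, p6):
            prob *= p if b else (1.0 - p)
        out[config] = prob
    return out


# ---------------------------------------------------------------------------
# ground-truth network
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """A tiny directly-placed network with every output precomputable."""

    network: NetworkModel
    meta: MetaConnectivity
    meta_unknown: MetaConnectivity
    alpha_star: dict           # (pre_class, post_type, label) -> true alpha
    balanced_bouton_z: dict    # pre class -> bouton depth profile balancing
                               # the PSTs under alpha_star
    frame: ReferenceFrame


def _ground_truth_meta(unknown: bool) -> MetaConnectivity:
    """Spines for exc->exc; surface PSTs only for exc->INH (soma+basal) so
    the depth-profile fit is identifiable with two unknowns."""
    a_soma, a_basal = 0.4, 0.25
    entries = {
        ("EXC", "EXC", "basal"): (1.0, 0.0),
        ("EXC", "EXC", "apical"): (0.8, 0.0),
        ("EXC", "INH", "soma"): (0.0, None if unknown else a_soma),
        ("EXC", "INH", "basal"): (0.0, None if unknown else a_basal),
        ("INH", "EXC", "basal"): (0.35, 0.0),
        ("INH", "EXC", "apical"): (0.35, 0.0),
        ("INH", "INH", "basal"): (0.35, 0.0),
    }
    return MetaConnectivity(entries)


def make_ground_truth_network(n_neurons: int = 6, seed: int = 0) -> GroundTruth:
    """Directly place <= 10 neurons in a one-column frame.

    Neurons keep their generated coordinates (identity transforms), so the
    dense oracle and the production pipeline see identical geometry.  The
    balanced bouton profiles are constructed from the oracle's collapsed
    PST profiles under the true surface densities, giving an exact
    recovery target for the surface-PST fit.
    """
    if not 3 <= n_neurons <= 10:
        raise ValueError("the ground-truth oracle path supports 3..10 neurons")
    cfg = FixtureConfig(n_columns=1, dims=(6, 6, 6), column_radius=120.0,
                        dendrite_length=300.0, axon_length=600.0, seed=seed)
    frame = make_reference_frame(cfg)
    rng = np.random.default_rng(seed)

    cell_types = {
        "EXC": CellTypeSpec(
            name="EXC", excitatory=True,
            bouton_density_per_zone={z: d for z, d in
                                     zip(ZONE_NAMES, (0.2, 0.3, 0.2))},
        ),
        "INH": CellTypeSpec(
            name="INH", excitatory=False,
            bouton_density_per_zone={z: 0.15 for z in ZONE_NAMES},
        ),
    }
    meta = _ground_truth_meta(unknown=False)
    meta_unknown = _ground_truth_meta(unknown=True)

    lo = 90.0
    hi = cfg.extent - 90.0
    neurons, morphologies = [], {}
    n_inh = max(2, n_neurons // 3)
    for nid in range(n_neurons):
        soma = lo + rng.random(3) * (hi - lo)
        ct = "INH" if nid < n_inh else "EXC"
        dend = make_morphology(rng, "dendrite", soma, cfg=cfg)
        axon = make_morphology(rng, "axon", soma, cfg=cfg)
        did, aid = f"d{nid}", f"a{nid}"
        morphologies[did] = dend
        morphologies[aid] = axon
        cid, inside = frame.columns[0].id, frame.columns[0].contains(soma)
        neurons.append(PlacedNeuron(
            id=nid, soma_position=dend.soma_position, column_id=cid,
            inside_column=inside, cell_type=ct,
            excitatory=cell_types[ct].excitatory,
            dendrite_morphology=did,
            dendrite_transform=RigidTransform.identity(),
            axon_morphology=aid,
        ))
    network = NetworkModel(frame=frame, neurons=neurons,
                           morphologies=morphologies, cell_types=cell_types)

    # balanced bouton profiles: spine PSTs plus alpha* times area profiles,
    # computed by the oracle route
    nz = cfg.dims[2]
    alpha_star = {("exc", "INH", "soma"): 0.4, ("exc", "INH", "basal"): 0.25}
    spine_exc = np.zeros(nz)
    area_profiles = {g: np.zeros(nz) for g in alpha_star}
    for n in neurons:
        morph = network.dendrite_geometry(n.id)
        for lab in ("soma", "apical", "basal"):
            lf, af = oracle_label_fields(morph, lab, frame.grid)
            lam, _ = meta.densities("EXC", n.cell_type, lab)
            spine_exc += lam * lf.sum(axis=(0, 1))
            g = ("exc", n.cell_type, lab)
            if g in area_profiles:
                area_profiles[g] += af.sum(axis=(0, 1))
    balanced = {
        "exc": spine_exc + sum(alpha_star[g] * area_profiles[g]
                               for g in alpha_star),
        "inh": None,  # filled below
    }
    # inhibitory class has no unknowns; balance it with its own known PSTs
    inh_known = np.zeros(nz)
    for n in neurons:
        morph = network.dendrite_geometry(n.id)
        for lab in ("soma", "apical", "basal"):
            lf, af = oracle_label_fields(morph, lab, frame.grid)
            lam, alpha = meta.densities("INH", n.cell_type, lab)
            inh_known += lam * lf.sum(axis=(0, 1)) + \
                (alpha or 0.0) * af.sum(axis=(0, 1))
    balanced["inh"] = inh_known

    return GroundTruth(network=network, meta=meta, meta_unknown=meta_unknown,
                       alpha_star=alpha_star, balanced_bouton_z=balanced,
                       frame=frame)
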