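"""Network assembly: up-scale sparse morphologies into an average dense model.

The assembly pipeline turns measured 3D soma-density fields plus a sparse
library of registered reconstructions into a dense network model:

1. somata are placed voxel by voxel — the density (in 10^3 somata per mm^3)
   times the voxel volume, rounded half-up to the nearest integer, positions
   uniform within the voxel;
2. each soma is labeled with its nearest column, column/septum membership,
   and a cell type drawn from the region's relative-frequency table;
3. a dendrite morphology of that type, registered to the same column and
   within one voxel of the soma's depth, is translated to the soma and
   rotated about the local vertical axis (uniform azimuth, or
   bearing-preserving for cell types with polar dendrites);
4. an axon morphology of that type and column is selected but NOT moved, so
   location-specific projection patterns survive up-scaling;
5. long-range axon types (somata outside the region, e.g., thalamocortical)
   are duplicated round-robin until the prescribed per-column count is met.

Randomness is fanned out from a single seed into independent child streams
per stage and per neuron id, so results do not depend on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import Morphology, RigidTransform, rotation_about_axis
from .reference_frame import ReferenceFrame, VoxelGrid, local_axis, nearest_column

__all__ = [
    "CellTypeSpec",
    "MorphologyRecord",
    "MorphologyLibrary",
    "PlacedNeuron",
    "NetworkModel",
    "NetworkSpecification",
    "AssemblyError",
    "sample_somata",
    "assign_cell_type",
    "select_dendrite",
    "select_axon",
    "upscale_long_range",
    "build_network",
]

# stage constants for seed fan-out (spawn_key prefixes)
_STAGE_SOMATA = 0
_STAGE_ASSIGN = 1
_STAGE_DENDRITE = 2
_STAGE_AXON = 3
_STAGE_LONG_RANGE = 4


class AssemblyError(RuntimeError):
    """Assembly cannot proceed (empty candidate set, inconsistent inputs)."""


@dataclass(frozen=True)
class CellTypeSpec:
    """Static properties of an axo-dendritic cell type.

    ``bouton_density_per_zone`` maps laminar-zone name to boutons per um of
    axon; ``occupancy`` restricts where somata of the type occur;
    ``long_range_count`` is the per-column number of axons for types whose
    somata lie outside the modeled region (e.g., 311 thalamocortical axons
    per barreloid).
    """

    name: str
    excitatory: bool
    rotate_polar: bool = False
    axon_only: bool = False
    occupancy: str = "both"  # {column, septum, both}
    bouton_density_per_zone: dict = field(default_factory=dict)
    long_range_count: int | None = None

    def __post_init__(self):
        if self.occupancy not in ("column", "septum", "both"):
            raise ValueError(f"invalid occupancy {self.occupancy!r}")
        if any(v < 0 for v in self.bouton_density_per_zone.values()):
            raise ValueError("bouton densities must be non-negative")
        if self.long_range_count is not None and self.long_range_count < 1:
            raise ValueError("long_range_count must be >= 1")

    def allows(self, inside_column: bool) -> bool:
        if self.occupancy == "both":
            return True
        return self.occupancy == ("column" if inside_column else "septum")


@dataclass(frozen=True)
class MorphologyRecord:
    """A registered library reconstruction.

    ``soma_depth`` is the registered soma depth below the pia along the
    column axis (um), used for the depth criterion of dendrite selection.
    """

    morphology_id: str
    morphology: Morphology
    cell_type: str
    column_id: str
    soma_depth: float


class MorphologyLibrary:
    """Lookup structure over :class:`MorphologyRecord` entries."""

    def __init__(self, records: list[MorphologyRecord]):
        if len({r.morphology_id for r in records}) != len(records):
            raise ValueError("morphology ids must be unique")
        self.records = list(records)
        self._by_id = {r.morphology_id: r for r in records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, morphology_id: str) -> MorphologyRecord:
        return self._by_id[morphology_id]

    def of_type(self, cell_type: str, column_id: str | None = None):
        return [
            r for r in self.records
            if r.cell_type == cell_type
            and (column_id is None or r.column_id == column_id)
        ]

    @property
    def morphologies(self) -> dict[str, Morphology]:
        return {r.morphology_id: r.morphology for r in self.records}


@dataclass
class PlacedNeuron:
    """One neuron of the assembled network.

    Long-range axon instances have no local dendrite: ``dendrite_morphology``
    and ``dendrite_transform`` are None and the soma position is the axon
    reconstruction's registered soma/root location.
    """

    id: int
    soma_position: np.ndarray
    column_id: str
    inside_column: bool
    cell_type: str
    excitatory: bool
    dendrite_morphology: str | None = None
    dendrite_transform: RigidTransform | None = None
    axon_morphology: str | None = None


@dataclass
class NetworkModel:
    """Assembled dense model: placed neurons + shared morphology library."""

    frame: ReferenceFrame
    neurons: list[PlacedNeuron]
    morphologies: dict[str, Morphology]
    cell_types: dict[str, CellTypeSpec]

    def __post_init__(self):
        self._dendrite_cache: dict[int, Morphology] = {}

    def neuron(self, neuron_id: int) -> PlacedNeuron:
        return self.neurons[neuron_id]

    def select(self, cell_type=None, column_id=None, inside_column=None,
               excitatory=None) -> list[int]:
        """Neuron ids matching the given annotations (None = any)."""
        types = None
        if cell_type is not None:
            types = {cell_type} if isinstance(cell_type, str) else set(cell_type)
        out = []
        for n in self.neurons:
            if types is not None and n.cell_type not in types:
                continue
            if column_id is not None and n.column_id != column_id:
                continue
            if inside_column is not None and n.inside_column != inside_column:
                continue
            if excitatory is not None and n.excitatory != excitatory:
                continue
            out.append(n.id)
        return out

    def dendrite_geometry(self, neuron_id: int) -> Morphology | None:
        """Transformed (placed) soma/dendrite morphology of a neuron."""
        if neuron_id not in self._dendrite_cache:
            n = self.neurons[neuron_id]
            if n.dendrite_morphology is None:
                return None
            from .morphology import apply_transform
            m = apply_transform(
                self.morphologies[n.dendrite_morphology], n.dendrite_transform
            )
            self._dendrite_cache[neuron_id] = m
        return self._dendrite_cache[neuron_id]

    def axon_geometry(self, neuron_id: int) -> Morphology | None:
        """Axon morphology of a neuron (untransformed by construction)."""
        n = self.neurons[neuron_id]
        if n.axon_morphology is None:
            return None
        return self.morphologies[n.axon_morphology]

    def counts_by_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.neurons:
            out[n.cell_type] = out.get(n.cell_type, 0) + 1
        return out


@dataclass
class NetworkSpecification:
    """Bundle of all anatomical inputs consumed by :func:`build_network`."""

    frame: ReferenceFrame
    excitatory_density: np.ndarray  # 10^3 somata / mm^3, shape = grid dims
    inhibitory_density: np.ndarray
    cell_types: dict[str, CellTypeSpec]
    frequencies: pd.DataFrame  # region, inside_column, cell_type, frequency
    library: MorphologyLibrary


def _rng_for(seed: int, stage: int, item: int = 0) -> np.random.Generator:
    """Child stream for (stage, item), independent of iteration order."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stage, item))
    )


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def sample_somata(density: np.ndarray, grid: VoxelGrid,
                  rng: np.random.Generator) -> np.ndarray:
    """Place somata from a per-voxel density field (10^3 somata per mm^3).

    Per voxel the count is ``density * 1e3 * voxel_volume_mm3`` rounded
    half-up; positions are independent uniform draws within the voxel.
    Returns an (n, 3) array.
    """
    density = np.asarray(density, dtype=float)
    if density.shape != tuple(grid.dims):
        raise ValueError(f"density shape {density.shape} != grid dims {grid.dims}")
    if np.any(density < 0):
        raise ValueError("soma density must be non-negative")
    counts = np.floor(density * 1e3 * grid.voxel_volume_mm3 + 0.5).astype(int)
    points = []
    for idx in np.argwhere(counts > 0):
        n = counts[tuple(idx)]
        lo = grid.origin + idx * grid.spacing
        points.append(lo + rng.random((n, 3)) * grid.spacing)
    if not points:
        return np.empty((0, 3))
    return np.concatenate(points, axis=0)


def expected_soma_count(density: np.ndarray, grid: VoxelGrid) -> int:
    """Deterministic total soma count implied by a density field."""
    density = np.asarray(density, dtype=float)
    return int(np.floor(density * 1e3 * grid.voxel_volume_mm3 + 0.5).sum())


def assign_cell_type(p, frame: ReferenceFrame, frequencies: pd.DataFrame,
                     cell_types: dict[str, CellTypeSpec],
                     rng: np.random.Generator, excitatory: bool) -> str:
    """Draw a cell type for a soma at ``p`` from the region's frequency table.

    The region is (nearest column, inside/septum).  Eligible rows must match
    the soma's excitatory class, respect the type's occupancy flag, and not
    be long-range axon-only types.  Frequencies among eligible rows must sum
    to 1 within 1e-9.
    """
    cid, inside = nearest_column(p, frame)
    rows = frequencies[
        (frequencies["region"] == cid)
        & (frequencies["inside_column"] == inside)
    ]
    names, probs = [], []
    for _, row in rows.iterrows():
        ct = cell_types[row["cell_type"]]
        if ct.excitatory != excitatory or ct.axon_only:
            continue
        if not ct.allows(inside):
            continue
        names.append(ct.name)
        probs.append(float(row["frequency"]))
    if not names:
        raise AssemblyError(
            f"no eligible cell type for region {cid!r} "
            f"({'column' if inside else 'septum'}, "
            f"{'excitatory' if excitatory else 'inhibitory'})"
        )
    total = sum(probs)
    if abs(total - 1.0) > 1e-9:
        raise AssemblyError(
            f"frequencies in region {cid!r} sum to {total}, expected 1"
        )
    return names[int(rng.choice(len(names), p=probs))]


def _perp(v: np.ndarray, axis: np.ndarray) -> np.ndarray:
    return v - np.dot(v, axis) * axis


def _signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    return float(np.arctan2(np.dot(np.cross(a, b), axis), np.dot(a, b)))


def select_dendrite(p, cell_type: str, library: MorphologyLibrary,
                    frame: ReferenceFrame, rng: np.random.Generator,
                    spec: CellTypeSpec) -> tuple[str, RigidTransform]:
    """Pick and orient a dendrite morphology for a soma at ``p``.

    Candidates must (1) match the cell type, (2) be registered to the
    nearest column, and (3) have a registered soma depth within one voxel of
    the new soma's depth along the column axis.  The selected morphology is
    translated to ``p`` and rotated about the local vertical axis — by a
    uniform random azimuth, or, for polar cell types, by the angle that
    aligns the reconstruction's soma-to-column-center bearing with the new
    soma's bearing.
    """
    p = np.asarray(p, dtype=float)
    cid, _ = nearest_column(p, frame)
    col = frame.column(cid)
    new_depth = col.depth_from_pia(p)

    type_matches = library.of_type(cell_type)
    col_matches = [r for r in type_matches if r.column_id == cid]
    candidates = [
        r for r in col_matches
        if abs(r.soma_depth - new_depth) <= frame.grid.spacing
    ]
    if not candidates:
        raise AssemblyError(
            f"no dendrite candidate for type {cell_type!r} at depth "
            f"{new_depth:.1f} um in column {cid!r} "
            f"(type matches: {len(type_matches)}, column matches: "
            f"{len(col_matches)}, depth matches: 0)"
        )
    rec = candidates[int(rng.integers(len(candidates)))]

    u = local_axis(p, frame)
    if spec.rotate_polar:
        b0 = _perp(col.center - rec.morphology.soma_position, u)
        b1 = _perp(col.center - p, u)
        if np.linalg.norm(b0) < 1e-9 or np.linalg.norm(b1) < 1e-9:
            angle = 0.0
        else:
            angle = _signed_angle(b0 / np.linalg.norm(b0),
                                  b1 / np.linalg.norm(b1), u)
    else:
        angle = float(rng.uniform(0.0, 2.0 * np.pi))
    transform = RigidTransform(
        translation=p - rec.morphology.soma_position,
        rotation=rotation_about_axis(u, angle),
    )
    return rec.morphology_id, transform


def select_axon(p, cell_type: str, library: MorphologyLibrary,
                frame: ReferenceFrame, rng: np.random.Generator) -> str:
    """Pick an axon morphology for a soma at ``p`` — never transformed.

    Only two criteria apply (cell type and nearest column); axons keep their
    registered location so that column- and depth-specific projection
    patterns are preserved.
    """
    cid, _ = nearest_column(p, frame)
    candidates = library.of_type(cell_type, column_id=cid)
    if not candidates:
        raise AssemblyError(
            f"no axon candidate for type {cell_type!r} in column {cid!r}"
        )
    return candidates[int(rng.integers(len(candidates)))].morphology_id


def upscale_long_range(cell_type: str, library: MorphologyLibrary,
                       count: int, rng: np.random.Generator,
                       column_id: str | None = None,
                       mode: str = "round_robin") -> list[str]:
    """Duplicate long-range axon reconstructions until ``count`` is reached.

    Round-robin duplication over a seed-shuffled library order keeps
    per-morphology multiplicities within one of each other (e.g., a library
    of 14 up-scaled to 311 uses each member 22 or 23 times).  An
    independent-uniform mode is available for comparison.
    """
    candidates = library.of_type(cell_type, column_id=column_id)
    if not candidates:
        raise AssemblyError(
            f"no long-range axon morphologies for type {cell_type!r}"
            + (f" in column {column_id!r}" if column_id else "")
        )
    ids = [r.morphology_id for r in candidates]
    order = [ids[i] for i in rng.permutation(len(ids))]
    if mode == "round_robin":
        return [order[i % len(order)] for i in range(count)]
    if mode == "independent":
        return [order[int(rng.integers(len(order)))] for _ in range(count)]
    raise ValueError(f"unknown up-scaling mode {mode!r}")


# ---------------------------------------------------------------------------
# full assembly
# ---------------------------------------------------------------------------

def build_network(spec: NetworkSpecification, seed: int) -> NetworkModel:
    """Run the full assembly pipeline and return the dense network model.

    Soma sampling, type assignment, morphology selection and long-range
    up-scaling each draw from independent child streams of ``seed``, so the
    result is reproducible and the total neuron count equals the sum of the
    per-voxel rounded density counts plus the long-range axon counts.
    """
    frame = spec.frame
    neurons: list[PlacedNeuron] = []

    somata: list[tuple[np.ndarray, bool]] = []
    for class_idx, (density, exc) in enumerate(
        [(spec.excitatory_density, True), (spec.inhibitory_density, False)]
    ):
        pts = sample_somata(density, frame.grid, _rng_for(seed, _STAGE_SOMATA, class_idx))
        somata.extend((pt, exc) for pt in pts)

    for nid, (p, exc) in enumerate(somata):
        cid, inside = nearest_column(p, frame)
        try:
            ct_name = assign_cell_type(
                p, frame, spec.frequencies, spec.cell_types,
                _rng_for(seed, _STAGE_ASSIGN, nid), exc,
            )
            ct = spec.cell_types[ct_name]
            dend_id, transform = (None, None)
            if not ct.axon_only:
                dend_id, transform = select_dendrite(
                    p, ct_name, spec.library, frame,
                    _rng_for(seed, _STAGE_DENDRITE, nid), ct,
                )
            axon_id = select_axon(
                p, ct_name, spec.library, frame, _rng_for(seed, _STAGE_AXON, nid)
            )
        except AssemblyError as exc_err:
            raise AssemblyError(
                f"neuron {nid} at {np.round(p, 1).tolist()}: {exc_err}"
            ) from exc_err
        neurons.append(PlacedNeuron(
            id=nid, soma_position=np.asarray(p, dtype=float), column_id=cid,
            inside_column=inside, cell_type=ct_name, excitatory=exc,
            dendrite_morphology=dend_id, dendrite_transform=transform,
            axon_morphology=axon_id,
        ))

    nid = len(neurons)
    for lt_idx, (name, ct) in enumerate(sorted(spec.cell_types.items())):
        if ct.long_range_count is None:
            continue
        columns = sorted({r.column_id for r in spec.library.of_type(name)})
        for col_idx, cid in enumerate(columns):
            rng = _rng_for(seed, _STAGE_LONG_RANGE, lt_idx * 1000 + col_idx)
            for morph_id in upscale_long_range(
                name, spec.library, ct.long_range_count, rng, column_id=cid
            ):
                m = spec.library[morph_id].morphology
                soma_pos = m.soma_position
                inside = frame.column(cid).contains(soma_pos)
                neurons.append(PlacedNeuron(
                    id=nid, soma_position=soma_pos, column_id=cid,
                    inside_column=inside, cell_type=name,
                    excitatory=ct.excitatory, axon_morphology=morph_id,
                ))
                nid += 1

    return NetworkModel(frame=frame, neurons=neurons,
                        morphologies=spec.library.morphologies,
                        cell_types=spec.cell_types)
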