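"""Labeled neuron morphologies: SWC I/O, measurement, rigid transforms.

A morphology is a rooted tree (possibly a forest) of 3D nodes with radii and
one of four compartment labels — soma, axon, basal dendrite, apical
dendrite.  Lengths are summed over parent-child segments; surface areas use
the lateral area of the truncated cone (frustum) spanned by each segment,
i.e., trapezoidal integration of the diameter along the branch.

On disk the standard SWC v1 dialect is used (7 whitespace-separated columns,
``#`` comments, structure codes 1=soma, 2=axon, 3=basal, 4=apical, parent
``-1`` for roots).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Morphology",
    "RigidTransform",
    "SWCParseError",
    "LABELS",
    "read_swc",
    "write_swc",
    "branch_length_by_label",
    "surface_area_by_label",
    "apply_transform",
    "rotation_about_axis",
]

#: SWC structure code <-> compartment label.
SWC_CODE_TO_LABEL = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
LABEL_TO_SWC_CODE = {v: k for k, v in SWC_CODE_TO_LABEL.items()}
LABELS = ("soma", "apical", "basal", "axon")


class SWCParseError(ValueError):
    """Malformed SWC content (bad code, cycle, orphan, negative radius)."""


@dataclass
class Morphology:
    """Labeled branch tree with radii.

    Attributes
    ----------
    positions : (n, 3) float array, um
    radii : (n,) float array, um
    labels : (n,) object array of {'soma','apical','basal','axon'}
    parents : (n,) int array; index of the parent node, -1 for roots
    cell_type : optional cell-type identifier
    registered_column : optional substructure (column) id the reconstruction
        is registered to
    """

    positions: np.ndarray
    radii: np.ndarray
    labels: np.ndarray
    parents: np.ndarray
    cell_type: str | None = None
    registered_column: str | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.labels = np.asarray(self.labels, dtype=object).reshape(-1)
        self.parents = np.asarray(self.parents, dtype=int).reshape(-1)
        n = len(self.positions)
        if not (len(self.radii) == len(self.labels) == len(self.parents) == n):
            raise ValueError("morphology arrays must have equal length")
        if np.any(self.radii < 0):
            raise ValueError("radii must be non-negative")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown compartment labels: {sorted(bad)}")

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def edges(self) -> np.ndarray:
        """Indices of non-root nodes; each defines the segment (parent, node)."""
        return np.flatnonzero(self.parents >= 0)

    @property
    def soma_position(self) -> np.ndarray:
        """Unweighted centroid of soma-labeled nodes (root node if none)."""
        mask = self.labels == "soma"
        if mask.any():
            return self.positions[mask].mean(axis=0)
        roots = np.flatnonzero(self.parents < 0)
        return self.positions[roots[0]].copy()

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of each segment, indexed like :attr:`edges`."""
        ch = self.edges
        return np.linalg.norm(
            self.positions[ch] - self.positions[self.parents[ch]], axis=1
        )

    def copy(self) -> "Morphology":
        return replace(
            self,
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            labels=self.labels.copy(),
            parents=self.parents.copy(),
        )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path, cell_type: str | None = None,
             registered_column: str | None = None) -> Morphology:
    """Parse and validate an SWC v1 file.

    Raises :class:`SWCParseError` naming the offending line for unknown
    structure codes, negative radii, orphan parent references, and cyclic
    parent links.
    """
    ids: list[int] = []
    rows: list[tuple] = []
    lines_of: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.split("#", 1)[0].strip()
            if not text:
                continue
            parts = text.split()
            if len(parts) != 7:
                raise SWCParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0]); code = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}:{lineno}: {exc}") from None
            if code not in SWC_CODE_TO_LABEL:
                raise SWCParseError(
                    f"{path}:{lineno}: unknown SWC structure code {code}"
                )
            if r < 0:
                raise SWCParseError(f"{path}:{lineno}: negative radius {r}")
            if nid in lines_of:
                raise SWCParseError(f"{path}:{lineno}: duplicate node id {nid}")
            lines_of[nid] = lineno
            ids.append(nid)
            rows.append((code, x, y, z, r, parent))

    if not rows:
        raise SWCParseError(f"{path}: no nodes")

    index_of = {nid: i for i, nid in enumerate(ids)}
    n = len(rows)
    positions = np.array([[r[1], r[2], r[3]] for r in rows])
    radii = np.array([r[4] for r in rows])
    labels = np.array([SWC_CODE_TO_LABEL[r[0]] for r in rows], dtype=object)
    parents = np.empty(n, dtype=int)
    for i, (nid, row) in enumerate(zip(ids, rows)):
        pid = row[5]
        if pid == -1:
            parents[i] = -1
        elif pid not in index_of:
            raise SWCParseError(
                f"{path}:{lines_of[nid]}: orphan node {nid} references "
                f"undefined parent {pid}"
            )
        elif pid == nid:
            raise SWCParseError(f"{path}:{lines_of[nid]}: node {nid} is its own parent")
        else:
            parents[i] = index_of[pid]

    # cycle detection: follow parent chains with a visitation state
    state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 in progress, 2 done
    for start in range(n):
        node = start
        chain = []
        while node >= 0 and state[node] == 0:
            state[node] = 1
            chain.append(node)
            node = parents[node]
        if node >= 0 and state[node] == 1:
            raise SWCParseError(
                f"{path}:{lines_of[ids[node]]}: cyclic parent links at node {ids[node]}"
            )
        for m in chain:
            state[m] = 2

    return Morphology(positions, radii, labels, parents,
                      cell_type=cell_type, registered_column=registered_column)


def write_swc(m: Morphology, path) -> None:
    """Write the same SWC dialect :func:`read_swc` consumes (1-based ids)."""
    with open(path, "w") as fh:
        fh.write("# SWC written by densecon\n")
        for i in range(m.n_nodes):
            code = LABEL_TO_SWC_CODE[m.labels[i]]
            x, y, z = m.positions[i]
            parent = m.parents[i] + 1 if m.parents[i] >= 0 else -1
            fh.write(f"{i + 1} {code} {x:.6f} {y:.6f} {z:.6f} "
                     f"{m.radii[i]:.6f} {parent}\n")


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def branch_length_by_label(m: Morphology, label: str) -> float:
    """Total Euclidean length (um) of segments whose child carries ``label``."""
    ch = m.edges
    mask = m.labels[ch] == label
    if not mask.any():
        return 0.0
    sel = ch[mask]
    return float(
        np.linalg.norm(m.positions[sel] - m.positions[m.parents[sel]], axis=1).sum()
    )


def surface_area_by_label(m: Morphology, label: str) -> float:
    """Lateral (frustum) surface area in um^2 of segments of ``label``.

    Per segment: ``pi * (r_parent + r_child) * length`` — the trapezoidal
    rule applied to the diameter along the branch.  A morphology whose soma
    is a single node contributes a sphere area ``4*pi*r^2`` for
    ``label='soma'``.
    """
    if label == "soma":
        soma_nodes = np.flatnonzero(m.labels == "soma")
        if len(soma_nodes) == 1:
            r = m.radii[soma_nodes[0]]
            return float(4.0 * math.pi * r**2)
    ch = m.edges
    mask = m.labels[ch] == label
    if not mask.any():
        return 0.0
    sel = ch[mask]
    par = m.parents[sel]
    seglen = np.linalg.norm(m.positions[sel] - m.positions[par], axis=1)
    return float((math.pi * (m.radii[par] + m.radii[sel]) * seglen).sum())


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the soma followed by a translation."""

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float).reshape(3))
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        object.__setattr__(self, "rotation", R)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant must be +1 (proper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by ``angle`` about ``axis``."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    c, s = math.cos(angle), math.sin(angle)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def apply_transform(m: Morphology, t: RigidTransform) -> Morphology:
    """Rotate ``m`` about its soma position, then translate.

    Positions map as ``p -> R (p - soma) + soma + translation``; radii,
    labels and topology are untouched, so lengths and areas are invariant.
    """
    soma = m.soma_position
    out = m.copy()
    out.positions = (m.positions - soma) @ t.rotation.T + soma + t.translation
    return out
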