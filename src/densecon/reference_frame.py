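"""Standardized 3D reference frame for an average circuit model.

The reference frame describes the geometry of the modeled brain region as a
set of cylindrical columns (e.g., cortical barrel columns), laminar zones
(depth intervals below the pia, per column), and a voxel grid at the
resolution set by the inter-animal variability of those landmarks (50 um for
rat vibrissal cortex).  Because the pia is curved, each column carries its
own vertical axis; a local vertical axis at an arbitrary point is obtained
by inverse-distance interpolation from the nearest column axes.

Conventions (enforced in all I/O):
    * coordinates in micrometers, right-handed;
    * column axes are unit vectors pointing from the pia toward the white
      matter, i.e., depth increases along the axis;
    * a point's axial coordinate in a column is measured along the column
      axis relative to the column center; ``top_depth``/``bottom_depth`` are
      the axial coordinates of the pia and white-matter intersections;
    * voxel and zone intervals are half-open, so in-bounds space is
      partitioned without double counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "Column",
    "LaminarZone",
    "ReferenceFrame",
    "OutOfDomainError",
    "FrameError",
    "OUTSIDE_ZONE",
    "point_to_voxel",
    "nearest_column",
    "local_axis",
    "laminar_zone_of",
    "load_columns",
    "load_zones",
]

#: Sentinel zone name returned for depths not covered by any declared zone.
OUTSIDE_ZONE = "outside"

_UNIT_TOL = 1e-9


class OutOfDomainError(ValueError):
    """A point lies outside the voxel grid (or another spatial domain)."""


class FrameError(ValueError):
    """Invalid reference-frame construction or degenerate geometry."""


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {p.shape}")
    return p


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned cubic voxel lattice with half-open voxel intervals."""

    origin: np.ndarray
    spacing: float = 50.0
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self):
        object.__setattr__(self, "origin", _as_point(self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if not self.spacing > 0:
            raise ValueError("voxel spacing must be positive")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be three integers >= 1")

    @property
    def extent(self) -> np.ndarray:
        """Physical edge lengths of the grid (um)."""
        return np.asarray(self.dims, dtype=float) * self.spacing

    @property
    def upper(self) -> np.ndarray:
        return self.origin + self.extent

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def voxel_volume_um3(self) -> float:
        return float(self.spacing**3)

    @property
    def voxel_volume_mm3(self) -> float:
        return float((self.spacing * 1e-3) ** 3)

    def contains(self, p) -> bool:
        p = _as_point(p)
        return bool(np.all(p >= self.origin) and np.all(p < self.upper))

    def point_to_voxel(self, p) -> tuple[int, int, int]:
        """Voxel index triple containing ``p`` (half-open convention)."""
        p = _as_point(p)
        if not self.contains(p):
            raise OutOfDomainError(
                f"point {p.tolist()} outside grid bounds "
                f"[{self.origin.tolist()}, {self.upper.tolist()})"
            )
        idx = np.floor((p - self.origin) / self.spacing).astype(int)
        # guard against floating-point spillover at the upper boundary
        idx = np.minimum(idx, np.asarray(self.dims) - 1)
        return tuple(int(i) for i in idx)

    def voxel_center(self, idx) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return self.origin + (idx + 0.5) * self.spacing

    def voxel_indices(self):
        """Iterate all voxel index triples in C order."""
        nx, ny, nz = self.dims
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    yield (i, j, k)


@dataclass(frozen=True)
class Column:
    """Cylindrical anatomical substructure (e.g., a barrel column)."""

    id: str
    center: np.ndarray
    radius: float
    axis: np.ndarray
    top_depth: float
    bottom_depth: float

    def __post_init__(self):
        object.__setattr__(self, "center", _as_point(self.center))
        axis = _as_point(self.axis)
        n = np.linalg.norm(axis)
        if abs(n - 1.0) > 1e-6:
            raise FrameError(f"column {self.id!r}: axis must be unit length, |axis|={n}")
        object.__setattr__(self, "axis", axis / n)
        if not self.radius > 0:
            raise FrameError(f"column {self.id!r}: radius must be positive")
        if not self.top_depth < self.bottom_depth:
            raise FrameError(f"column {self.id!r}: top_depth must be < bottom_depth")

    def axial_coordinate(self, p) -> float:
        """Signed coordinate of ``p`` along the axis, relative to the center."""
        return float(np.dot(_as_point(p) - self.center, self.axis))

    def radial_distance(self, p) -> float:
        """Perpendicular distance of ``p`` from the (infinite) axis line."""
        d = _as_point(p) - self.center
        return float(np.linalg.norm(d - np.dot(d, self.axis) * self.axis))

    def distance_to_axis_segment(self, p) -> float:
        """Distance of ``p`` to the axis segment between pia and WM depths."""
        s = np.clip(self.axial_coordinate(p), self.top_depth, self.bottom_depth)
        foot = self.center + s * self.axis
        return float(np.linalg.norm(_as_point(p) - foot))

    def depth_from_pia(self, p) -> float:
        """Depth of ``p`` below the pia surface, along the column axis (um)."""
        return self.axial_coordinate(p) - self.top_depth

    def contains(self, p) -> bool:
        s = self.axial_coordinate(p)
        return (
            self.radial_distance(p) <= self.radius
            and self.top_depth <= s <= self.bottom_depth
        )


@dataclass(frozen=True)
class LaminarZone:
    """Half-open depth interval ``[depth_min, depth_max)`` below the pia."""

    column_id: str
    name: str
    depth_min: float
    depth_max: float

    def __post_init__(self):
        if not self.depth_min < self.depth_max:
            raise FrameError(
                f"zone {self.name!r} in column {self.column_id!r}: "
                "depth_min must be < depth_max"
            )


@dataclass
class ReferenceFrame:
    """Voxel grid + columns + laminar zones + local vertical-axis field."""

    grid: VoxelGrid
    columns: list[Column]
    zones: list[LaminarZone] = field(default_factory=list)
    axis_interp_k: int = 3

    def __post_init__(self):
        if not self.columns:
            raise FrameError("a reference frame requires at least one column")
        ids = [c.id for c in self.columns]
        if len(set(ids)) != len(ids):
            raise FrameError("column ids must be unique")
        self._columns_by_id = {c.id: c for c in self.columns}
        zones_by_col: dict[str, list[LaminarZone]] = {}
        for z in self.zones:
            zones_by_col.setdefault(z.column_id, []).append(z)
        for cid, zs in zones_by_col.items():
            zs.sort(key=lambda z: z.depth_min)
            for a, b in zip(zs, zs[1:]):
                if b.depth_min < a.depth_max:
                    raise FrameError(
                        f"zones {a.name!r} and {b.name!r} overlap in column {cid!r}"
                    )
        self._zones_by_col = zones_by_col
        self._axis_field: np.ndarray | None = None

    def column(self, column_id: str) -> Column:
        return self._columns_by_id[column_id]

    @property
    def axis_field(self) -> np.ndarray:
        """Per-voxel unit vertical axis, shape ``dims + (3,)`` (lazily built)."""
        if self._axis_field is None:
            fld = np.empty(self.grid.dims + (3,), dtype=float)
            for idx in self.grid.voxel_indices():
                fld[idx] = local_axis(self.grid.voxel_center(idx), self)
            self._axis_field = fld
        return self._axis_field


# ---------------------------------------------------------------------------
# point queries
# ---------------------------------------------------------------------------

def point_to_voxel(p, grid: VoxelGrid) -> tuple[int, int, int]:
    """Half-open voxel index of ``p``; raises :class:`OutOfDomainError`."""
    return grid.point_to_voxel(p)


def nearest_column(p, frame: ReferenceFrame) -> tuple[str, bool]:
    """Closest column to ``p`` and whether ``p`` lies inside it.

    Closeness is the perpendicular distance to the column's axis segment;
    ties resolve to the lexicographically smallest column id.  An
    ``inside_flag`` of False marks septum membership.
    """
    p = _as_point(p)
    best = min(
        frame.columns, key=lambda c: (c.distance_to_axis_segment(p), c.id)
    )
    return best.id, best.contains(p)


def local_axis(p, frame: ReferenceFrame, k: int | None = None) -> np.ndarray:
    """Local vertical (depth) axis at ``p``.

    Inverse-distance-weighted mean of the ``k`` nearest column axes
    (distance to the infinite axis line), renormalized to unit length.  A
    point on a column axis returns that column's axis exactly.
    """
    p = _as_point(p)
    k = frame.axis_interp_k if k is None else k
    dists = np.array([c.radial_distance(p) for c in frame.columns])
    order = np.argsort(dists, kind="stable")[: max(1, k)]
    if dists[order[0]] < 1e-9:
        return frame.columns[order[0]].axis.copy()
    weights = 1.0 / dists[order]
    v = np.sum(
        weights[:, None] * np.array([frame.columns[i].axis for i in order]), axis=0
    )
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise FrameError(f"degenerate axis interpolation at {p.tolist()}")
    return v / n


def laminar_zone_of(p, frame: ReferenceFrame) -> str:
    """Name of the laminar zone containing ``p`` (``'outside'`` if none).

    Depth is measured from the pia along the nearest column's axis; zone
    intervals are half-open, so a point on a boundary belongs to the deeper
    zone.
    """
    p = _as_point(p)
    if not frame.grid.contains(p):
        raise OutOfDomainError(f"point {p.tolist()} outside grid bounds")
    cid, _ = nearest_column(p, frame)
    depth = frame.column(cid).depth_from_pia(p)
    for z in frame._zones_by_col.get(cid, ()):
        if z.depth_min <= depth < z.depth_max:
            return z.name
    return OUTSIDE_ZONE


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

_COLUMN_FIELDS = ["id", "cx", "cy", "cz", "ax", "ay", "az", "radius",
                  "top_depth", "bottom_depth"]


def load_columns(path) -> list[Column]:
    """Read a column table CSV (header ``id,cx,cy,cz,ax,ay,az,radius,top_depth,bottom_depth``)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(_COLUMN_FIELDS) - set(df.columns)
    if missing:
        raise FrameError(f"column table {path}: missing columns {sorted(missing)}")
    return [
        Column(
            id=row["id"],
            center=np.array([row["cx"], row["cy"], row["cz"]]),
            axis=np.array([row["ax"], row["ay"], row["az"]]),
            radius=float(row["radius"]),
            top_depth=float(row["top_depth"]),
            bottom_depth=float(row["bottom_depth"]),
        )
        for _, row in df.iterrows()
    ]


def save_columns(columns: list[Column], path) -> None:
    rows = [
        {
            "id": c.id, "cx": c.center[0], "cy": c.center[1], "cz": c.center[2],
            "ax": c.axis[0], "ay": c.axis[1], "az": c.axis[2],
            "radius": c.radius, "top_depth": c.top_depth,
            "bottom_depth": c.bottom_depth,
        }
        for c in columns
    ]
    pd.DataFrame(rows, columns=_COLUMN_FIELDS).to_csv(path, index=False)


def load_zones(path) -> list[LaminarZone]:
    """Read a zone table CSV (header ``column_id,zone,depth_min,depth_max``)."""
    df = pd.read_csv(path, dtype={"column_id": str, "zone": str})
    return [
        LaminarZone(
            column_id=row["column_id"], name=row["zone"],
            depth_min=float(row["depth_min"]), depth_max=float(row["depth_max"]),
        )
        for _, row in df.iterrows()
    ]


def save_zones(zones: list[LaminarZone], path) -> None:
    rows = [
        {"column_id": z.column_id, "zone": z.name,
         "depth_min": z.depth_min, "depth_max": z.depth_max}
        for z in zones
    ]
    pd.DataFrame(rows, columns=["column_id", "zone", "depth_min", "depth_max"]).to_csv(
        path, index=False
    )
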