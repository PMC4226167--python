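"""On-disk formats for input tables and assembled models.

Input tables are plain CSV (column geometry, laminar zones, cell types,
relative frequencies, morphology manifest, meta-connectivity); morphologies
are SWC files referenced by the manifest.  Assembled networks and
innervation matrices persist as HDF5; the tabular parts are embedded as CSV
text so a saved file is self-contained.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .assembly import (
    CellTypeSpec,
    MorphologyLibrary,
    MorphologyRecord,
    NetworkModel,
    PlacedNeuron,
)
from .innervation import InnervationMatrix
from .morphology import Morphology, RigidTransform, read_swc, write_swc
from .reference_frame import (
    LaminarZone,
    ReferenceFrame,
    VoxelGrid,
    load_columns,
    load_zones,
    save_columns,
    save_zones,
)

__all__ = [
    "ZONE_NAMES",
    "load_cell_types", "save_cell_types",
    "load_frequencies", "save_frequencies",
    "load_library", "save_library",
    "save_network", "load_network",
    "save_innervation_matrix", "load_innervation_matrix",
]

#: Laminar zone names used by the cell-type table's bouton-density columns.
ZONE_NAMES = ("supragranular", "granular", "infragranular")
_ZONE_COLS = ("bouton_supra", "bouton_gran", "bouton_infra")


# ---------------------------------------------------------------------------
# cell types / frequencies
# ---------------------------------------------------------------------------

def load_cell_types(path) -> dict[str, CellTypeSpec]:
    """Read the cell-type table CSV:
    ``name,excitatory,rotate_polar,axon_only,occupancy,bouton_supra,bouton_gran,bouton_infra,long_range_count``.
    """
    df = pd.read_csv(path, dtype={"name": str, "occupancy": str})
    out = {}
    for _, row in df.iterrows():
        lrc = row.get("long_range_count")
        lrc = None if pd.isna(lrc) else int(lrc)
        out[row["name"]] = CellTypeSpec(
            name=row["name"],
            excitatory=bool(row["excitatory"]),
            rotate_polar=bool(row["rotate_polar"]),
            axon_only=bool(row["axon_only"]),
            occupancy=row["occupancy"],
            bouton_density_per_zone={
                zone: float(row[col]) for zone, col in zip(ZONE_NAMES, _ZONE_COLS)
            },
            long_range_count=lrc,
        )
    return out


def save_cell_types(cell_types: dict[str, CellTypeSpec], path) -> None:
    rows = []
    for name in sorted(cell_types):
        ct = cell_types[name]
        row = {
            "name": ct.name, "excitatory": int(ct.excitatory),
            "rotate_polar": int(ct.rotate_polar),
            "axon_only": int(ct.axon_only), "occupancy": ct.occupancy,
            "long_range_count": "" if ct.long_range_count is None
            else ct.long_range_count,
        }
        for zone, col in zip(ZONE_NAMES, _ZONE_COLS):
            row[col] = ct.bouton_density_per_zone.get(zone, 0.0)
        rows.append(row)
    cols = ["name", "excitatory", "rotate_polar", "axon_only", "occupancy",
            *_ZONE_COLS, "long_range_count"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_frequencies(path) -> pd.DataFrame:
    """Read the relative-frequency table CSV:
    ``region,inside_column,cell_type,frequency``."""
    df = pd.read_csv(path, dtype={"region": str, "cell_type": str})
    df["inside_column"] = df["inside_column"].astype(bool)
    df["frequency"] = df["frequency"].astype(float)
    return df


def save_frequencies(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["inside_column"] = out["inside_column"].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# morphology library
# ---------------------------------------------------------------------------

def load_library(manifest_path, base_dir=None) -> MorphologyLibrary:
    """Read a library manifest CSV
    (``morphology_id,path,cell_type,column_id,soma_depth``) and its SWC files.
    """
    manifest_path = Path(manifest_path)
    base = Path(base_dir) if base_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"morphology_id": str, "path": str,
                                           "cell_type": str, "column_id": str})
    records = []
    for _, row in df.iterrows():
        m = read_swc(base / row["path"], cell_type=row["cell_type"],
                     registered_column=row["column_id"])
        records.append(MorphologyRecord(
            morphology_id=row["morphology_id"], morphology=m,
            cell_type=row["cell_type"], column_id=row["column_id"],
            soma_depth=float(row["soma_depth"]),
        ))
    return MorphologyLibrary(records)


def save_library(library: MorphologyLibrary, out_dir) -> Path:
    """Write SWC files plus ``manifest.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    swc_dir = out_dir / "swc"
    swc_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in library.records:
        rel = f"swc/{rec.morphology_id}.swc"
        write_swc(rec.morphology, out_dir / rel)
        rows.append({
            "morphology_id": rec.morphology_id, "path": rel,
            "cell_type": rec.cell_type, "column_id": rec.column_id,
            "soma_depth": rec.soma_depth,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["morphology_id", "path", "cell_type",
                                "column_id", "soma_depth"]).to_csv(
        manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# HDF5 persistence
# ---------------------------------------------------------------------------

def _df_to_string(df: pd.DataFrame) -> str:
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def _df_from_string(text: str) -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(text))


def _swc_text(m: Morphology) -> str:
    from .morphology import LABEL_TO_SWC_CODE
    lines = []
    for i in range(m.n_nodes):
        code = LABEL_TO_SWC_CODE[m.labels[i]]
        x, y, z = m.positions[i]
        parent = m.parents[i] + 1 if m.parents[i] >= 0 else -1
        lines.append(f"{i + 1} {code} {x:.17g} {y:.17g} {z:.17g} "
                     f"{m.radii[i]:.17g} {parent}")
    return "\n".join(lines)


def _swc_from_text(text: str) -> Morphology:
    from .morphology import SWC_CODE_TO_LABEL
    positions, radii, labels, parents = [], [], [], []
    for line in text.splitlines():
        parts = line.split()
        positions.append([float(v) for v in parts[2:5]])
        radii.append(float(parts[5]))
        labels.append(SWC_CODE_TO_LABEL[int(parts[1])])
        parents.append(int(parts[6]) - 1 if int(parts[6]) != -1 else -1)
    return Morphology(np.array(positions), np.array(radii),
                      np.array(labels, dtype=object), np.array(parents))


def save_network(network: NetworkModel, path) -> None:
    """Persist a network model (neurons, transforms, frame, morphologies)."""
    frame = network.frame
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.attrs["origin"] = frame.grid.origin
        g.attrs["spacing"] = frame.grid.spacing
        g.attrs["dims"] = frame.grid.dims
        f.attrs["axis_interp_k"] = frame.axis_interp_k

        cols = pd.DataFrame([
            {"id": c.id, "cx": c.center[0], "cy": c.center[1],
             "cz": c.center[2], "ax": c.axis[0], "ay": c.axis[1],
             "az": c.axis[2], "radius": c.radius,
             "top_depth": c.top_depth, "bottom_depth": c.bottom_depth}
            for c in frame.columns
        ])
        zones = pd.DataFrame([
            {"column_id": z.column_id, "zone": z.name,
             "depth_min": z.depth_min, "depth_max": z.depth_max}
            for z in frame.zones
        ])
        f.create_dataset("columns_csv", data=_df_to_string(cols))
        f.create_dataset("zones_csv", data=_df_to_string(zones))

        ct_json = {
            name: {
                "excitatory": ct.excitatory, "rotate_polar": ct.rotate_polar,
                "axon_only": ct.axon_only, "occupancy": ct.occupancy,
                "bouton_density_per_zone": ct.bouton_density_per_zone,
                "long_range_count": ct.long_range_count,
            }
            for name, ct in network.cell_types.items()
        }
        f.create_dataset("cell_types_json", data=json.dumps(ct_json))

        neurons = pd.DataFrame([
            {"id": n.id, "x": n.soma_position[0], "y": n.soma_position[1],
             "z": n.soma_position[2], "column_id": n.column_id,
             "inside_column": int(n.inside_column), "cell_type": n.cell_type,
             "excitatory": int(n.excitatory),
             "dendrite_morphology": n.dendrite_morphology or "",
             "axon_morphology": n.axon_morphology or ""}
            for n in network.neurons
        ])
        f.create_dataset("neurons_csv", data=_df_to_string(neurons))

        nt = len(network.neurons)
        rot = np.tile(np.eye(3), (nt, 1, 1))
        trans = np.zeros((nt, 3))
        has_t = np.zeros(nt, dtype=bool)
        for k, n in enumerate(network.neurons):
            if n.dendrite_transform is not None:
                rot[k] = n.dendrite_transform.rotation
                trans[k] = n.dendrite_transform.translation
                has_t[k] = True
        f.create_dataset("transform_rotations", data=rot)
        f.create_dataset("transform_translations", data=trans)
        f.create_dataset("transform_present", data=has_t)

        mg = f.create_group("morphologies")
        for mid, m in network.morphologies.items():
            mg.create_dataset(mid, data=_swc_text(m))


def load_network(path) -> NetworkModel:
    with h5py.File(path, "r") as f:
        grid = VoxelGrid(
            origin=np.asarray(f["grid"].attrs["origin"]),
            spacing=float(f["grid"].attrs["spacing"]),
            dims=tuple(int(d) for d in f["grid"].attrs["dims"]),
        )
        cols_df = _df_from_string(f["columns_csv"][()].decode())
        zones_df = _df_from_string(f["zones_csv"][()].decode())
        from .reference_frame import Column
        columns = [
            Column(id=str(r["id"]),
                   center=np.array([r["cx"], r["cy"], r["cz"]]),
                   axis=np.array([r["ax"], r["ay"], r["az"]]),
                   radius=float(r["radius"]), top_depth=float(r["top_depth"]),
                   bottom_depth=float(r["bottom_depth"]))
            for _, r in cols_df.iterrows()
        ]
        zones = [
            LaminarZone(column_id=str(r["column_id"]), name=str(r["zone"]),
                        depth_min=float(r["depth_min"]),
                        depth_max=float(r["depth_max"]))
            for _, r in zones_df.iterrows()
        ]
        frame = ReferenceFrame(grid, columns, zones,
                               axis_interp_k=int(f.attrs["axis_interp_k"]))

        ct_json = json.loads(f["cell_types_json"][()].decode())
        cell_types = {
            name: CellTypeSpec(
                name=name, excitatory=d["excitatory"],
                rotate_polar=d["rotate_polar"], axon_only=d["axon_only"],
                occupancy=d["occupancy"],
                bouton_density_per_zone=d["bouton_density_per_zone"],
                long_range_count=d["long_range_count"],
            )
            for name, d in ct_json.items()
        }

        morphologies = {
            mid: _swc_from_text(f["morphologies"][mid][()].decode())
            for mid in f["morphologies"]
        }

        neurons_df = _df_from_string(f["neurons_csv"][()].decode())
        rot = f["transform_rotations"][()]
        trans = f["transform_translations"][()]
        has_t = f["transform_present"][()]
        neurons = []
        for k, (_, r) in enumerate(neurons_df.iterrows()):
            transform = RigidTransform(trans[k], rot[k]) if has_t[k] else None
            dm = r["dendrite_morphology"]
            am = r["axon_morphology"]
            neurons.append(PlacedNeuron(
                id=int(r["id"]),
                soma_position=np.array([r["x"], r["y"], r["z"]]),
                column_id=str(r["column_id"]),
                inside_column=bool(r["inside_column"]),
                cell_type=str(r["cell_type"]),
                excitatory=bool(r["excitatory"]),
                dendrite_morphology=None if pd.isna(dm) or dm == "" else str(dm),
                dendrite_transform=transform,
                axon_morphology=None if pd.isna(am) or am == "" else str(am),
            ))
    return NetworkModel(frame=frame, neurons=neurons,
                        morphologies=morphologies, cell_types=cell_types)


def save_innervation_matrix(matrix: InnervationMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        csr = matrix.matrix.tocsr()
        f.create_dataset("data", data=csr.data)
        f.create_dataset("indices", data=csr.indices)
        f.create_dataset("indptr", data=csr.indptr)
        f.attrs["shape"] = csr.shape
        f.create_dataset("pre_ids", data=np.asarray(matrix.pre_ids, dtype=np.int64))
        f.create_dataset("post_ids", data=np.asarray(matrix.post_ids, dtype=np.int64))
        if matrix.pre_info is not None:
            f.create_dataset("pre_info_csv", data=_df_to_string(matrix.pre_info))
        if matrix.post_info is not None:
            f.create_dataset("post_info_csv", data=_df_to_string(matrix.post_info))


def load_innervation_matrix(path) -> InnervationMatrix:
    import scipy.sparse as sp
    with h5py.File(path, "r") as f:
        csr = sp.csr_matrix(
            (f["data"][()], f["indices"][()], f["indptr"][()]),
            shape=tuple(f.attrs["shape"]),
        )
        pre_ids = [int(i) for i in f["pre_ids"][()]]
        post_ids = [int(i) for i in f["post_ids"][()]]
        pre_info = _df_from_string(f["pre_info_csv"][()].decode()) \
            if "pre_info_csv" in f else None
        post_info = _df_from_string(f["post_info_csv"][()].decode()) \
            if "post_info_csv" in f else None
    return InnervationMatrix(csr, pre_ids, post_ids, pre_info, post_info)
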