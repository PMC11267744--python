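"""Readers and writers for the pipeline's on-disk artefacts.

Formats: ASCII PLY for surface meshes, CSV for per-vertex scalars, labels,
parcellations and matrices (with the stable sub-area header ordering
V1d1..V3v6), NIfTI for volumes, TCK (MRtrix track format) for tractograms
and JSON for configuration, truth and statistics.  Every writer/reader pair
is lossless (bit-level for integers, ~1e-9 for floats where text formats
round).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import SurfaceMesh
from .retinotopy import (
    AREA_NAMES,
    AreaLabels,
    N_SUBAREAS,
    SUBAREA_NAMES,
    SubAreaParcellation,
)
from .tracking import Tractogram

__all__ = [
    "write_mesh_ply",
    "read_mesh_ply",
    "write_vertex_scalars",
    "read_vertex_scalars",
    "write_area_labels",
    "read_area_labels",
    "write_parcellation",
    "read_parcellation",
    "write_volume",
    "read_volume",
    "write_tractogram",
    "read_tractogram",
    "write_matrix",
    "read_matrix",
    "write_json",
    "read_json",
]


def write_mesh_ply(mesh: SurfaceMesh, path) -> None:
    """ASCII PLY export preserving vertex and triangle order."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\n")
        f.write(f"element vertex {mesh.n_vertices}\n")
        f.write("property double x\nproperty double y\nproperty double z\n")
        f.write(f"element face {mesh.n_triangles}\n")
        f.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            f.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh_ply(path) -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), file_type="ply", process=False, maintain_order=True)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))


def write_vertex_scalars(values: np.ndarray, path, name: str = "value") -> None:
    values = np.asarray(values)
    pd.DataFrame(
        {"vertex_index": np.arange(len(values)), name: values}
    ).to_csv(path, index=False)


def read_vertex_scalars(path) -> np.ndarray:
    df = pd.read_csv(path)
    order = np.argsort(df["vertex_index"].to_numpy())
    return df.iloc[order, 1].to_numpy()


def write_area_labels(labels: AreaLabels, path) -> None:
    rows = []
    for name, idx in zip(AREA_NAMES, labels.areas):
        for v in idx:
            rows.append((int(v), name))
    pd.DataFrame(rows, columns=["vertex_index", "area"]).to_csv(path, index=False)


def read_area_labels(path) -> AreaLabels:
    df = pd.read_csv(path)
    sets = {
        name: df.loc[df["area"] == name, "vertex_index"].to_numpy()
        for name in AREA_NAMES
    }
    return AreaLabels(v1=sets["V1"], v2=sets["V2"], v3=sets["V3"])


def write_parcellation(parcellation: SubAreaParcellation, csv_path, json_path) -> None:
    rows = []
    for i, verts in enumerate(parcellation.sub_areas):
        for v in verts:
            rows.append((int(v), i))
    rows.sort()
    pd.DataFrame(rows, columns=["vertex_index", "subarea_index"]).to_csv(
        csv_path, index=False
    )
    meta = {
        "subarea_names": list(SUBAREA_NAMES),
        "area_of": [int(a) for a in parcellation.area_of],
        "hemifield_of": parcellation.hemifield_of,
        "eccentricity_bin_of": [int(b) for b in parcellation.eccentricity_bin_of],
        "eccentricity_cuts_deg": parcellation.eccentricity_cuts,
    }
    write_json(meta, json_path)


def read_parcellation(csv_path, json_path=None) -> SubAreaParcellation:
    df = pd.read_csv(csv_path)
    subs = [
        df.loc[df["subarea_index"] == i, "vertex_index"].to_numpy()
        for i in range(N_SUBAREAS)
    ]
    cuts = {}
    if json_path is not None:
        cuts = read_json(json_path).get("eccentricity_cuts_deg", {})
    return SubAreaParcellation(sub_areas=subs, eccentricity_cuts=cuts)


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, np.asarray(affine, dtype=float)), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_tractogram(tractogram: Tractogram, path) -> None:
    """Save as TCK; streamline coordinates are already in mm (identity affine)."""
    t = nib.streamlines.Tractogram(
        streamlines=tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(t, str(path))


def read_tractogram(path, provenance: str = "odf") -> Tractogram:
    tck = nib.streamlines.load(str(path))
    return Tractogram(
        streamlines=[np.asarray(s, dtype=float) for s in tck.streamlines],
        provenance=provenance,
    )


def write_matrix(matrix: np.ndarray, path) -> None:
    """CSV with the stable sub-area header row/column (V1d1..V3v6)."""
    m = np.asarray(matrix)
    names = SUBAREA_NAMES if m.shape[0] == N_SUBAREAS else [str(i) for i in range(m.shape[0])]
    pd.DataFrame(m, index=list(names), columns=list(names)).to_csv(path)


def read_matrix(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy()


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, cls=_NumpyEncoder)
        f.write("\n")


def read_json(path):
    with open(path) as f:
        return json.load(f)
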