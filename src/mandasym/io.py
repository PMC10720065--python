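"""File formats: landmark JSON, plane/transform JSON, ITK .tfm, PLY/STL,
VTK XML PolyData (.vtp) with per-vertex scalars, and distance-field CSV."""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET

import numpy as np
import trimesh

from .asymmetry import DistanceField
from .geometry import LandmarkSet, Plane, RigidTransform

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_plane",
    "write_plane",
    "read_transform",
    "write_transform",
    "write_itk_tfm",
    "load_mesh",
    "save_mesh",
    "write_vtp",
    "read_vtp_point_data",
    "write_ply_with_scalar",
    "write_field_csv",
]


# -- landmarks: {name: [x, y, z]} in mm, scanner RAS -------------------------

def read_landmarks(path) -> LandmarkSet:
    with open(path) as fh:
        return LandmarkSet(json.load(fh))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(landmarks.to_dict(), fh, indent=1)


# -- planes and transforms ---------------------------------------------------

def read_plane(path) -> Plane:
    with open(path) as fh:
        return Plane.from_dict(json.load(fh))


def write_plane(plane: Plane, path) -> None:
    with open(path, "w") as fh:
        json.dump(plane.to_dict(), fh)


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        return RigidTransform.from_matrix(np.asarray(json.load(fh)["matrix"]))


def write_transform(transform: RigidTransform, path) -> None:
    with open(path, "w") as fh:
        json.dump({"matrix": transform.matrix.tolist(), "rmsd_mm": transform.rmsd}, fh)


def write_itk_tfm(transform: RigidTransform, path) -> None:
    """ITK text transform (row-major 3x3 + translation) for interoperability."""
    params = " ".join(f"{v:.17g}" for v in transform.rotation.ravel())
    trans = " ".join(f"{v:.17g}" for v in transform.translation)
    with open(path, "w") as fh:
        fh.write(
            "#Insight Transform File V1.0\n#Transform 0\n"
            "Transform: AffineTransform_double_3_3\n"
            f"Parameters: {params} {trans}\nFixedParameters: 0 0 0\n"
        )


# -- meshes ------------------------------------------------------------------

def load_mesh(path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    return mesh


def save_mesh(mesh: trimesh.Trimesh, path) -> None:
    # string vertex attributes (region/side labels) are not representable in
    # PLY/STL; they are dropped from the file, not from the mesh
    out = mesh.copy()
    out.vertex_attributes.clear()
    out.export(str(path))


# -- VTK XML PolyData --------------------------------------------------------

def _ascii(arr: np.ndarray) -> str:
    return " ".join(f"{v:.9g}" for v in np.asarray(arr).ravel())


def write_vtp(path, mesh: trimesh.Trimesh, point_scalars: dict, colors=None) -> None:
    """Minimal ASCII VTK XML PolyData writer (vertices, triangles, point data)."""
    n, m = len(mesh.vertices), len(mesh.faces)
    root = ET.Element("VTKFile", type="PolyData", version="0.1", byte_order="LittleEndian")
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        poly, "Piece", NumberOfPoints=str(n), NumberOfPolys=str(m),
        NumberOfVerts="0", NumberOfLines="0", NumberOfStrips="0",
    )
    pdata = ET.SubElement(piece, "PointData")
    for name, values in point_scalars.items():
        da = ET.SubElement(
            pdata, "DataArray", type="Float64", Name=name, format="ascii",
            NumberOfComponents="1",
        )
        da.text = _ascii(np.asarray(values, dtype=float))
    if colors is not None:
        da = ET.SubElement(
            pdata, "DataArray", type="UInt8", Name="RGB", format="ascii",
            NumberOfComponents="3",
        )
        da.text = " ".join(str(int(v)) for v in np.asarray(colors).ravel())
    points = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        points, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = _ascii(mesh.vertices)
    polys = ET.SubElement(piece, "Polys")
    conn = ET.SubElement(
        polys, "DataArray", type="Int64", Name="connectivity", format="ascii"
    )
    conn.text = " ".join(str(int(v)) for v in mesh.faces.ravel())
    offs = ET.SubElement(polys, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = " ".join(str(3 * (i + 1)) for i in range(m))
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")


def read_vtp_point_data(path) -> dict:
    """Read point-data arrays back from a .vtp written by :func:`write_vtp`."""
    root = ET.parse(str(path)).getroot()
    out = {}
    for da in root.iter("DataArray"):
        name = da.get("Name")
        if name is None or name in ("connectivity", "offsets"):
            continue
        ncomp = int(da.get("NumberOfComponents", "1"))
        dtype = np.uint8 if da.get("type") == "UInt8" else float
        values = np.array(da.text.split(), dtype=float).astype(dtype)
        out[name] = values.reshape(-1, ncomp) if ncomp > 1 else values
    return out


def write_ply_with_scalar(path, mesh: trimesh.Trimesh, scalar, colors) -> None:
    """Binary PLY with vertex colors and a float ``signed_distance_mm`` property."""
    out = mesh.copy()
    out.vertex_attributes.clear()
    out.visual.vertex_colors = np.column_stack(
        [colors, np.full(len(colors), 255, dtype=np.uint8)]
    )
    out.vertex_attributes["signed_distance_mm"] = np.asarray(scalar, dtype=np.float32)
    data = trimesh.exchange.ply.export_ply(out, encoding="binary", include_attributes=True)
    with open(path, "wb") as fh:
        fh.write(data)


def write_field_csv(field: DistanceField, path) -> None:
    field.to_dataframe().to_csv(path, index=False, float_format="%.6f")
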