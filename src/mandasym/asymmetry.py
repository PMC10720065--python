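"""Signed and absolute surface-distance fields between hemimandibles.

The measurement pipeline: mirror the mandible across the midsagittal plane,
register the mirror back onto the original on cranial-base landmarks (so
positional asymmetries vanish and what remains is morphology), split both at
the midsagittal plane, and connect every point of the reference (by default
right) hemimandible to the closest point of the mirrored contralateral
surface.  The connecting vector's component convention gives the signed
distance: positive when the left hemimandible tends to contain the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    LandmarkSet,
    build_reference_frame,
    clip_mesh,
    midsagittal_plane,
    reflect,
)
from .registration import CRANIAL_BASE_NAMES, landmark_rigid_register
from .surface import SurfaceLocator
from .volume import VoxelMask, mask_to_mesh

__all__ = [
    "Correspondence",
    "DistanceField",
    "correspond_points",
    "signed_distance_field",
    "label_regions",
    "colormap_export",
    "measure_subject",
    "distance_colors",
]

RELEVANCE_RANGE_MM = 2.0  # clinically relevant color range is +/- 2 mm


@dataclass(frozen=True)
class Correspondence:
    """Closest-point map from every reference surface point to the target."""

    reference_points: np.ndarray
    target_points: np.ndarray

    @property
    def vectors(self) -> np.ndarray:
        return self.target_points - self.reference_points

    @property
    def count(self) -> int:
        return len(self.reference_points)


@dataclass
class DistanceField:
    """Per-point asymmetry record: position, 3-component displacement vector,
    signed distance, absolute distance and anatomical region."""

    points: np.ndarray
    vectors: np.ndarray
    signed: np.ndarray
    absolute: np.ndarray
    region: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        n = len(self.points)
        for name in ("vectors", "signed", "absolute", "region"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match points")
        if not np.allclose(self.absolute, np.abs(self.signed), atol=1e-9):
            raise ValueError("absolute distance must equal |signed distance|")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "dx": self.vectors[:, 0],
                "dy": self.vectors[:, 1],
                "dz": self.vectors[:, 2],
                "signed": self.signed,
                "absolute": self.absolute,
                "region": self.region,
            }
        )

    def region_mean_signed(self) -> dict:
        return {
            r: float(self.signed[self.region == r].mean())
            for r in np.unique(self.region)
        }


def correspond_points(reference: trimesh.Trimesh, target: trimesh.Trimesh) -> Correspondence:
    """Map every reference vertex to the exactly closest point on ``target``.

    Both surfaces must already be in the common registered frame.  Replaces
    spherical-harmonic correspondence with closest-point correspondence on
    nearly congruent, pre-registered surfaces.
    """
    if len(reference.vertices) == 0 or len(target.faces) == 0:
        raise ValueError("empty mesh in correspondence")
    ref_pts = reference.vertices.view(np.ndarray)
    closest, _, _ = SurfaceLocator(target).query(ref_pts)
    return Correspondence(ref_pts.copy(), closest)


def signed_distance_field(
    correspondence: Correspondence,
    reference_normals: np.ndarray,
    region_labels: np.ndarray,
    meta: dict | None = None,
) -> DistanceField:
    """Signed = +/-|vector| with the sign of (vector . outward normal).

    A positive value means the corresponding contralateral (mirrored-left)
    surface lies outside the reference right surface — the left
    hemimandible "contains" the right.
    """
    normals = np.asarray(reference_normals, dtype=float)
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length reference normal")
    normals = normals / norms[:, None]
    v = correspondence.vectors
    absolute = np.linalg.norm(v, axis=1)
    sign = np.where(np.einsum("ij,ij->i", v, normals) >= 0.0, 1.0, -1.0)
    signed = np.where(absolute == 0.0, 0.0, sign * absolute)
    return DistanceField(
        points=correspondence.reference_points,
        vectors=v,
        signed=signed,
        absolute=np.abs(signed),
        region=np.asarray(region_labels),
        meta=dict(meta or {}),
    )


def label_regions(points, landmarks: LandmarkSet, side: str | None = None) -> np.ndarray:
    """Assign condyle / ramus / corpus to each point (Habets-style partition).

    Condyle: superior to the axial plane through the sigmoid notch.  Corpus:
    anterior-inferior to the oblique plane bisecting the gonial angle at
    Gonion.  Ramus: the remainder.  Axial/anterior directions come from the
    natural-head-position frame rebuilt from the landmarks; ``side`` selects
    which side's landmarks anchor the planes (inferred from the midsagittal
    plane when None).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    frame = build_reference_frame(landmarks)
    x_axis, y_axis, z_axis = frame.rotation  # world directions of frame axes
    oblique = (y_axis - z_axis) / np.sqrt(2.0)

    if side is None:
        plane = midsagittal_plane(landmarks)
        side_of = np.where(plane.signed_distance(pts) > 0, "left", "right")
    else:
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        side_of = np.full(len(pts), side, dtype="U5")

    labels = np.full(len(pts), "ramus", dtype="U7")
    for s, suffix in (("left", "_L"), ("right", "_R")):
        sel = side_of == s
        if not sel.any():
            continue
        landmarks.require("SigmoidNotch" + suffix, "Gonion" + suffix)
        notch = landmarks["SigmoidNotch" + suffix]
        gonion = landmarks["Gonion" + suffix]
        p = pts[sel]
        lab = np.full(sel.sum(), "ramus", dtype="U7")
        lab[(p - gonion) @ oblique > 0] = "corpus"
        lab[(p - notch) @ z_axis > 0] = "condyle"
        labels[sel] = lab
    return labels


# ---------------------------------------------------------------------------
# Color maps
# ---------------------------------------------------------------------------

_NEUTRAL = {"grey": (128, 128, 128), "green": (0, 128, 0)}


def distance_colors(signed_mm, neutral: str = "grey") -> np.ndarray:
    """8-bit RGB from the diverging clinical scale clamped to +/- 2 mm.

    Anchors: dark blue at -2, blue at -1, neutral at 0, yellow at +1,
    red at +2.  The neutral color is configurable (grey by default, green
    optional) because published scales use either.  Piecewise-linear
    interpolation per channel, exact at the anchors.
    """
    if neutral not in _NEUTRAL:
        raise ValueError("neutral must be 'grey' or 'green'")
    anchors_mm = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    anchor_rgb = np.array(
        [(0, 0, 139), (0, 0, 255), _NEUTRAL[neutral], (255, 255, 0), (255, 0, 0)],
        dtype=float,
    )
    values = np.clip(np.asarray(signed_mm, dtype=float), -RELEVANCE_RANGE_MM, RELEVANCE_RANGE_MM)
    rgb = np.stack(
        [np.interp(values, anchors_mm, anchor_rgb[:, ch]) for ch in range(3)], axis=1
    )
    return (rgb + 0.5).astype(np.uint8)


def colormap_export(
    mesh: trimesh.Trimesh, field: DistanceField, path, neutral: str = "grey"
) -> None:
    """Write a surface file with per-vertex signed distance and RGB colors.

    ``.vtp`` writes VTK XML PolyData (scalar array ``signed_distance_mm``
    plus RGB); ``.ply`` writes a binary PLY with vertex colors and the
    scalar as a custom vertex property.
    """
    from . import io as _io

    n = len(mesh.vertices)
    if field.n_points != n:
        raise ValueError(
            f"field has {field.n_points} points but mesh has {n} vertices"
        )
    colors = distance_colors(field.signed, neutral=neutral)
    path = str(path)
    if path.endswith(".vtp"):
        _io.write_vtp(path, mesh, {"signed_distance_mm": field.signed}, colors)
    elif path.endswith(".ply"):
        _io.write_ply_with_scalar(path, mesh, field.signed, colors)
    else:
        raise ValueError("colormap export supports .vtp and .ply")


# ---------------------------------------------------------------------------
# Per-subject orchestration
# ---------------------------------------------------------------------------


def measure_subject(
    geometry,
    landmarks: LandmarkSet,
    reference_side: str = "right",
    registration_names=CRANIAL_BASE_NAMES,
) -> DistanceField:
    """Full mirror-and-register asymmetry measurement for one subject.

    ``geometry`` is a mandible surface (trimesh) or binary mask (VoxelMask,
    converted by marching cubes).  Stages: midsagittal plane from ANS /
    Nasion / fronto-zygomatic midpoint -> mirror -> rigid cranial-base
    registration of the mirror onto the original -> clip both to the
    reference side -> closest-point correspondence -> signed/absolute field
    with condyle/ramus/corpus labels.
    """
    if reference_side not in ("left", "right"):
        raise ValueError("reference_side must be 'left' or 'right'")
    if isinstance(geometry, VoxelMask):
        mesh = mask_to_mesh(geometry)
    elif isinstance(geometry, trimesh.Trimesh):
        mesh = geometry
    else:
        raise TypeError("geometry must be a trimesh.Trimesh or VoxelMask")

    try:
        plane = midsagittal_plane(landmarks)
    except Exception as exc:
        raise RuntimeError(f"midsagittal-plane stage failed: {exc}") from exc

    mirrored = reflect(mesh, plane)
    mirrored_lm = reflect(landmarks, plane).with_sides_swapped()

    try:
        transform = landmark_rigid_register(mirrored_lm, landmarks, registration_names)
    except Exception as exc:
        raise RuntimeError(f"cranial-base registration stage failed: {exc}") from exc
    mirrored.vertices = transform.apply(mirrored.vertices)

    # the midsagittal normal points left, so the right side is 'negative'
    keep = "negative" if reference_side == "right" else "positive"
    reference_h = clip_mesh(mesh, plane, keep=keep)
    target_h = clip_mesh(mirrored, plane, keep=keep)
    if len(reference_h.faces) == 0 or len(target_h.faces) == 0:
        raise RuntimeError("hemimandible clipping produced an empty surface")

    correspondence = correspond_points(reference_h, target_h)
    labels = label_regions(reference_h.vertices, landmarks, side=reference_side)
    normals = reference_h.vertex_normals.view(np.ndarray)
    # the sign convention is tied to the reference side: with the right
    # hemimandible as reference, positive means "left contains right";
    # taking the left as reference flips the reported sign.
    field = signed_distance_field(
        correspondence,
        normals,
        labels,
        meta={
            "n_points": correspondence.count,
            "registration_rmsd_mm": transform.rmsd,
            "reference_side": reference_side,
            "midsagittal_plane": plane.to_dict(),
            "transform": transform.matrix.tolist(),
        },
    )
    return field
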