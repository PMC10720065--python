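"""Coordinate frames, planes, reflections, clipping and cephalometric measures.

All coordinates are millimetres in a right-handed RAS frame:
``+x`` = patient right, ``+y`` = anterior, ``+z`` = superior.  The
midsagittal-plane normal is oriented toward the patient's *left* so that a
positive signed distance along the normal matches the clinical convention
"left hemimandible contains the right".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import trimesh

__all__ = [
    "Plane",
    "RigidTransform",
    "LandmarkSet",
    "reflect",
    "reflection_transform",
    "build_reference_frame",
    "midsagittal_plane",
    "clip_mesh",
    "menton_deviation",
    "cephalometric_classify",
    "classify_angles",
    "CephalometricResult",
    "MissingLandmarkError",
    "DegenerateGeometryError",
]

#: Landmarks every synthetic subject carries.  ``Incisal_midpoint`` is the
#: third occlusal support point used by the natural-head-position frame.
REQUIRED_LANDMARKS = (
    "Nasion",
    "Basion",
    "ANS",
    "FZ_R",
    "FZ_L",
    "Menton",
    "Gonion_R",
    "Gonion_L",
    "SigmoidNotch_R",
    "SigmoidNotch_L",
    "A_point",
    "B_point",
    "Porion_R",
    "Porion_L",
    "Orbitale_R",
    "Orbitale_L",
    "MB_cusp_first_molar_R",
    "MB_cusp_first_molar_L",
    "Incisal_midpoint",
)


class MissingLandmarkError(KeyError):
    """A named landmark required by an operation is absent."""


class DegenerateGeometryError(ValueError):
    """Defining points are collinear/coincident and do not fix the construct."""


# ---------------------------------------------------------------------------
# Planes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Plane:
    """Oriented plane {p : n.p = d} with unit normal ``n`` and offset ``d`` (mm)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise DegenerateGeometryError("plane normal has zero length")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "offset", float(self.offset) / norm)

    @classmethod
    def from_points(cls, a, b, c) -> "Plane":
        a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
        n = np.cross(b - a, c - a)
        if np.linalg.norm(n) < 1e-9 * max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0):
            raise DegenerateGeometryError("plane-defining points are collinear")
        return cls(n, float(np.dot(n, a)))

    def signed_distance(self, points) -> np.ndarray:
        """n.p - d for each point; positive on the side the normal points to."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.normal - self.offset

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset)

    def to_dict(self) -> dict:
        return {"n": [float(v) for v in self.normal], "d": float(self.offset)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Plane":
        return cls(np.asarray(d["n"], dtype=float), float(d["d"]))


# ---------------------------------------------------------------------------
# Rigid (and reflecting) transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Orthogonal map p -> R p + t.  det(R) = +1 (rigid) or -1 (reflection)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float = field(default=0.0, compare=False)
    score: float | None = field(default=None, compare=False)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthogonal within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @property
    def is_reflection(self) -> bool:
        return bool(np.linalg.det(self.rotation) < 0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])


def reflection_transform(plane: Plane) -> RigidTransform:
    """Householder reflection across ``plane``: p -> p - 2 (n.p - d) n."""
    n = plane.normal
    return RigidTransform(np.eye(3) - 2.0 * np.outer(n, n), 2.0 * plane.offset * n)


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

_SIDE_SUFFIX = {"_R": "_L", "_L": "_R"}


class LandmarkSet:
    """Named anatomical 3D points (mm)."""

    def __init__(self, points: Mapping[str, Iterable[float]]):
        self._points = {}
        for name, p in points.items():
            arr = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"landmark {name!r} has non-finite coordinates")
            self._points[str(name)] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._points[name]
        except KeyError:
            raise MissingLandmarkError(f"missing landmark {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._points

    def __iter__(self):
        return iter(self._points)

    def __len__(self):
        return len(self._points)

    def items(self):
        return self._points.items()

    def names(self):
        return list(self._points)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self._points]
        if missing:
            raise MissingLandmarkError(f"missing landmarks: {missing}")

    def array(self, names: Iterable[str]) -> np.ndarray:
        return np.stack([self[n] for n in names])

    def transformed(self, transform: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: transform.apply(p) for n, p in self._points.items()})

    def with_sides_swapped(self) -> "LandmarkSet":
        """Rename paired ``*_R``/``*_L`` landmarks (used after mirroring)."""
        out = {}
        for name, p in self._points.items():
            for suf, other in _SIDE_SUFFIX.items():
                if name.endswith(suf):
                    out[name[: -len(suf)] + other] = p
                    break
            else:
                out[name] = p
        return LandmarkSet(out)

    def to_dict(self) -> dict:
        return {n: [float(v) for v in p] for n, p in self._points.items()}


# ---------------------------------------------------------------------------
# Reflection dispatch
# ---------------------------------------------------------------------------


def reflect(geometry, plane: Plane):
    """Mirror a mesh, voxel mask or landmark set across ``plane``.

    An involution: ``reflect(reflect(g, p), p)`` recovers ``g``.  Mesh face
    winding is flipped so outward normals stay outward.
    """
    T = reflection_transform(plane)
    if isinstance(geometry, trimesh.Trimesh):
        out = geometry.copy()
        out.vertices = T.apply(out.vertices)
        out.faces = out.faces[:, ::-1]  # restore outward orientation
        return out
    if isinstance(geometry, LandmarkSet):
        return geometry.transformed(T)
    # VoxelMask lives in mandasym.volume; avoid circular import.
    from .volume import VoxelMask

    if isinstance(geometry, VoxelMask):
        return geometry.transformed(T)
    raise TypeError(f"cannot reflect object of type {type(geometry).__name__}")


# ---------------------------------------------------------------------------
# Reference frame (natural head position)
# ---------------------------------------------------------------------------

_OCCLUSAL_NAMES = ("MB_cusp_first_molar_R", "MB_cusp_first_molar_L", "Incisal_midpoint")


def _fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Least-squares plane normal through >= 3 points; raises if collinear."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("plane-fit points are collinear")
    return vt[2]


def build_reference_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Transform scanner coordinates into the natural-head-position frame.

    The axial plane is the occlusal plane (least-squares fit through the
    mesiobuccal cusps of the maxillary first molars and the incisal
    midpoint); +z is its normal oriented toward Nasion; +x is the
    left-to-right fronto-zygomatic direction projected into the axial plane;
    +y = z x x (anterior); the origin is the mid fronto-zygomatic point.
    """
    landmarks.require(*_OCCLUSAL_NAMES, "FZ_R", "FZ_L", "Nasion")
    occ = landmarks.array(_OCCLUSAL_NAMES)
    z = _fit_plane_normal(occ)
    origin = 0.5 * (landmarks["FZ_R"] + landmarks["FZ_L"])
    if np.dot(z, landmarks["Nasion"] - occ.mean(axis=0)) < 0:
        z = -z
    x = landmarks["FZ_R"] - landmarks["FZ_L"]
    x = x - np.dot(x, z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise DegenerateGeometryError("fronto-zygomatic axis is parallel to the occlusal normal")
    x = x / nx
    y = np.cross(z, x)
    R = np.stack([x, y, z])  # rows: world directions of the frame axes
    return RigidTransform(R, -R @ origin)


def midsagittal_plane(landmarks: LandmarkSet) -> Plane:
    """Midsagittal plane through ANS, Nasion and the mid fronto-zygomatic point.

    The normal is oriented toward the patient's left side.
    """
    landmarks.require("ANS", "Nasion", "FZ_R", "FZ_L")
    mid_fz = 0.5 * (landmarks["FZ_R"] + landmarks["FZ_L"])
    plane = Plane.from_points(landmarks["ANS"], landmarks["Nasion"], mid_fz)
    to_left = landmarks["FZ_L"] - landmarks["FZ_R"]
    if np.dot(plane.normal, to_left) < 0:
        plane = plane.flipped()
    return plane


# ---------------------------------------------------------------------------
# Clipping
# ---------------------------------------------------------------------------


def clip_mesh(mesh: trimesh.Trimesh, plane: Plane, keep: str = "positive") -> trimesh.Trimesh:
    """Keep the sub-surface of ``mesh`` on one side of ``plane``.

    Crossing triangles are split at the intersection; the cut is left open
    (no cap) because downstream distances are surface-to-surface.
    """
    if keep not in ("positive", "negative"):
        raise ValueError("keep must be 'positive' or 'negative'")
    normal = plane.normal if keep == "positive" else -plane.normal
    origin = plane.normal * plane.offset
    out = trimesh.intersections.slice_mesh_plane(
        mesh, plane_normal=normal, plane_origin=origin, cap=False
    )
    if out is None:
        out = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), dtype=int))
    return out


def menton_deviation(landmarks: LandmarkSet, plane: Plane) -> float:
    """Unsigned distance (mm) of Menton from the midsagittal plane."""
    landmarks.require("Menton")
    return float(abs(plane.signed_distance(landmarks["Menton"])[0]))


# ---------------------------------------------------------------------------
# Cephalometric classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CephalometricResult:
    sagittal_class: str  # "I" | "II" | "III"
    vertical_type: str  # "brachycephalic" | "mesocephalic" | "dolichocephalic"
    anb_deg: float
    fma_deg: float


def classify_angles(anb_deg: float, fma_deg: float) -> tuple[str, str]:
    """Steiner sagittal class from ANB and Ricketts vertical type from FMA.

    Class I is the closed band 0-4 deg (2 +/- 2), class II strictly > 4 deg,
    class III strictly < 0 deg.  Mesocephalic is the closed band 22-28 deg.
    """
    if anb_deg > 4.0:
        sagittal = "II"
    elif anb_deg < 0.0:
        sagittal = "III"
    else:
        sagittal = "I"
    if fma_deg < 22.0:
        vertical = "brachycephalic"
    elif fma_deg > 28.0:
        vertical = "dolichocephalic"
    else:
        vertical = "mesocephalic"
    return sagittal, vertical


def _sagittal_ray_angle(v: np.ndarray) -> float:
    """Angle of a sagittal-plane ray measured from straight down, anterior positive."""
    return float(np.degrees(np.arctan2(v[1], -v[2])))


def cephalometric_classify(landmarks: LandmarkSet) -> CephalometricResult:
    """ANB (Steiner) and FMA (Ricketts) with the study's class thresholds.

    ANB is the signed angle at Nasion between the rays to A-point and
    B-point, measured in the natural-head-position sagittal projection and
    positive when A lies anterior to B.  FMA is the dihedral angle between
    the Frankfort plane (Porion/Orbitale) and the mandibular plane
    (Gonion/Menton).  Both are invariant to global rigid motion because the
    frame is rebuilt from the landmarks themselves.
    """
    landmarks.require(
        "A_point", "B_point", "Nasion", "Menton",
        "Porion_R", "Porion_L", "Orbitale_R", "Orbitale_L",
        "Gonion_R", "Gonion_L",
    )
    frame = build_reference_frame(landmarks)
    lm = landmarks.transformed(frame)

    nasion = lm["Nasion"]
    ray_a = lm["A_point"] - nasion
    ray_b = lm["B_point"] - nasion
    if np.linalg.norm(ray_a) < 1e-9 or np.linalg.norm(ray_b) < 1e-9:
        raise DegenerateGeometryError("A/B point coincides with Nasion")
    anb = _sagittal_ray_angle(ray_a) - _sagittal_ray_angle(ray_b)
    anb = (anb + 180.0) % 360.0 - 180.0

    frankfort = _fit_plane_normal(
        lm.array(["Porion_R", "Porion_L", "Orbitale_R", "Orbitale_L"])
    )
    mandibular = _fit_plane_normal(lm.array(["Gonion_R", "Gonion_L", "Menton"]))
    cosang = abs(float(np.dot(frankfort, mandibular)))
    fma = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))

    sagittal, vertical = classify_angles(anb, fma)
    return CephalometricResult(sagittal, vertical, float(anb), fma)
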