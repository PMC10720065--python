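"""Synthetic mandible + cranial-base landmarks with known ground-truth asymmetry.

The template is the zero level set of a union of analytic implicit
primitives — a swept elliptical corpus arch, two rounded ramus slabs and two
condylar ellipsoids — extracted with marching cubes on a grid that is
symmetric about x = 0.  Because every primitive depends on x only through
|x|, the template is bilaterally symmetric to floating-point precision, and
region/side labels come for free from the analytic construction.

Skeletal classes are encoded in the landmarks: ANB by placing B-point on a
ray at the target angle from Nasion, FMA by inclining the Frankfort
landmarks (Porion/Orbitale) against the horizontal mandibular plane.  The
mandible mesh itself is shared across classes, which keeps the classifier
round-trip exact and the cohort cheap to generate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from skimage import measure

from .geometry import LandmarkSet, RigidTransform
from .volume import voxelize  # re-export: voxelization belongs to this surface

__all__ = [
    "MandibleParams",
    "AsymmetrySpec",
    "AsymmetryDistribution",
    "CohortConfig",
    "Subject",
    "generate_mandible",
    "apply_asymmetry",
    "generate_cohort",
    "voxelize",
]

REGIONS = ("condyle", "ramus", "corpus")
SIDES = ("left", "right")
MODES = ("outward_dilation", "lateral_shift", "elongation")

# oblique gonial-angle boundary between ramus and corpus: unit normal in the
# sagittal (anterior, superior) plane pointing anterior-inferior
_OBLIQUE_Y = 1.0 / np.sqrt(2.0)
_OBLIQUE_Z = -1.0 / np.sqrt(2.0)


@dataclass(frozen=True)
class MandibleParams:
    """Template dimensions (mm).  Defaults approximate an adult mandible."""

    corpus_length: float = 75.0
    ramus_height: float = 50.0
    condyle_radius: float = 9.0
    intergonial_width: float = 95.0
    symphysis_height: float = 13.0
    surface_point_budget: int = 20000

    def __post_init__(self):
        for name in (
            "corpus_length",
            "ramus_height",
            "condyle_radius",
            "intergonial_width",
            "symphysis_height",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.condyle_radius >= self.ramus_height:
            raise ValueError("condyle_radius must be smaller than ramus_height")
        if self.surface_point_budget < 100:
            raise ValueError("surface_point_budget must be at least 100")


@dataclass(frozen=True)
class AsymmetrySpec:
    """A localized ground-truth deformation of known magnitude (mm)."""

    region: str = "condyle"
    side: str = "left"
    mode: str = "outward_dilation"
    magnitude: float = 0.0

    def __post_init__(self):
        if self.region not in REGIONS + ("global",):
            raise ValueError(f"unknown region {self.region!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be non-negative")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

_RAMUS_HALF_THICKNESS = 4.0
_RAMUS_HALF_DEPTH = 12.0
_RAMUS_CENTER_Y = -2.0
_CORPUS_HALF_THICKNESS = 5.5
_RAMUS_ROUNDING = 2.5
_CONDYLE_NECK_DROP = 4.0  # extra inferior reach of the condylar ellipsoid (mm)


def _template_fields(params: MandibleParams):
    """Geometry constants derived from the parameters."""
    A = params.intergonial_width / 2.0
    B = params.corpus_length
    H = params.ramus_height
    z_notch = H - params.condyle_radius
    gonion = np.array([A, _RAMUS_CENTER_Y - _RAMUS_HALF_DEPTH, -params.symphysis_height])
    notch = np.array([A, _RAMUS_CENTER_Y, z_notch])
    return A, B, H, z_notch, gonion, notch


def _implicit_value(points: np.ndarray, params: MandibleParams) -> np.ndarray:
    """Union implicit field, negative inside.  Even in x by construction."""
    A, B, H, z_notch, _, _ = _template_fields(params)
    u = np.abs(points[:, 0])
    y = points[:, 1]
    z = points[:, 2]

    # corpus: quarter-ellipse centerline in the (|x|, y) plane, elliptical
    # cross-section (half thickness, symphysis height) swept along it
    phi = np.linspace(0.0, np.pi / 2.0, 720)
    curve = np.column_stack([A * np.sin(phi), B * np.cos(phi)])
    d_pl, _ = cKDTree(curve).query(np.column_stack([u, y]))
    f_corpus = np.sqrt(
        (d_pl / _CORPUS_HALF_THICKNESS) ** 2 + (z / params.symphysis_height) ** 2
    ) - 1.0

    # ramus: rounded box from the gonial angle to just below the sigmoid notch
    z_lo, z_hi = -params.symphysis_height, z_notch - 2.0
    half = np.array(
        [_RAMUS_HALF_THICKNESS, _RAMUS_HALF_DEPTH, (z_hi - z_lo) / 2.0]
    ) - _RAMUS_ROUNDING
    center = np.array([A, _RAMUS_CENTER_Y, (z_hi + z_lo) / 2.0])
    q = np.abs(np.column_stack([u, y, z]) - center) - half
    qp = np.maximum(q, 0.0)
    f_ramus = (
        np.sqrt(np.einsum("ij,ij->i", qp, qp))
        + np.minimum(q.max(axis=1), 0.0)
        - _RAMUS_ROUNDING
    )

    # condyle: head + neck as one elongated ellipsoid whose base overlaps the
    # ramus below the notch, so the notch-plane cross-section is wide and the
    # condyle/ramus junction crease is short
    r = params.condyle_radius
    f_condyle = np.sqrt(
        ((u - A) / (0.9 * r)) ** 2
        + ((y - _RAMUS_CENTER_Y) / r) ** 2
        + ((z - H) / (r + _CONDYLE_NECK_DROP)) ** 2
    ) - 1.0

    return np.minimum(np.minimum(f_corpus, f_ramus), f_condyle)


def _grid_spacing(params: MandibleParams) -> float:
    """Spacing chosen so the extracted surface has roughly the point budget."""
    A, B, H, _, _, _ = _template_fields(params)
    arc = np.pi / 2.0 * np.sqrt((A**2 + B**2) / 2.0)
    corpus_area = 2.0 * arc * np.pi * (_CORPUS_HALF_THICKNESS + params.symphysis_height) / 2.0 * 2.0
    ramus_area = 2.0 * 2.0 * (
        2 * _RAMUS_HALF_THICKNESS * 2 * _RAMUS_HALF_DEPTH
        + 2 * _RAMUS_HALF_THICKNESS * (H + params.symphysis_height)
        + 2 * _RAMUS_HALF_DEPTH * (H + params.symphysis_height)
    )
    condyle_area = 2.0 * 4.0 * np.pi * 0.9 * params.condyle_radius**2
    area = corpus_area + ramus_area + condyle_area
    return float(np.clip(np.sqrt(2.0 * area / params.surface_point_budget), 0.4, 3.0))


def _label_vertices(vertices: np.ndarray, params: MandibleParams):
    """Ground-truth region/side labels from the analytic plane partition."""
    _, _, _, z_notch, gonion, _ = _template_fields(params)
    x, y, z = vertices[:, 0], vertices[:, 1], vertices[:, 2]
    side = np.where(x < 0, "left", "right").astype("U5")
    region = np.full(len(vertices), "ramus", dtype="U7")
    region[z > z_notch] = "condyle"
    oblique = _OBLIQUE_Y * (y - gonion[1]) + _OBLIQUE_Z * (z - gonion[2])
    region[(z <= z_notch) & (oblique > 0)] = "corpus"
    return region, side


def _cranial_landmarks(anb_deg: float, fma_deg: float) -> dict:
    """Cranial/cephalometric points in the canonical frame.

    The occlusal plane is z = 18 and the mandibular plane z = -symphysis
    height, so ANB and FMA are hit exactly by construction.
    """
    nasion = np.array([0.0, 88.0, 62.0])
    a_point = np.array([0.0, 84.0, 22.0])
    ray_a = a_point - nasion
    theta_a = np.degrees(np.arctan2(ray_a[1], -ray_a[2]))
    theta_b = np.radians(theta_a - anb_deg)
    b_point = nasion + 70.0 * np.array([0.0, np.sin(theta_b), -np.cos(theta_b)])

    # Frankfort landmarks rotated about x through their pivot by the target FMA
    pivot = np.array([0.0, 26.0, 40.0])
    c, s = np.cos(np.radians(fma_deg)), np.sin(np.radians(fma_deg))

    def tilt(p):
        d = np.asarray(p, dtype=float) - pivot
        return pivot + np.array([d[0], c * d[1] - s * d[2], s * d[1] + c * d[2]])

    return {
        "Nasion": nasion,
        "Basion": [0.0, -35.0, 5.0],
        "ANS": [0.0, 86.0, 30.0],
        "FZ_R": [48.0, 68.0, 55.0],
        "FZ_L": [-48.0, 68.0, 55.0],
        "A_point": a_point,
        "B_point": b_point,
        "Porion_R": tilt([58.0, -20.0, 40.0]),
        "Porion_L": tilt([-58.0, -20.0, 40.0]),
        "Orbitale_R": tilt([33.0, 72.0, 40.0]),
        "Orbitale_L": tilt([-33.0, 72.0, 40.0]),
        "MB_cusp_first_molar_R": [24.0, 38.0, 18.0],
        "MB_cusp_first_molar_L": [-24.0, 38.0, 18.0],
        "Incisal_midpoint": [0.0, 70.0, 18.0],
    }


def template_landmarks(
    params: MandibleParams, anb_deg: float = 3.0, fma_deg: float = 25.0
) -> LandmarkSet:
    """Full landmark set for the canonical template."""
    A, B, _, _, gonion, notch = _template_fields(params)
    lm = _cranial_landmarks(anb_deg, fma_deg)
    lm.update(
        {
            "Menton": [0.0, B, -params.symphysis_height],
            "Gonion_R": gonion,
            "Gonion_L": gonion * np.array([-1.0, 1.0, 1.0]),
            "SigmoidNotch_R": notch,
            "SigmoidNotch_L": notch * np.array([-1.0, 1.0, 1.0]),
        }
    )
    return LandmarkSet(lm)


def _symmetrize(verts: np.ndarray) -> np.ndarray:
    """Average each vertex with its mirror partner to pin exact x-symmetry.

    Marching cubes interpolates in single precision, which leaves ~1e-5 mm
    of left/right discrepancy; pairing mirrored vertices and averaging
    removes it exactly wherever the pairing is an involution.
    """
    mirrored = verts * np.array([-1.0, 1.0, 1.0])
    dist, partner = cKDTree(verts).query(mirrored)
    ok = (partner[partner] == np.arange(len(verts))) & (dist < 1e-3)
    out = verts.copy()
    out[ok] = 0.5 * (verts[ok] + mirrored[partner][ok])
    return out


def generate_mandible(
    params: MandibleParams | None = None,
    seed: int = 0,
    anb_deg: float = 3.0,
    fma_deg: float = 25.0,
):
    """Build the symmetric template mesh, its landmarks and ground-truth labels.

    Returns ``(mesh, landmarks, labels)`` where ``labels`` is a dict with
    per-vertex ``region`` ({condyle, ramus, corpus}) and ``side``
    ({left, right}) arrays; the same arrays are attached to
    ``mesh.vertex_attributes``.  Deterministic: identical inputs give
    bit-identical vertex arrays (``seed`` is part of the API for symmetry
    with the cohort generator but the template itself is analytic).
    """
    if params is None:
        params = MandibleParams()
    spacing = _grid_spacing(params)
    A, B, H, _, _, _ = _template_fields(params)

    # x-grid symmetric about 0 (odd count) so the field is exactly even
    half_x = A + 0.9 * params.condyle_radius + 3.0 * spacing
    nx = int(np.ceil(half_x / spacing))
    xs = np.arange(-nx, nx + 1) * spacing
    ys = np.arange(
        _RAMUS_CENTER_Y - _RAMUS_HALF_DEPTH - 3.0 * spacing,
        B + _CORPUS_HALF_THICKNESS + 3.0 * spacing,
        spacing,
    )
    zs = np.arange(
        -params.symphysis_height - 3.0 * spacing,
        H + params.condyle_radius + _CONDYLE_NECK_DROP + 3.0 * spacing,
        spacing,
    )
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    f = _implicit_value(pts, params).reshape(gx.shape)

    verts, faces, _, _ = measure.marching_cubes(f, level=0.0)
    verts = verts * spacing + np.array([xs[0], ys[0], zs[0]])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    # weld duplicate vertices emitted by marching cubes, drop the collapsed
    # faces, then pin exact bilateral symmetry
    mesh.merge_vertices()
    fc = mesh.faces
    degenerate = (fc[:, 0] == fc[:, 1]) | (fc[:, 1] == fc[:, 2]) | (fc[:, 0] == fc[:, 2])
    mesh.update_faces(~degenerate)
    mesh.remove_unreferenced_vertices()
    mesh.vertices = _symmetrize(mesh.vertices.view(np.ndarray))
    if mesh.volume < 0:
        mesh.faces = mesh.faces[:, ::-1]

    region, side = _label_vertices(mesh.vertices.view(np.ndarray), params)
    mesh.vertex_attributes["region"] = region
    mesh.vertex_attributes["side"] = side
    landmarks = template_landmarks(params, anb_deg=anb_deg, fma_deg=fma_deg)
    return mesh, landmarks, {"region": region, "side": side}


# ---------------------------------------------------------------------------
# Asymmetry injection
# ---------------------------------------------------------------------------


def apply_asymmetry(mesh: trimesh.Trimesh, spec: AsymmetrySpec) -> trimesh.Trimesh:
    """Displace exactly the vertices matching ``spec.region``/``side``.

    ``outward_dilation`` moves along outward vertex normals,
    ``lateral_shift`` away from the midline along x, ``elongation`` along
    +z for condyle/ramus/global and +y (anterior) for corpus.  The maximum
    displacement equals ``spec.magnitude`` exactly.
    """
    if "region" not in mesh.vertex_attributes or "side" not in mesh.vertex_attributes:
        raise ValueError("mesh does not carry region/side labels")
    region = np.asarray(mesh.vertex_attributes["region"])
    side = np.asarray(mesh.vertex_attributes["side"])
    sel = side == spec.side
    if spec.region != "global":
        sel &= region == spec.region

    out = mesh.copy()
    out.vertex_attributes["region"] = region.copy()
    out.vertex_attributes["side"] = side.copy()
    if spec.magnitude == 0.0 or not sel.any():
        return out

    if spec.mode == "outward_dilation":
        direction = mesh.vertex_normals.view(np.ndarray)[sel]
    elif spec.mode == "lateral_shift":
        lateral = 1.0 if spec.side == "right" else -1.0
        direction = np.tile([lateral, 0.0, 0.0], (int(sel.sum()), 1))
    else:  # elongation
        axis = [0.0, 1.0, 0.0] if spec.region == "corpus" else [0.0, 0.0, 1.0]
        direction = np.tile(axis, (int(sel.sum()), 1))

    vertices = out.vertices.copy()
    vertices[sel] += spec.magnitude * direction
    out.vertices = vertices
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AsymmetryDistribution:
    """Per-subject sampler for the injected asymmetry.

    Defaults describe a clinically symmetric cohort: sub-millimetre
    half-normal magnitudes, a mild left-side preponderance and most of the
    deformation concentrated in the condyle.
    """

    region_probs: tuple = (("condyle", 0.45), ("ramus", 0.30), ("corpus", 0.25))
    p_left: float = 0.55
    mode: str = "outward_dilation"
    magnitude_scale_mm: float = 0.6

    def sample(self, rng: np.random.Generator) -> AsymmetrySpec:
        regions, probs = zip(*self.region_probs)
        region = str(rng.choice(regions, p=np.asarray(probs) / np.sum(probs)))
        side = "left" if rng.random() < self.p_left else "right"
        magnitude = float(np.abs(rng.normal(0.0, self.magnitude_scale_mm)))
        return AsymmetrySpec(region=region, side=side, mode=self.mode, magnitude=magnitude)


# ANB / FMA sampling bands per class, inside the Steiner / Ricketts thresholds
_ANB_BANDS = {"I": (0.5, 3.5), "II": (4.5, 8.0), "III": (-4.0, -0.5)}
_FMA_BANDS = {"brachycephalic": (16.0, 21.0), "mesocephalic": (22.5, 27.5), "dolichocephalic": (28.5, 34.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout.  Default split mirrors the study: 21/20/19 sagittal and
    22/19/19 vertical subjects."""

    n_per_sagittal_class: tuple = (21, 20, 19)
    n_per_vertical_class: tuple = (22, 19, 19)
    asymmetry_distribution: AsymmetryDistribution = field(default_factory=AsymmetryDistribution)
    seed: int = 0
    mandible_params: MandibleParams = field(default_factory=MandibleParams)
    pose_rotation_deg: float = 5.0
    pose_translation_mm: float = 10.0

    def __post_init__(self):
        if len(self.n_per_sagittal_class) != 3 or len(self.n_per_vertical_class) != 3:
            raise ValueError("class partitions must have 3 entries each")
        if sum(self.n_per_sagittal_class) != sum(self.n_per_vertical_class):
            raise ValueError("sagittal and vertical partitions must sum to the same total")


@dataclass
class Subject:
    subject_id: str
    mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    sagittal_class: str
    vertical_type: str
    anb_deg: float
    fma_deg: float
    asymmetry: AsymmetrySpec
    pose: RigidTransform


def _random_pose(rng: np.random.Generator, max_rot_deg: float, max_trans_mm: float) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    angles = rng.uniform(-max_rot_deg, max_rot_deg, size=3)
    R = Rotation.from_euler("xyz", angles, degrees=True).as_matrix()
    t = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    return RigidTransform(R, t)


def generate_cohort(config: CohortConfig | None = None) -> list[Subject]:
    """Generate a reproducible cohort with known per-subject ground truth.

    Every subject shares the template geometry, receives its sampled
    asymmetry, class-consistent cephalometric landmarks and a small random
    scanner pose (so the registration stages do real work).  The menton
    inclusion gate (< 2 mm midsagittal deviation) holds by construction.
    """
    if config is None:
        config = CohortConfig()
    rng = np.random.default_rng(config.seed)

    sagittal = [c for c, n in zip(("I", "II", "III"), config.n_per_sagittal_class) for _ in range(n)]
    vertical = [
        v
        for v, n in zip(
            ("brachycephalic", "mesocephalic", "dolichocephalic"), config.n_per_vertical_class
        )
        for _ in range(n)
    ]
    vertical = list(np.asarray(vertical)[rng.permutation(len(vertical))])

    base_mesh, _, _ = generate_mandible(config.mandible_params)
    subjects = []
    for i, (sag, vert) in enumerate(zip(sagittal, vertical)):
        anb = float(rng.uniform(*_ANB_BANDS[sag]))
        fma = float(rng.uniform(*_FMA_BANDS[vert]))
        spec = config.asymmetry_distribution.sample(rng)
        mesh = apply_asymmetry(base_mesh, spec)
        landmarks = template_landmarks(config.mandible_params, anb_deg=anb, fma_deg=fma)
        pose = _random_pose(rng, config.pose_rotation_deg, config.pose_translation_mm)
        region = mesh.vertex_attributes["region"]
        side = mesh.vertex_attributes["side"]
        mesh.vertices = pose.apply(mesh.vertices)
        mesh.vertex_attributes["region"] = region
        mesh.vertex_attributes["side"] = side
        subjects.append(
            Subject(
                subject_id=f"S{i:03d}",
                mesh=mesh,
                landmarks=landmarks.transformed(pose),
                sagittal_class=sag,
                vertical_type=vert,
                anb_deg=anb,
                fma_deg=fma,
                asymmetry=spec,
                pose=pose,
            )
        )
    return subjects
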