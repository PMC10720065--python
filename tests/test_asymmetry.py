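"""Correspondence, signed distance fields, region labels, color maps and the
full per-subject measurement."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from mandasym.asymmetry import (
    Correspondence,
    DistanceField,
    colormap_export,
    correspond_points,
    distance_colors,
    label_regions,
    measure_subject,
    signed_distance_field,
)
from mandasym.geometry import RigidTransform
from mandasym.synthetic import AsymmetrySpec, apply_asymmetry


@pytest.fixture(scope="module")
def measured_null(small_template):
    mesh, landmarks, _ = small_template
    return measure_subject(mesh, landmarks)


@pytest.fixture(scope="module")
def measured_dilated(small_template):
    mesh, landmarks, _ = small_template
    dilated = apply_asymmetry(mesh, AsymmetrySpec("condyle", "left", "outward_dilation", 2.0))
    return measure_subject(dilated, landmarks)


class TestCorrespondence:
    def test_identical_surfaces_give_zero_vectors(self):
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=6.0)
        c = correspond_points(sphere, sphere)
        assert c.count == len(sphere.vertices)
        assert np.linalg.norm(c.vectors, axis=1).max() < 1e-12

    def test_planar_patch_translation_vectors(self):
        patch = trimesh.Trimesh(
            vertices=[[0, 0, 0], [0, 10, 0], [0, 10, 10], [0, 0, 10]],
            faces=[[0, 1, 2], [0, 2, 3]],
            process=False,
        )
        target = patch.copy()
        target.apply_translation([0.5, 0, 0])
        c = correspond_points(patch, target)
        assert np.abs(np.linalg.norm(c.vectors, axis=1) - 0.5).max() < 1e-6

    def test_totality(self, small_template):
        mesh, _, _ = small_template
        sphere = trimesh.creation.icosphere(subdivisions=2, radius=40.0)
        c = correspond_points(mesh, sphere)
        assert c.count == len(mesh.vertices)

    def test_empty_mesh_rejected(self):
        empty = trimesh.Trimesh(vertices=np.zeros((0, 3)), faces=np.zeros((0, 3), int))
        sphere = trimesh.creation.icosphere(subdivisions=1)
        with pytest.raises(ValueError):
            correspond_points(empty, sphere)


class TestSignedField:
    def test_outward_dilated_sphere_positive_one(self):
        ref = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        target = trimesh.creation.icosphere(subdivisions=3, radius=11.0)
        c = correspond_points(ref, target)
        field = signed_distance_field(
            c, ref.vertex_normals, np.full(len(ref.vertices), "condyle")
        )
        assert np.abs(field.signed - 1.0).max() < 0.05
        assert np.allclose(field.absolute, np.abs(field.signed))

    def test_identical_surfaces_zero(self):
        ref = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
        c = correspond_points(ref, ref)
        field = signed_distance_field(c, ref.vertex_normals, np.full(len(ref.vertices), "ramus"))
        assert np.abs(field.signed).max() < 1e-12

    def test_worked_example_half_plus_half_minus(self):
        # half the points at +2 mm, half at -2 mm: mean signed 0, mean absolute 2
        n = 100
        pts = np.column_stack([np.zeros(n), np.arange(n, dtype=float), np.zeros(n)])
        normals = np.tile([1.0, 0.0, 0.0], (n, 1))
        offsets = np.where(np.arange(n) < n // 2, 2.0, -2.0)
        c = Correspondence(pts, pts + offsets[:, None] * normals)
        field = signed_distance_field(c, normals, np.full(n, "corpus"))
        assert field.signed.mean() == pytest.approx(0.0, abs=1e-12)
        assert field.absolute.mean() == pytest.approx(2.0, abs=1e-12)

    def test_zero_normal_rejected(self):
        pts = np.zeros((2, 3))
        c = Correspondence(pts, pts)
        with pytest.raises(ValueError, match="normal"):
            signed_distance_field(c, np.zeros((2, 3)), np.full(2, "corpus"))

    def test_invariants_on_measured_subject(self, measured_dilated):
        f = measured_dilated
        assert np.allclose(f.absolute, np.abs(f.signed), atol=1e-9)
        assert f.absolute.mean() >= abs(f.signed.mean())
        # vector norm equals absolute distance
        assert np.abs(np.linalg.norm(f.vectors, axis=1) - f.absolute).max() < 1e-9


class TestLabelRegions:
    def test_agreement_with_generator_truth(self, template):
        mesh, landmarks, labels = template
        pred = label_regions(mesh.vertices, landmarks)
        assert (pred == labels["region"]).mean() >= 0.95

    def test_partition_counts(self, template):
        mesh, landmarks, _ = template
        pred = label_regions(mesh.vertices, landmarks)
        counts = {r: int((pred == r).sum()) for r in ("condyle", "ramus", "corpus")}
        assert sum(counts.values()) == len(mesh.vertices)

    def test_point_above_notch_is_condyle(self, template):
        _, landmarks, _ = template
        p = landmarks["SigmoidNotch_R"] + [0.0, 0.0, 1.0]
        assert label_regions(p[None], landmarks, side="right")[0] == "condyle"

    def test_missing_landmarks_named(self, template):
        from mandasym.geometry import LandmarkSet, MissingLandmarkError

        _, landmarks, _ = template
        partial = LandmarkSet(
            {n: p for n, p in landmarks.items() if not n.startswith("SigmoidNotch")}
        )
        with pytest.raises(MissingLandmarkError, match="SigmoidNotch"):
            label_regions(np.zeros((1, 3)), partial, side="right")


class TestColormap:
    def test_anchor_colors_and_clamping(self):
        rgb = distance_colors([-2.5, -2.0, 0.0, 2.0, 2.5])
        assert tuple(rgb[0]) == (0, 0, 139)  # clamped to dark blue
        assert tuple(rgb[1]) == (0, 0, 139)
        assert tuple(rgb[2]) == (128, 128, 128)  # neutral grey
        assert tuple(rgb[3]) == (255, 0, 0)
        assert tuple(rgb[4]) == (255, 0, 0)

    def test_green_neutral_option(self):
        rgb = distance_colors([0.0], neutral="green")
        assert tuple(rgb[0]) == (0, 128, 0)
        with pytest.raises(ValueError):
            distance_colors([0.0], neutral="purple")

    def test_vtp_round_trip(self, tmp_path):
        from mandasym.io import read_vtp_point_data

        mesh = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        n = len(mesh.vertices)
        signed = np.linspace(-3.0, 3.0, n)
        field = DistanceField(
            points=mesh.vertices.view(np.ndarray).copy(),
            vectors=np.zeros((n, 3)),
            signed=signed,
            absolute=np.abs(signed),
            region=np.full(n, "corpus"),
        )
        path = tmp_path / "map.vtp"
        colormap_export(mesh, field, path)
        data = read_vtp_point_data(path)
        assert np.allclose(data["signed_distance_mm"], signed, atol=1e-6)
        assert data["RGB"].shape == (n, 3)

    def test_ply_written_with_colors(self, tmp_path):
        mesh = trimesh.creation.icosphere(subdivisions=1, radius=5.0)
        n = len(mesh.vertices)
        field = DistanceField(
            points=mesh.vertices.view(np.ndarray).copy(),
            vectors=np.zeros((n, 3)),
            signed=np.zeros(n),
            absolute=np.zeros(n),
            region=np.full(n, "corpus"),
        )
        path = tmp_path / "map.ply"
        colormap_export(mesh, field, path)
        back = trimesh.load(str(path), process=False)
        assert len(back.vertices) == n
        assert tuple(back.visual.vertex_colors[0][:3]) == (128, 128, 128)

    def test_mismatched_counts_rejected(self, tmp_path):
        mesh = trimesh.creation.icosphere(subdivisions=1)
        field = DistanceField(
            points=np.zeros((3, 3)),
            vectors=np.zeros((3, 3)),
            signed=np.zeros(3),
            absolute=np.zeros(3),
            region=np.full(3, "corpus"),
        )
        with pytest.raises(ValueError, match="points"):
            colormap_export(mesh, field, tmp_path / "map.vtp")


class TestMeasureSubject:
    def test_symmetric_subject_null(self, measured_null):
        assert abs(measured_null.signed.mean()) < 0.05
        assert measured_null.absolute.mean() < 0.05

    def test_left_condyle_dilation_recovered(self, measured_dilated):
        means = measured_dilated.region_mean_signed()
        assert 1.8 <= means["condyle"] <= 2.2
        assert abs(means["ramus"]) < 0.1
        assert abs(means["corpus"]) < 0.1

    def test_right_side_dilation_flips_sign(self, small_template):
        mesh, landmarks, _ = small_template
        dilated = apply_asymmetry(
            mesh, AsymmetrySpec("condyle", "right", "outward_dilation", 2.0)
        )
        field = measure_subject(dilated, landmarks)
        assert -2.2 <= field.region_mean_signed()["condyle"] <= -1.8

    def test_reference_side_swap(self, small_template, measured_dilated):
        mesh, landmarks, _ = small_template
        dilated = apply_asymmetry(
            mesh, AsymmetrySpec("condyle", "left", "outward_dilation", 2.0)
        )
        swapped = measure_subject(dilated, landmarks, reference_side="left")
        right_mean = measured_dilated.signed.mean()
        assert abs(swapped.signed.mean() + right_mean) <= 0.1 * abs(right_mean)
        assert abs(swapped.absolute.mean() - measured_dilated.absolute.mean()) < 0.05 * abs(
            measured_dilated.absolute.mean()
        )

    def test_rigid_invariance(self, small_template, measured_dilated, rng):
        mesh, landmarks, _ = small_template
        dilated = apply_asymmetry(
            mesh, AsymmetrySpec("condyle", "left", "outward_dilation", 2.0)
        )
        R = Rotation.from_euler("xyz", [9.0, -14.0, 21.0], degrees=True).as_matrix()
        motion = RigidTransform(R, np.array([12.0, -5.0, 30.0]))
        moved = dilated.copy()
        region = dilated.vertex_attributes["region"]
        side = dilated.vertex_attributes["side"]
        moved.vertices = motion.apply(moved.vertices)
        moved.vertex_attributes["region"] = region
        moved.vertex_attributes["side"] = side
        field = measure_subject(moved, landmarks.transformed(motion))
        assert abs(field.signed.mean() - measured_dilated.signed.mean()) < 1e-6
        assert abs(field.absolute.mean() - measured_dilated.absolute.mean()) < 1e-6

    def test_meta_reports_point_count(self, measured_null):
        assert measured_null.meta["n_points"] == measured_null.n_points > 0

    def test_stage_errors_are_named(self, small_template):
        from mandasym.geometry import LandmarkSet

        mesh, landmarks, _ = small_template
        broken = {n: p for n, p in landmarks.items()}
        broken["ANS"] = broken["Nasion"]
        with pytest.raises(RuntimeError, match="midsagittal"):
            measure_subject(mesh, LandmarkSet(broken))
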