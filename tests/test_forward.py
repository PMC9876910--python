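"""Forward projector: tangent-cone oracle and seeded case generation."""

import math

import numpy as np
import pytest

from hipplane import (
    GeometryError,
    MarkerProjection,
    generate_case,
    marker_height_iterative,
    project_sphere,
)
from hipplane.forward import (
    FULL_PINHOLE,
    PAPER_MODEL,
    axis_for_height,
)


class TestProjectSphere:
    def test_on_axis_inversion_is_exact(self, device):
        """On the central beam the height formula inverts the tangent
        cone exactly."""
        axis, disp = project_sphere(device, 0.0, 328.0)
        assert disp == 0.0
        sol = marker_height_iterative(device, MarkerProjection(axis, disp),
                                      tol=1e-10)
        assert sol.height_mm == pytest.approx(328.0, abs=1e-9)

    def test_standard_axis_anchors_plausible_height(self, device):
        """A 35 mm shadow of the 12.5 mm marker corresponds to a height
        around 328 mm (magnification ~1.4)."""
        z = device.S * (1 - 1 / 1.4)
        axis, _ = project_sphere(device, 0.0, z)
        assert axis == pytest.approx(35.0, abs=0.1)

    def test_near_contact_limit(self, device):
        """A sphere resting on the detector casts a shadow barely larger
        than its diameter."""
        axis, _ = project_sphere(device, 0.0, device.r)
        assert 2 * device.r < axis < 2 * device.r * 1.02

    def test_oblique_rays_elongate_the_shadow(self, device):
        on_axis, d0 = project_sphere(device, 0.0, 300.0)
        off_axis, d1 = project_sphere(device, 150.0, 300.0)
        assert off_axis >= on_axis
        assert d1 > d0

    def test_sphere_at_source_rejected(self, device):
        with pytest.raises(GeometryError):
            project_sphere(device, 0.0, device.S)

    def test_oracle_inversion_grid(self, device):
        """The iterative solver recovers the true sphere height within
        0.5 mm across the clinically relevant placement envelope."""
        worst = 0.0
        for z in np.linspace(100.0, 500.0, 9):
            for x in np.linspace(0.0, 200.0, 9):
                axis, disp = project_sphere(device, x, z)
                sol = marker_height_iterative(
                    device, MarkerProjection(axis, abs(disp)), tol=1e-8)
                worst = max(worst, abs(sol.height_mm - z))
        assert worst < 0.5


class TestAxisForHeight:
    @pytest.mark.parametrize("H, disp", [(100.0, 0.0), (328.4, 10.0),
                                         (316.0, 200.0), (500.0, 150.0)])
    def test_inverts_height_formula(self, device, H, disp):
        from hipplane import marker_height

        axis = axis_for_height(device, H, disp)
        back = marker_height(device, MarkerProjection(axis, disp))
        assert back == pytest.approx(H, abs=1e-8)


class TestGenerateCase:
    def test_seed_determinism(self):
        a = generate_case(1234)
        b = generate_case(1234)
        assert a.ap_landmarks == b.ap_landmarks
        assert a.lateral_landmarks == b.lateral_landmarks
        assert a.truth == b.truth
        assert a.scene == b.scene

    def test_different_seeds_differ(self):
        assert generate_case(1).truth != generate_case(2).truth

    def test_truth_consistent_with_scene(self):
        case = generate_case(5)
        scene = case.scene
        assert case.truth["H_Hip_true"] == scene.hip_plane_height_mm
        assert case.truth["H_ECM_true"] == pytest.approx(
            scene.hip_plane_height_mm + scene.marker_anterior_mm)
        assert case.truth["i_true"] == abs(scene.marker_left_mm)

    @pytest.mark.parametrize("fidelity", [PAPER_MODEL, FULL_PINHOLE])
    def test_marker_axis_is_magnified(self, fidelity):
        case = generate_case(9, fidelity=fidelity)
        assert case.ap_landmarks.marker_long_axis_mm > 2 * case.device.r
        assert case.lateral_landmarks.marker_long_axis_mm > 2 * case.device.r

    def test_perfect_lateral_overlays_hips(self):
        """Without rotation the two hip centers coincide horizontally in
        the lateral image.  Under the exact pinhole model this requires
        the hip axis on the central beam (off-beam hips at different
        depths diverge even unrotated — a physical property of cone
        beams that the trigonometric model idealises away)."""
        case = generate_case(77, fidelity=PAPER_MODEL,
                             ranges={"alpha_true": (0.0, 0.0)})
        lat = case.lateral_landmarks
        assert lat.right_hip[0] == pytest.approx(lat.left_hip[0], abs=1e-9)

        case = generate_case(77, fidelity=FULL_PINHOLE,
                             ranges={"alpha_true": (0.0, 0.0),
                                     "lat_horizontal_offset": (0.0, 0.0)})
        lat = case.lateral_landmarks
        assert lat.right_hip[0] == pytest.approx(lat.left_hip[0], abs=1e-9)

    def test_rotation_separates_hips_by_m_sin_alpha(self):
        """Under the trigonometric measurement model the hip-center
        separation equals m*sin(alpha) after marker-plane calibration."""
        case = generate_case(88, fidelity=PAPER_MODEL,
                             ranges={"alpha_true": (18.0, 18.0)})
        lat = case.lateral_landmarks
        sol = marker_height_iterative(
            case.device,
            MarkerProjection(
                lat.marker_long_axis_mm,
                math.hypot(lat.marker_center[0], lat.marker_center[1]),
                "lateral"),
            tol=1e-10)
        c_img = abs(lat.right_hip[0] - lat.left_hip[0])
        c_cal = c_img / (sol.factor_percent / 100.0)
        expected = case.truth["m_true"] * math.sin(math.radians(18.0))
        assert c_cal == pytest.approx(expected, abs=1e-4)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(GeometryError):
            generate_case(1, ranges={"hip_plane_height": (1100.0, 1120.0),
                                     "d_true": (90.0, 130.0)})
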