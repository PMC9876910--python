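"""Closed-form sphere-height geometry and the iterative solver."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hipplane import (
    ConvergenceError,
    DeviceSetup,
    GeometryError,
    MarkerProjection,
    factor_from_height,
    height_from_factor,
    marker_height,
    marker_height_iterative,
)


class TestMarkerHeight:
    @pytest.mark.parametrize(
        "axis, disp, expected, tol",
        [
            (35.0, 10.0, 328.415, 0.01),   # standard a.p. measurement
            (35.0, 200.0, 305.7, 0.1),     # standard lateral measurement
        ],
    )
    def test_closed_form_examples(self, device, axis, disp, expected, tol):
        H = marker_height(device, MarkerProjection(axis, disp))
        assert H == pytest.approx(expected, abs=tol)

    def test_monotone_in_axis(self, device):
        """A larger shadow means the marker sits nearer the source."""
        h36 = marker_height(device, MarkerProjection(36.0, 10.0))
        h35 = marker_height(device, MarkerProjection(35.0, 10.0))
        assert h36 > h35

    def test_monotone_in_displacement(self, device):
        """Off-axis spheres cast larger shadows, so at a fixed axis a
        larger displacement implies a lower marker."""
        h_near = marker_height(device, MarkerProjection(35.0, 10.0))
        h_far = marker_height(device, MarkerProjection(35.0, 150.0))
        assert h_far < h_near

    def test_axis_not_magnified_rejected(self, device):
        with pytest.raises(GeometryError, match="long axis"):
            marker_height(device, MarkerProjection(25.0, 0.0))

    def test_non_physical_height_rejected(self, device):
        # axis barely above the marker diameter implies a center below
        # the detector plane
        with pytest.raises(GeometryError, match="below the detector"):
            marker_height(device, MarkerProjection(25.0001, 0.0))


class TestIterativeSolver:
    def test_standard_ap_measurement(self, device):
        sol = marker_height_iterative(device, MarkerProjection(35.0, 10.0))
        assert sol.height_mm == pytest.approx(328.445, abs=0.01)
        assert sol.converged
        assert sol.n_iterations >= 1

    def test_zero_displacement_single_pass(self, device):
        """With the marker on the central beam the recalibration is the
        identity, so the mandatory single pass already converges."""
        direct = marker_height(device, MarkerProjection(35.0, 0.0))
        sol = marker_height_iterative(device, MarkerProjection(35.0, 0.0))
        assert sol.n_iterations == 1
        assert sol.height_mm == pytest.approx(direct, abs=1e-12)

    def test_large_displacement_converges(self, device):
        sol = marker_height_iterative(device, MarkerProjection(35.0, 200.0))
        assert sol.height_mm == pytest.approx(316.0, abs=1.0)
        assert sol.n_iterations >= 2

    @pytest.mark.parametrize("disp", [0.0, 10.0, 120.0, 250.0])
    def test_factor_sequence_contracts(self, device, disp):
        """Successive factor differences shrink monotonically."""
        S = device.S
        proj = MarkerProjection(35.0, disp)
        factors = []
        H = marker_height(device, proj)
        factors.append(factor_from_height(S, H))
        for _ in range(6):
            d = disp * (S - H) / S
            H = marker_height(device, MarkerProjection(35.0, d))
            factors.append(factor_from_height(S, H))
        diffs = [abs(b - a) for a, b in zip(factors, factors[1:])]
        assert all(b <= a + 1e-15 for a, b in zip(diffs, diffs[1:]))

    def test_fixed_point_self_consistent(self, device):
        """The converged height reproduces itself when the original
        displacement is de-magnified with the converged factor."""
        sol = marker_height_iterative(
            device, MarkerProjection(35.0, 200.0), tol=1e-12)
        d_cal = 200.0 * (device.S - sol.height_mm) / device.S
        H_again = marker_height(device, MarkerProjection(35.0, d_cal))
        assert H_again == pytest.approx(sol.height_mm, abs=1e-8)

    def test_non_convergence_raises_with_last_iterate(self, device):
        with pytest.raises(ConvergenceError) as exc:
            marker_height_iterative(
                device, MarkerProjection(35.0, 200.0), tol=1e-13, max_iter=2)
        assert exc.value.last is not None
        assert exc.value.last.n_iterations == 2


class TestFactorHeightConversions:
    @pytest.mark.parametrize(
        "H, expected",
        [(0.0, 100.0), (575.0, 200.0), (218.45, 123.45)],
    )
    def test_factor_from_height(self, H, expected):
        assert factor_from_height(1150.0, H) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("F, expected", [(100.0, 0.0), (200.0, 575.0)])
    def test_height_from_factor(self, F, expected):
        assert height_from_factor(1150.0, F) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(GeometryError):
            factor_from_height(1150.0, 1150.0)
        with pytest.raises(GeometryError):
            height_from_factor(1150.0, 99.0)

    @settings(max_examples=200, derandomize=True)
    @given(H=st.floats(min_value=0.0, max_value=1149.0))
    def test_inverse_identity(self, H):
        S = 1150.0
        back = height_from_factor(S, factor_from_height(S, H))
        assert back == pytest.approx(H, rel=1e-9, abs=1e-9)

    def test_roundtrip_through_solver_height(self, device):
        sol = marker_height_iterative(device, MarkerProjection(35.0, 10.0))
        back = height_from_factor(device.S,
                                  factor_from_height(device.S, sol.height_mm))
        assert back == pytest.approx(sol.height_mm, rel=1e-12)


class TestDeviceSetupValidation:
    @pytest.mark.parametrize("S, r", [(0.0, 12.5), (1150.0, 0.0),
                                      (1150.0, 600.0), (-5.0, 1.0)])
    def test_invalid_device_rejected(self, S, r):
        with pytest.raises(GeometryError):
            DeviceSetup(S, r)

    def test_negative_displacement_rejected(self):
        with pytest.raises(GeometryError):
            MarkerProjection(35.0, -1.0)
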