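"""Strain kernels, tensor algebra, principal strains, end-to-end recovery."""

import numpy as np
import pytest

import cardiostrain as cs
from cardiostrain.strain import (
    DERIVATIVE_KERNEL_5,
    derivative_response,
    displacement_gradient,
)


def grids(n=31, spacing=12.0):
    y, x = np.mgrid[0:n, 0:n].astype(float) * spacing
    return x, y


class TestDisplacementGradient:
    def test_constant_field_zero_gradient(self):
        u = np.full((20, 20), 3.7)
        g = displacement_gradient(u, u, spacing=12.0)
        interior = g[4]
        for comp in g[:4]:
            assert np.all(comp[interior] == 0.0)

    def test_linear_field_exact(self):
        """U_x = 0.02 x gives dUx/dx = 0.02 exactly (to 1e-10)."""
        x, y = grids()
        u_x = 0.02 * x
        u_y = np.zeros_like(x)
        dux_dx, dux_dy, duy_dx, duy_dy, valid = displacement_gradient(
            u_x, u_y, spacing=12.0
        )
        assert np.allclose(dux_dx[valid], 0.02, atol=1e-10)
        assert np.allclose(dux_dy[valid], 0.0, atol=1e-10)
        assert np.allclose(duy_dx[valid], 0.0, atol=1e-10)
        assert np.allclose(duy_dy[valid], 0.0, atol=1e-10)

    def test_sine_field_within_kernel_response(self):
        """Recovered d/dx sin(2 pi x / L) stays within the kernel's
        documented frequency response, and beats a coarse central
        difference used as a secondary oracle."""
        spacing = 12.0
        n = 64
        x, y = grids(n, spacing)
        L = 40 * spacing  # wavelength in px
        u_x = np.sin(2 * np.pi * x / L)
        u_y = np.zeros_like(x)
        dux_dx, *_, valid = displacement_gradient(u_x, u_y, spacing=spacing)
        true = (2 * np.pi / L) * np.cos(2 * np.pi * x / L)
        omega = 2 * np.pi * spacing / L  # radians per grid step
        expected_ratio = derivative_response(omega) / omega
        assert np.allclose(dux_dx[valid], expected_ratio * true[valid], atol=1e-9)
        # secondary oracle: plain central difference on the same samples
        cd = np.gradient(u_x, spacing, axis=1)
        assert np.abs(dux_dx[valid] - true[valid]).max() <= np.abs(
            cd[valid] - true[valid]
        ).max() + 1e-12

    def test_off_by_spacing_guard(self):
        """Halving the spacing doubles the reported gradient."""
        x, y = grids()
        u = 0.01 * x
        g12 = displacement_gradient(u, u * 0, spacing=12.0)[0]
        g6 = displacement_gradient(u, u * 0, spacing=6.0)[0]
        assert np.allclose(g6, 2 * g12)

    def test_invalid_points_propagate(self):
        x, y = grids(21)
        u = 0.01 * x
        valid = np.ones_like(u, dtype=bool)
        valid[10, 10] = False
        *_, vout = displacement_gradient(u, u * 0, spacing=12.0, valid=valid)
        # 5x5 kernel support around the invalid point is flagged
        assert not vout[8:13, 8:13].any()
        assert vout[4, 4]

    def test_grid_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            displacement_gradient(np.zeros((4, 4)), np.zeros((4, 4)), 12.0)

    def test_kernel_moments(self):
        """The 5-tap derivative has zero mean and unit first moment."""
        k = np.arange(-2, 3)
        assert DERIVATIVE_KERNEL_5.sum() == pytest.approx(0.0, abs=1e-15)
        assert (k * DERIVATIVE_KERNEL_5).sum() == pytest.approx(1.0, abs=1e-15)


class TestStrainTensor:
    def test_pure_shear(self):
        z = np.zeros((8, 8))
        s = np.full((8, 8), 0.01)
        exx, eyy, exy = cs.strain_tensor(z, s, s, z)
        assert np.all(exx == 0) and np.all(eyy == 0)
        assert np.allclose(exy, 0.01)

    def test_uniaxial_definition(self):
        x, y = grids()
        u_y = -0.05 * y
        g = displacement_gradient(np.zeros_like(y), u_y, spacing=12.0)
        exx, eyy, exy = cs.strain_tensor(*g[:4])
        v = g[4]
        assert np.allclose(eyy[v], -0.05, atol=1e-10)
        assert np.allclose(exx[v], 0.0, atol=1e-10)
        assert np.allclose(exy[v], 0.0, atol=1e-10)

    def test_rigid_rotation_cancels(self):
        """U_x = -theta y, U_y = theta x: symmetrization kills the strain."""
        theta = 0.01
        x, y = grids()
        g = displacement_gradient(-theta * y, theta * x, spacing=12.0)
        exx, eyy, exy = cs.strain_tensor(*g[:4])
        v = g[4]
        for comp in (exx, eyy, exy):
            assert np.abs(comp[v]).max() < 1e-10
        e1, e2 = cs.principal_strains(exx, eyy, exy)
        assert np.abs(e1[v]).max() < 1e-3 and np.abs(e2[v]).max() < 1e-3

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.strain_tensor(np.zeros((3, 3)), np.zeros((3, 3)),
                             np.zeros((3, 3)), np.zeros((4, 4)))


class TestPrincipalStrains:
    def test_diagonal_tensor(self):
        e1, e2 = cs.principal_strains(np.array(0.0), np.array(-0.05), np.array(0.0))
        assert e1 == pytest.approx(0.0, abs=1e-15)
        assert e2 == pytest.approx(-0.05, abs=1e-15)

    def test_isotropic_tensor(self):
        e1, e2 = cs.principal_strains(np.array(-0.02), np.array(-0.02), np.array(0.0))
        assert e1 == e2 == pytest.approx(-0.02)

    def test_matches_eigendecomposition_oracle(self):
        """Closed form agrees with numpy's symmetric eigensolver to 1e-12
        on 10^4 random tensors; trace and determinant invariants hold."""
        rng = np.random.default_rng(12345)
        exx, eyy, exy = rng.normal(0, 0.1, (3, 10_000))
        e1, e2 = cs.principal_strains(exx, eyy, exy)
        assert np.all(e1 >= e2)
        T = np.empty((10_000, 2, 2))
        T[:, 0, 0], T[:, 1, 1] = exx, eyy
        T[:, 0, 1] = T[:, 1, 0] = exy
        w = np.linalg.eigvalsh(T)  # ascending
        assert np.abs(e2 - w[:, 0]).max() <= 1e-12
        assert np.abs(e1 - w[:, 1]).max() <= 1e-12
        assert np.abs((e1 + e2) - (exx + eyy)).max() <= 1e-12
        assert np.abs(e1 * e2 - (exx * eyy - exy**2)).max() <= 1e-12

    def test_rotation_invariance(self):
        """Rotating the displacement field leaves (e1, e2) unchanged."""
        theta = np.deg2rad(30)
        c, s = np.cos(theta), np.sin(theta)
        x, y = grids()
        # uniform strain state in unrotated coordinates
        exx0, eyy0, exy0 = 0.03, -0.01, 0.02
        u_x = exx0 * x + exy0 * y
        u_y = exy0 * x + eyy0 * y
        # same physical field expressed in rotated coordinates:
        # U' = R U(R^T x'), with the tensor transforming as R E R^T
        xr = c * x + s * y
        yr = -s * x + c * y
        ux_r = exx0 * xr + exy0 * yr
        uy_r = exy0 * xr + eyy0 * yr
        u_xp = c * ux_r - s * uy_r
        u_yp = s * ux_r + c * uy_r
        g0 = displacement_gradient(u_x, u_y, spacing=12.0)
        gr = displacement_gradient(u_xp, u_yp, spacing=12.0)
        e1a, e2a = cs.principal_strains(*cs.strain_tensor(*g0[:4]))
        e1b, e2b = cs.principal_strains(*cs.strain_tensor(*gr[:4]))
        v = g0[4] & gr[4]
        assert np.allclose(e1a[v], e1b[v], atol=1e-10)
        assert np.allclose(e2a[v], e2b[v], atol=1e-10)


class TestEndToEndRecovery:
    def test_masked_mean_eps2_peak_within_10pct(self, uniaxial_analysis):
        """Full pipeline on a 0.05 peak-strain video lands within 10 %."""
        result, truth = uniaxial_analysis
        peak = result.metrics.max_contractile_strain
        assert peak == pytest.approx(truth.true_peak_mean_contractile_strain, rel=0.10)
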