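"""Strain-tensor fields from gridded displacement data.

Displacement gradients are taken on the subset grid by separable
convolution with a fixed 5-tap derivative kernel along the derivative
axis and a matched 5-tap smoother transverse to it, then divided by the
grid spacing in pixels so strains come out dimensionless.  The
infinitesimal (small-strain) tensor is used: at the <= 15 % strains of
contracting monolayers the finite-strain correction is second order.

The second principal strain eps_2 — the smaller (most compressive)
eigenvalue of the 2-D tensor — is the contractile-strain observable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

#: 5-tap derivative kernel (per grid step).  Fourth-order central
#: difference: exact for cubic polynomials, hence exact on the linear
#: displacement fields of uniform strain.
DERIVATIVE_KERNEL_5 = np.array([1.0, -8.0, 0.0, 8.0, -1.0]) / 12.0

#: Matched 5-tap binomial smoother applied transverse to the derivative.
SMOOTHING_KERNEL_5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0

#: 3-tap central-difference fallback for cross-validation.
DERIVATIVE_KERNEL_3 = np.array([-0.5, 0.0, 0.5])


def derivative_response(omega: np.ndarray) -> np.ndarray:
    """Frequency response of the 5-tap derivative kernel.

    For a signal exp(i w k) sampled at unit grid step the kernel returns
    i * R(w) * exp(i w k) with R(w) = (8 sin w - sin 2w) / 6; the ideal
    differentiator has R(w) = w.  Useful for bounding the error expected
    on sinusoidal test fields.
    """
    omega = np.asarray(omega, dtype=float)
    return (8.0 * np.sin(omega) - np.sin(2.0 * omega)) / 6.0


@dataclass
class StrainField:
    """Per-frame strain tensor and principal-strain grids.

    All components dimensionless; eps_1 >= eps_2 pointwise.  ``valid``
    marks grid points whose 5x5 kernel support lay fully inside valid
    displacement data.
    """

    eps_xx: np.ndarray
    eps_yy: np.ndarray
    eps_xy: np.ndarray
    eps_1: np.ndarray
    eps_2: np.ndarray
    valid: np.ndarray
    frame_rate: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.eps_xx.shape[0]


def displacement_gradient(
    u_x: np.ndarray,
    u_y: np.ndarray,
    spacing: float,
    valid: Optional[np.ndarray] = None,
    kernel: str = "optimal5",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Four displacement-gradient grids by separable convolution.

    Returns (dux_dx, dux_dy, duy_dx, duy_dy, valid_out).  ``spacing``
    is the subset spacing in px: derivatives per grid step are divided
    by it, converting to per-pixel gradients and therefore dimensionless
    strain — omitting this division is the classic off-by-spacing bug.

    Points whose kernel support overruns the grid border or touches an
    invalid displacement point are flagged invalid.
    """
    u_x = np.asarray(u_x, dtype=float)
    u_y = np.asarray(u_y, dtype=float)
    if u_x.shape != u_y.shape:
        raise ValueError(f"u_x {u_x.shape} and u_y {u_y.shape} differ in shape")
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if kernel == "optimal5":
        d, s, half = DERIVATIVE_KERNEL_5, SMOOTHING_KERNEL_5, 2
    elif kernel == "central3":
        d, s, half = DERIVATIVE_KERNEL_3, np.array([0.0, 1.0, 0.0]), 1
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    ny, nx = u_x.shape
    if ny < len(d) or nx < len(d):
        raise ValueError(
            f"grid {u_x.shape} smaller than the {len(d)}-tap kernel"
        )

    if valid is None:
        valid = np.ones_like(u_x, dtype=bool)
    else:
        valid = np.asarray(valid, dtype=bool)
    # zero-fill invalid points so they cannot inject NaN; their influence
    # zone is flagged invalid below
    ux_f = np.where(valid, u_x, 0.0)
    uy_f = np.where(valid, u_y, 0.0)

    def sep(u, deriv_axis):
        # correlate1d centers the taps, so tap k multiplies the sample at
        # offset k: a unit ramp returns exactly +1 per grid step
        g = ndimage.correlate1d(u, d, axis=deriv_axis, mode="nearest")
        other = 1 - deriv_axis
        g = ndimage.correlate1d(g, s, axis=other, mode="nearest")
        return g / spacing

    dux_dx = sep(ux_f, 1)
    dux_dy = sep(ux_f, 0)
    duy_dx = sep(uy_f, 1)
    duy_dy = sep(uy_f, 0)

    # validity: erode by the kernel footprint and cut the border
    valid_out = ndimage.binary_erosion(
        valid, structure=np.ones((2 * half + 1, 2 * half + 1)), border_value=0
    )
    return dux_dx, dux_dy, duy_dx, duy_dy, valid_out


def strain_tensor(
    dux_dx: np.ndarray,
    dux_dy: np.ndarray,
    duy_dx: np.ndarray,
    duy_dy: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infinitesimal strain tensor from the four gradient grids.

    eps_xx = dUx/dx, eps_yy = dUy/dy, eps_xy = (dUx/dy + dUy/dx) / 2.
    The antisymmetric part (rigid rotation) cancels in the
    symmetrization.
    """
    shapes = {g.shape for g in (dux_dx, dux_dy, duy_dx, duy_dy)}
    if len(shapes) != 1:
        raise ValueError(f"gradient grids differ in shape: {sorted(shapes)}")
    eps_xx = np.asarray(dux_dx, dtype=float)
    eps_yy = np.asarray(duy_dy, dtype=float)
    eps_xy = 0.5 * (np.asarray(dux_dy, dtype=float) + np.asarray(duy_dx, dtype=float))
    return eps_xx, eps_yy, eps_xy


def principal_strains(
    eps_xx: np.ndarray, eps_yy: np.ndarray, eps_xy: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Principal strains of the 2-D symmetric tensor, eps_1 >= eps_2.

    Closed form: (exx + eyy)/2 +/- sqrt(((exx - eyy)/2)^2 + exy^2).
    eps_2 is the most compressive eigenvalue — the contractile strain.
    """
    eps_xx = np.asarray(eps_xx, dtype=float)
    eps_yy = np.asarray(eps_yy, dtype=float)
    eps_xy = np.asarray(eps_xy, dtype=float)
    if not (eps_xx.shape == eps_yy.shape == eps_xy.shape):
        raise ValueError("tensor component grids differ in shape")
    mean = 0.5 * (eps_xx + eps_yy)
    radius = np.sqrt((0.5 * (eps_xx - eps_yy)) ** 2 + eps_xy**2)
    return mean + radius, mean - radius


def strain_from_displacement(
    disp_field,
    kernel: str = "optimal5",
) -> StrainField:
    """Full strain pipeline over a DisplacementField (all frames)."""
    n = disp_field.n_frames
    ny, nx = disp_field.grid_shape
    out = {k: np.zeros((n, ny, nx)) for k in ("eps_xx", "eps_yy", "eps_xy", "eps_1", "eps_2")}
    valid = np.zeros((n, ny, nx), dtype=bool)
    for k in range(n):
        g = displacement_gradient(
            disp_field.u_x[k],
            disp_field.u_y[k],
            spacing=disp_field.subset_spacing,
            valid=disp_field.valid[k],
            kernel=kernel,
        )
        exx, eyy, exy = strain_tensor(g[0], g[1], g[2], g[3])
        e1, e2 = principal_strains(exx, eyy, exy)
        out["eps_xx"][k], out["eps_yy"][k], out["eps_xy"][k] = exx, eyy, exy
        out["eps_1"][k], out["eps_2"][k] = e1, e2
        valid[k] = g[4]
    return StrainField(
        eps_xx=out["eps_xx"],
        eps_yy=out["eps_yy"],
        eps_xy=out["eps_xy"],
        eps_1=out["eps_1"],
        eps_2=out["eps_2"],
        valid=valid,
        frame_rate=disp_field.frame_rate,
        meta={"kernel": kernel, "spacing_px": disp_field.subset_spacing},
    )
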