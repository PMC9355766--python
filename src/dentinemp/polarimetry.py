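"""Signed hyperpolarizability-ratio (ρ) inversion from polarimetric SHG.

Collagen's polarization-resolved SHG response under cylindrical symmetry
is I(Δ) ∝ sin²(2Δ) + [sin²Δ + ρ·cos²Δ]², with Δ the angle between the
incident linear polarization and the fiber axis.  Three acquisitions
suffice to recover ρ per pixel: the two states nearest the parallel and
perpendicular configurations carry the magnitude information (in the
canonical frame |ρ| = sqrt(I_par/I_perp)), and the remaining oblique
state resolves the sign.  Negative ρ of growing magnitude indicates
increasing internal (nanoscale) order of the dentinal collagen.

Off the canonical frame the intensity ratio of the two states still pins
ρ down to the two roots of a quadratic; :func:`rho_map` solves it exactly
and lets the third state select the root, so noiseless recovery is exact
for any fiber orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axial import axial_distance_deg
from .images import MPImage, PolarimetricStack
from .synthetic import shg_response


class GeometryError(ValueError):
    """The polarization-state geometry cannot resolve ρ."""


@dataclass
class RhoMap:
    """Signed ρ field with validity mask and summary statistics."""

    values: np.ndarray
    mask: np.ndarray  # True where valid
    summary_mean: float
    summary_sd: float
    fiber_orientation_deg: float

    @property
    def masked_fraction(self) -> float:
        return 1.0 - float(self.mask.mean())


def _check_mirror_degeneracy(deltas: np.ndarray, tol_deg: float) -> None:
    """Reject fiber frames where two states are mirror images about the axis.

    The response is even in Δ, so states at Δ and −Δ give identical
    intensities for every ρ: the stack then carries only one independent
    ratio and ρ is two-valued.  With acquisition angles {0°, 90°, 60°}
    this happens for fibers near 30°, 45°, 75° (mod 90°).
    """
    for i in range(3):
        for j in range(i + 1, 3):
            sep = axial_distance_deg(deltas[i], -deltas[j])
            if sep < tol_deg:
                raise GeometryError(
                    f"mirror-degenerate geometry: states at Δ={deltas[i]:.1f}° "
                    f"and Δ={deltas[j]:.1f}° are symmetric about the fiber "
                    "axis, so their intensities coincide for every ρ")


def _frame_roles(stack: PolarimetricStack, theta_deg: float,
                 pair_min_sep_deg: float = 25.0,
                 mirror_tol_deg: float = 3.0) -> tuple[int, int, int, np.ndarray]:
    """Assign (parallel, perpendicular, oblique) roles in the fiber frame."""
    deltas = stack.angles_deg - theta_deg
    _check_mirror_degeneracy(deltas, mirror_tol_deg)
    d_par = np.array([axial_distance_deg(d, 0.0) for d in deltas])
    d_perp = np.array([axial_distance_deg(d, 90.0) for d in deltas])
    i_par = int(np.argmin(d_par))
    i_perp = int(np.argmin(d_perp))
    if i_par == i_perp:
        i_perp = int(np.argsort(d_perp)[1])
    sep = axial_distance_deg(deltas[i_par], deltas[i_perp])
    if sep < pair_min_sep_deg:
        raise GeometryError(
            f"geometry unresolvable: magnitude states only {sep:.1f}° apart "
            "in the fiber frame")
    i_third = ({0, 1, 2} - {i_par, i_perp}).pop()
    return i_par, i_perp, i_third, deltas


def _default_floor(i_perp: np.ndarray) -> float:
    return 0.01 * float(i_perp.max())


def rho_magnitude(stack: PolarimetricStack, theta_deg: float,
                  floor: float | None = None) -> np.ndarray:
    """|ρ| field from the two states nearest Δ = 0 and Δ = 90°.

    Pixelwise sqrt(I_par / I_perp); exact when the acquisition angles sit
    on the fiber frame (Δ exactly 0/90°).  Pixels with I_perp at/below
    the floor are NaN.
    """
    i_par, i_perp, _, _ = _frame_roles(stack, theta_deg)
    frames = stack.intensity()
    ipar, iperp = frames[i_par], frames[i_perp]
    if floor is None:
        floor = _default_floor(iperp)
    out = np.full(ipar.shape, np.nan)
    ok = iperp > floor
    out[ok] = np.sqrt(np.clip(ipar[ok], 0.0, None) / iperp[ok])
    return out


def rho_sign(stack: PolarimetricStack, abs_rho: np.ndarray, theta_deg: float,
             floor: float | None = None,
             degenerate_tol_deg: float = 5.0) -> np.ndarray:
    """Sign field {−1, +1} resolved by the oblique third state.

    For each pixel the forward model predicts the third-state/perpendicular
    intensity ratio under +|ρ| and −|ρ|; the sign with the smaller
    discrepancy wins.  Pixels with |ρ| ≈ 0, ties, or masked inputs get 0.
    """
    i_par, i_perp, i_third, deltas = _frame_roles(stack, theta_deg)
    d3 = deltas[i_third]
    if (axial_distance_deg(d3, 0.0) < degenerate_tol_deg
            or axial_distance_deg(d3, 90.0) < degenerate_tol_deg):
        raise GeometryError(
            f"third state at Δ={d3:.1f}° is (anti)parallel/perpendicular "
            "in the fiber frame: sign unresolvable")
    frames = stack.intensity()
    iperp, ithird = frames[i_perp], frames[i_third]
    if floor is None:
        floor = _default_floor(iperp)
    ok = (iperp > floor) & np.isfinite(abs_rho) & (np.abs(abs_rho) > 1e-9)
    measured = np.zeros_like(iperp)
    np.divide(ithird, iperp, out=measured, where=ok)
    sign = np.zeros(iperp.shape, dtype=np.int8)
    a = np.abs(abs_rho)
    d_perp = deltas[i_perp]
    err_pos = np.abs(shg_response(d3, a) / shg_response(d_perp, a) - measured)
    err_neg = np.abs(shg_response(d3, -a) / shg_response(d_perp, -a) - measured)
    sign[ok & (err_pos < err_neg)] = 1
    sign[ok & (err_neg < err_pos)] = -1
    return sign


def _quadratic_roots(delta1: float, delta2: float,
                     ratio: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Both ρ roots of I(Δ1)/I(Δ2) = ratio under the forward model."""
    d1, d2 = np.deg2rad(delta1), np.deg2rad(delta2)
    s1, c1 = np.sin(d1) ** 2, np.cos(d1) ** 2
    s2, c2 = np.sin(d2) ** 2, np.cos(d2) ** 2
    k1, k2 = np.sin(2 * d1) ** 2, np.sin(2 * d2) ** 2
    a = c1 ** 2 - ratio * c2 ** 2
    b = 2.0 * (s1 * c1 - ratio * s2 * c2)
    c = (k1 + s1 ** 2) - ratio * (k2 + s2 ** 2)
    disc = b ** 2 - 4.0 * a * c
    valid = disc >= -1e-9 * np.maximum(b ** 2, 1.0)
    sq = np.sqrt(np.clip(disc, 0.0, None))
    lin = np.abs(a) < 1e-12
    r_plus = np.where(lin, np.divide(-c, b, out=np.zeros_like(c),
                                     where=np.abs(b) > 1e-300),
                      (-b + sq) / np.where(lin, 1.0, 2.0 * a))
    r_minus = np.where(lin, r_plus, (-b - sq) / np.where(lin, 1.0, 2.0 * a))
    return r_plus, r_minus, valid


def rho_map(stack: PolarimetricStack, theta_deg: float | None = None,
            floor: float | None = None, method: str = "pixelwise",
            degenerate_tol_deg: float = 5.0) -> RhoMap:
    """Signed ρ map from a three-polarization SHG stack.

    The intensity ratio of the (near-)parallel and (near-)perpendicular
    states determines ρ up to the two roots of a quadratic (±sqrt of the
    ratio in the canonical frame); the oblique state picks the root whose
    predicted intensity matches best, fixing both sign and value.  With
    ``method="mean"`` the inversion runs once on image-averaged
    intensities instead of pixelwise.

    If ``theta_deg`` is omitted the fiber orientation is estimated from
    the summed stack via the Hough transform.
    """
    if theta_deg is None:
        from .morphometry import estimate_orientation_hough
        total = MPImage(stack.intensity().sum(axis=0), "SHG",
                        stack.pixel_size_um)
        theta_deg = estimate_orientation_hough(total)
    i_par, i_perp, i_third, deltas = _frame_roles(stack, theta_deg)
    d1, d2, d3 = deltas[i_par], deltas[i_perp], deltas[i_third]
    if (axial_distance_deg(d3, 0.0) < degenerate_tol_deg
            or axial_distance_deg(d3, 90.0) < degenerate_tol_deg):
        raise GeometryError(
            f"third state at Δ={d3:.1f}° cannot disambiguate the two roots")
    frames = stack.intensity()
    ipar, iperp, ithird = frames[i_par], frames[i_perp], frames[i_third]
    if floor is None:
        floor = _default_floor(iperp)

    if method == "mean":
        ok0 = iperp > floor
        if not ok0.any():
            raise ValueError("all pixels below the noise floor")
        ratio = np.array([ipar[ok0].mean() / iperp[ok0].mean()])
        meas3 = np.array([ithird[ok0].mean() / iperp[ok0].mean()])
    elif method == "pixelwise":
        ok0 = iperp > floor
        ratio = np.zeros_like(iperp)
        meas3 = np.zeros_like(iperp)
        np.divide(ipar, iperp, out=ratio, where=ok0)
        np.divide(ithird, iperp, out=meas3, where=ok0)
    else:
        raise ValueError(f"unknown method {method!r}")

    r_a, r_b, root_ok = _quadratic_roots(d1, d2, ratio)
    err_a = np.abs(shg_response(d3, r_a) / shg_response(d2, r_a) - meas3)
    err_b = np.abs(shg_response(d3, r_b) / shg_response(d2, r_b) - meas3)
    values = np.where(err_a <= err_b, r_a, r_b)

    if method == "mean":
        v = float(values[0])
        vals = np.full(iperp.shape, v)
        mask = ok0 & np.asarray(root_ok[0])
        return RhoMap(values=vals, mask=mask, summary_mean=v, summary_sd=0.0,
                      fiber_orientation_deg=float(theta_deg))

    mask = ok0 & root_ok & np.isfinite(values) & (np.abs(values) > 1e-9)
    if not mask.any():
        raise ValueError("no valid pixels: ρ map undefined")
    inside = values[mask]
    return RhoMap(values=np.where(mask, values, np.nan), mask=mask,
                  summary_mean=float(inside.mean()),
                  summary_sd=float(inside.std()),
                  fiber_orientation_deg=float(theta_deg))
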