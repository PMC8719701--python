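"""Parametric red-blood-cell shape model and voxel rasterization.

The resting discocyte is modelled as an axisymmetric biconcave disc with an
Evans-Fung-style quartic half-thickness profile::

    h(x) = 1/2 * sqrt(1 - x^2) * (C0 + C2 x^2 + C4 x^4),   x = r / R0 in [0, 1]

so the full thickness at radial position r is 2 h(r / R0).  The default
coefficients C0 = 0.81, C2 = 7.83, C4 = -4.39 um with maximal radius
R0 = 3.91 um reproduce the canonical human RBC: diameter 7.8 um, maximal
thickness ~2.5 um and volume ~94 fL.

Sphering (saline/PBS-induced loss of biconcavity) is modelled by a
*sphering index* s in [0, 1] that linearly blends the normalized biconcave
profile with the profile of the equal-volume sphere, followed by an
isotropic rescale so that the cell volume is conserved along the morph.

Everything here is exact, continuous geometry; :func:`rasterize_cell`
samples it onto a voxel grid with supersampled partial-volume averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import integrate, optimize

from .io import Tomogram

__all__ = [
    "DEFAULT_COEFFS",
    "DEFAULT_R0",
    "ShapeSpec",
    "discocyte_half_thickness",
    "default_discocyte",
    "spherocyte",
    "shape_volume_analytic",
    "shape_surface_area_analytic",
    "shape_sphericity_analytic",
    "shape_max_thickness",
    "morph_to_sphere",
    "rasterize_cell",
    "tilt_rotation",
]

#: default Evans-Fung quartic coefficients (C0, C2, C4), um
DEFAULT_COEFFS = (0.81, 7.83, -4.39)
#: default maximal cell radius, um (diameter 7.82 um)
DEFAULT_R0 = 3.91

_KINDS = ("discocyte", "spherocyte", "morph")


def discocyte_half_thickness(x, coeffs=DEFAULT_COEFFS):
    """Half-thickness h(x) of the biconcave profile at normalized radius x.

    Parameters
    ----------
    x : float or ndarray
        Normalized radial coordinate r / R0 in [0, 1].
    coeffs : (C0, C2, C4)
        Quartic profile coefficients in um.

    Returns
    -------
    float or ndarray
        Half-thickness in um; h(1) = 0 (closed rim).
    """
    x = np.asarray(x, dtype=float)
    if np.any((x < -1e-12) | (x > 1 + 1e-12)):
        raise ValueError("normalized radius x must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    c0, c2, c4 = coeffs
    h = 0.5 * np.sqrt(1.0 - x**2) * (c0 + c2 * x**2 + c4 * x**4)
    if h.ndim == 0:
        return float(h)
    return h


def _validate_coeffs(coeffs: tuple[float, float, float]) -> None:
    xs = np.linspace(0.0, 1.0, 2001)
    if np.any(discocyte_half_thickness(xs, coeffs) < -1e-12):
        raise ValueError(f"profile coefficients {coeffs} give negative half-thickness on [0, 1]")


@dataclass
class ShapeSpec:
    """A parametric cell shape.

    ``kind`` is ``discocyte`` (quartic biconcave profile), ``spherocyte``
    (ball of radius ``R0``) or ``morph`` (sphering blend at index ``s``).
    ``target_volume_fl`` triggers an isotropic rescale to that volume; for a
    ``morph`` the rescale additionally conserves volume along s.
    ``orientation`` maps cell-frame coordinates (z = symmetry axis) to lab
    frame; ``center_um`` positions the cell in the field, (z, y, x) um.
    """

    kind: str = "discocyte"
    R0: float = DEFAULT_R0
    profile_coeffs: tuple[float, float, float] = DEFAULT_COEFFS
    s: float = 0.0
    target_volume_fl: float | None = None
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    center_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("sphering index s must lie in [0, 1]")
        if self.kind != "spherocyte":
            _validate_coeffs(self.profile_coeffs)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 rotation matrix")


def default_discocyte(**kwargs) -> ShapeSpec:
    """The canonical resting discocyte (7.82 um diameter, ~94 fL)."""
    return ShapeSpec(kind="discocyte", **kwargs)


def spherocyte(radius_um: float, **kwargs) -> ShapeSpec:
    return ShapeSpec(kind="spherocyte", R0=radius_um, **kwargs)


# ---------------------------------------------------------------------------
# profile evaluation: every shape is a solid of revolution |z| <= h(r), r <= R
# ---------------------------------------------------------------------------


def _unscaled_profile(spec: ShapeSpec) -> tuple[float, Callable]:
    """Support radius R and half-thickness h(x on [0,1]) before any rescale."""
    if spec.kind == "discocyte":
        return spec.R0, lambda x: discocyte_half_thickness(x, spec.profile_coeffs)
    if spec.kind == "spherocyte":
        return spec.R0, lambda x: spec.R0 * np.sqrt(np.clip(1.0 - np.asarray(x) ** 2, 0.0, None))

    # morph: blend normalized biconcave and equal-volume-sphere profiles
    base = ShapeSpec(kind="discocyte", R0=spec.R0, profile_coeffs=spec.profile_coeffs)
    v0 = _quadrature_volume(*_unscaled_profile(base))
    r_eq = (3.0 * v0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    s = spec.s
    support = (1.0 - s) * spec.R0 + s * r_eq

    def h(x):
        x = np.asarray(x, dtype=float)
        disc = discocyte_half_thickness(np.clip(x, 0, 1), spec.profile_coeffs)
        sph = r_eq * np.sqrt(np.clip(1.0 - x**2, 0.0, None))
        return (1.0 - s) * disc + s * sph

    return support, h


def _quadrature_volume(support: float, h: Callable) -> float:
    # V = int_0^R 2 h(r/R) 2 pi r dr, substituting r = R sin(theta)
    def integrand(theta):
        x = np.sin(theta)
        return 4.0 * np.pi * support * x * h(x) * support * np.cos(theta)

    v, _ = integrate.quad(integrand, 0.0, np.pi / 2.0, epsabs=1e-10, epsrel=1e-9, limit=200)
    return v


def _quadrature_area(support: float, h: Callable) -> float:
    # A = 2 * int 2 pi r ds over one face; parametrize r = R sin(theta) so the
    # rim (vertical tangent of the sqrt(1-x^2) factor) is regular.
    eps = 1e-6

    def dh_dtheta(theta):
        # profiles are even in x, so |sin| keeps the stencil in-domain at 0
        return (h(abs(np.sin(theta + eps))) - h(abs(np.sin(theta - eps)))) / (2.0 * eps)

    def integrand(theta):
        r = support * np.sin(theta)
        dr = support * np.cos(theta)
        return 2.0 * 2.0 * np.pi * r * np.sqrt(dr**2 + dh_dtheta(theta) ** 2)

    a, _ = integrate.quad(integrand, 0.0, np.pi / 2.0, epsabs=1e-10, epsrel=1e-9, limit=200)
    return a


def _scale_factor(spec: ShapeSpec) -> float:
    if spec.target_volume_fl is None:
        return 1.0
    if spec.target_volume_fl <= 0:
        raise ValueError("target_volume_fl must be positive")
    v0 = _quadrature_volume(*_unscaled_profile(spec))
    return (spec.target_volume_fl / v0) ** (1.0 / 3.0)


def support_radius(spec: ShapeSpec) -> float:
    """Maximal radial extent of the (possibly rescaled) shape, um."""
    return _unscaled_profile(spec)[0] * _scale_factor(spec)


def half_thickness(spec: ShapeSpec, r) -> np.ndarray:
    """Half-thickness at radial distance(s) r um from the symmetry axis."""
    support, h = _unscaled_profile(spec)
    scale = _scale_factor(spec)
    x = np.clip(np.asarray(r, dtype=float) / (support * scale), 0.0, 1.0)
    return scale * h(x)


def shape_volume_analytic(spec: ShapeSpec) -> float:
    """Cell volume in fL by adaptive quadrature (closed form for spheres)."""
    if spec.kind == "spherocyte" and spec.target_volume_fl is None:
        return 4.0 / 3.0 * np.pi * spec.R0**3
    if spec.target_volume_fl is not None:
        # rescale is exact by construction
        return float(spec.target_volume_fl)
    support, h = _unscaled_profile(spec)
    return _quadrature_volume(support, h)


def shape_surface_area_analytic(spec: ShapeSpec) -> float:
    """Membrane surface area in um^2 (surface-of-revolution quadrature)."""
    if spec.kind == "spherocyte" and spec.target_volume_fl is None:
        return 4.0 * np.pi * spec.R0**2
    support, h = _unscaled_profile(spec)
    return _quadrature_area(support, h) * _scale_factor(spec) ** 2


def shape_sphericity_analytic(spec: ShapeSpec) -> float:
    v = shape_volume_analytic(spec)
    a = shape_surface_area_analytic(spec)
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a)


def shape_max_thickness(spec: ShapeSpec) -> float:
    """Maximal full thickness 2 h(r) over radial position, um."""
    support, h = _unscaled_profile(spec)
    scale = _scale_factor(spec)
    res = optimize.minimize_scalar(
        lambda x: -2.0 * h(x), bounds=(0.0, 1.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(-res.fun * scale)


def morph_to_sphere(spec: ShapeSpec, s: float) -> ShapeSpec:
    """Blend a discocyte toward the equal-volume sphere.

    Returns a shape whose half-thickness profile is the convex combination of
    the biconcave profile (weight 1-s) and the equal-volume sphere profile
    (weight s) on a common normalized support, isotropically rescaled so the
    volume equals the input shape's volume.  ``s=0`` is the identity;
    ``s=1`` is the sphere of equal volume.
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("sphering index s must lie in [0, 1]")
    if spec.kind == "spherocyte":
        return replace(spec)
    v_in = shape_volume_analytic(spec)
    if s == 0.0:
        return replace(spec)
    return ShapeSpec(
        kind="morph",
        R0=spec.R0,
        profile_coeffs=spec.profile_coeffs,
        s=s,
        target_volume_fl=v_in,
        orientation=spec.orientation,
        center_um=spec.center_um,
    )


def tilt_rotation(tilt_rad: float, azimuth_rad: float, spin_rad: float = 0.0) -> np.ndarray:
    """Rotation matrix tilting the symmetry axis by ``tilt_rad`` toward the
    in-plane direction ``azimuth_rad``, after a spin about the axis."""
    ct, st = np.cos(tilt_rad), np.sin(tilt_rad)
    ca, sa = np.cos(azimuth_rad), np.sin(azimuth_rad)
    cs, ss = np.cos(spin_rad), np.sin(spin_rad)
    spin = np.array([[1, 0, 0], [0, cs, -ss], [0, ss, cs]])  # about z (axis 0)
    tilt = np.array([[ct, st, 0], [-st, ct, 0], [0, 0, 1]])  # z toward y
    azim = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    return azim @ tilt @ spin


def bounding_radius(spec: ShapeSpec) -> float:
    """Radius of a ball (about the cell center) containing the shape."""
    support, h = _unscaled_profile(spec)
    scale = _scale_factor(spec)
    xs = np.linspace(0.0, 1.0, 513)
    rr = np.sqrt((support * xs) ** 2 + h(xs) ** 2)
    return float(rr.max() * scale)


def rasterize_cell(
    spec: ShapeSpec,
    voxel_size: float | tuple[float, float, float],
    cell_ri: float,
    medium_ri: float,
    supersample: int = 3,
    pad_um: float = 0.5,
) -> Tomogram:
    """Sample a cell onto a voxel grid with partial-volume averaging.

    Each voxel's value is ``medium_ri + (cell_ri - medium_ri) * f`` where f
    is the fraction of ``supersample**3`` subvoxel points falling inside the
    rotated shape.  The returned patch fully contains the rotated cell (the
    cell center sits at the patch center; ``spec.center_um`` is not applied).

    Raises
    ------
    ValueError
        If ``supersample < 1``.
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if np.isscalar(voxel_size):
        voxel_size = (float(voxel_size),) * 3
    dz, dy, dx = (float(v) for v in voxel_size)
    import logging

    if min(dz, dy, dx) > support_radius(spec) / 5.0:
        logging.getLogger(__name__).warning(
            "voxel size %s is coarse relative to cell radius %.2f um",
            voxel_size, support_radius(spec),
        )

    rb = bounding_radius(spec) + pad_um
    shape = (
        int(np.ceil(2 * rb / dz)),
        int(np.ceil(2 * rb / dy)),
        int(np.ceil(2 * rb / dx)),
    )
    values = np.zeros(shape, dtype=np.float64)

    support, h = _unscaled_profile(spec)
    scale = _scale_factor(spec)
    rsup = support * scale
    rot_inv = spec.orientation.T  # lab -> cell frame

    # voxel-center coordinates relative to the patch center
    axes = [
        (np.arange(n) + 0.5) * d - n * d / 2.0
        for n, d in zip(shape, (dz, dy, dx))
    ]
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5

    zc = axes[0][:, None, None]
    yc = axes[1][None, :, None]
    xc = axes[2][None, None, :]
    for oz in offsets:
        for oy in offsets:
            for ox in offsets:
                z = zc + oz * dz
                y = yc + oy * dy
                x = xc + ox * dx
                # rotate into the cell frame
                pz = rot_inv[0, 0] * z + rot_inv[0, 1] * y + rot_inv[0, 2] * x
                py = rot_inv[1, 0] * z + rot_inv[1, 1] * y + rot_inv[1, 2] * x
                px = rot_inv[2, 0] * z + rot_inv[2, 1] * y + rot_inv[2, 2] * x
                r = np.sqrt(py**2 + px**2)
                xn = np.clip(r / rsup, 0.0, 1.0)
                inside = (r <= rsup) & (np.abs(pz) <= scale * h(xn))
                values += inside
    values /= supersample**3
    values = medium_ri + (cell_ri - medium_ri) * values
    return Tomogram(values=values.astype(np.float32), voxel_size=(dz, dy, dx), medium_ri=medium_ri)
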