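"""Level-set primitives shared by the two- and four-phase solvers.

The level-set function ``phi`` is a signed scalar field on the pixel grid;
its zero contour is the evolving segmentation boundary and its sign
partitions the image into phases.  Everything here is deliberately
re-initialization free: ``phi`` starts as a binary step of height ``rho``
(not a signed distance function) and is kept regular by Gaussian smoothing
each iteration instead of PDE-based redistancing.

Conventions: grids are row-major float64 arrays, pixel spacing 1, gradients
by central differences (one-sided at borders), all Gaussian convolutions use
a truncated, unit-sum kernel with reflective boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "KernelSpec",
    "heaviside_eps",
    "dirac_eps",
    "gaussian_smooth",
    "edge_indicator",
    "curvature_term",
    "init_levelset",
    "rect_region",
    "circle_region",
    "regularize",
    "characteristic_2p",
    "characteristic_4p",
]

#: floor applied to |grad phi| before division in the curvature term
GRAD_FLOOR = 1e-8


def _check_image(a: np.ndarray, name: str = "image") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass(frozen=True)
class KernelSpec:
    """Truncated discrete Gaussian kernel: std ``sigma`` (pixels), cut at
    ``truncation_radius`` pixels and renormalized to unit sum."""

    sigma: float
    truncation_radius: int = field(default=0)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        min_radius = math.ceil(3 * self.sigma)
        radius = self.truncation_radius or math.ceil(3 * self.sigma) + 1
        if radius < min_radius:
            raise ValueError(
                f"truncation_radius must be >= ceil(3*sigma) = {min_radius}"
            )
        object.__setattr__(self, "truncation_radius", int(radius))

    def kernel_1d(self) -> np.ndarray:
        """Normalized 1-D kernel of length ``2*truncation_radius + 1``."""
        x = np.arange(-self.truncation_radius, self.truncation_radius + 1)
        k = np.exp(-0.5 * (x / self.sigma) ** 2)
        return k / k.sum()

    def kernel_2d(self) -> np.ndarray:
        k = self.kernel_1d()
        return np.outer(k, k)


def gaussian_smooth(a: np.ndarray, kernel: KernelSpec | float) -> np.ndarray:
    """Convolve with the (separable) truncated Gaussian, reflective borders."""
    if not isinstance(kernel, KernelSpec):
        kernel = KernelSpec(float(kernel))
    a = np.asarray(a, dtype=float)
    return ndimage.gaussian_filter(
        a, kernel.sigma, mode="reflect", radius=kernel.truncation_radius
    )


def heaviside_eps(phi, eps: float):
    """Smoothed Heaviside H_eps(phi) = 1/2 + arctan(phi/eps)/pi, in (0, 1).

    ``eps`` sets the width of the transition band around the zero contour;
    eps -> 0 recovers the ideal unit step.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    return 0.5 + np.arctan(np.asarray(phi, dtype=float) / eps) / np.pi


def dirac_eps(phi, eps: float):
    """Smoothed Dirac delta_eps(phi) = eps / (pi (phi^2 + eps^2)).

    The exact derivative of :func:`heaviside_eps`; even in phi, maximal at
    the zero contour, unit integral over the real line.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    phi = np.asarray(phi, dtype=float)
    return eps / (np.pi * (phi**2 + eps**2))


def edge_indicator(image: np.ndarray, kernel: KernelSpec | float) -> np.ndarray:
    """Edge indicator g = 1 / (1 + |grad(K_sigma * I)|^2), in (0, 1].

    Equals 1 over flat regions of the smoothed image and drops towards 0 at
    strong edges; weights the length/area terms of the contour energy.
    """
    image = _check_image(image)
    smoothed = gaussian_smooth(image, kernel)
    gy, gx = np.gradient(smoothed)
    return 1.0 / (1.0 + gx**2 + gy**2)


def curvature_term(phi: np.ndarray, g: np.ndarray) -> np.ndarray:
    """div(g * grad(phi) / |grad(phi)|) by central differences.

    |grad phi| is floored at ``GRAD_FLOOR`` so the normal field stays finite
    where phi is locally flat.
    """
    phi = _check_image(phi, "phi")
    g = _check_image(g, "g")
    if phi.shape != g.shape:
        raise ValueError("phi and g must have the same shape")
    py, px = np.gradient(phi)
    norm = np.sqrt(px**2 + py**2)
    norm = np.maximum(norm, GRAD_FLOOR)
    nx = g * px / norm
    ny = g * py / norm
    return np.gradient(ny, axis=0) + np.gradient(nx, axis=1)


def rect_region(shape: tuple[int, int], top: int, left: int,
                bottom: int, right: int) -> np.ndarray:
    """Boolean mask of the rectangle [top, bottom) x [left, right)."""
    h, w = shape
    if not (0 <= top < bottom <= h and 0 <= left < right <= w):
        raise ValueError("rectangle out of bounds or empty")
    m = np.zeros(shape, dtype=bool)
    m[top:bottom, left:right] = True
    return m


def circle_region(shape: tuple[int, int], row: float, col: float,
                  radius: float) -> np.ndarray:
    """Boolean mask of the disk of given center (row, col) and radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
    if not m.any():
        raise ValueError("circle does not cover any pixel of the grid")
    if not m[1:-1, 1:-1].any():
        raise ValueError("circle interior lies outside the grid")
    return m


def init_levelset(shape: tuple[int, int], region: np.ndarray,
                  rho: float) -> np.ndarray:
    """Ternary initial level set: -rho strictly inside ``region``, 0 on its
    boundary ring, +rho outside.

    ``region`` is a boolean mask of the seeded area (boundary included).
    Deliberately *not* a signed distance function: the Gaussian
    regularization applied each iteration makes redistancing unnecessary.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    region = np.asarray(region, dtype=bool)
    if region.shape != tuple(shape):
        raise ValueError("region mask shape does not match grid shape")
    if not region.any():
        raise ValueError("initial region is empty")
    interior = ndimage.binary_erosion(region, border_value=0)
    phi = np.full(shape, float(rho))
    phi[region] = 0.0
    phi[interior] = -float(rho)
    return phi


def regularize(phi: np.ndarray, chi: float) -> np.ndarray:
    """Gaussian regularization of phi (std ``chi``), replacing signed
    distance re-initialization; unit-sum kernel so constants are preserved."""
    if chi <= 0:
        raise ValueError("chi must be positive")
    return gaussian_smooth(np.asarray(phi, dtype=float), KernelSpec(chi))


def characteristic_2p(phi: np.ndarray, eps: float):
    """Soft phase memberships (M1, M2) = (H_eps(phi), 1 - H_eps(phi))."""
    m1 = heaviside_eps(phi, eps)
    return m1, 1.0 - m1


def characteristic_4p(phi1: np.ndarray, phi2: np.ndarray, eps: float):
    """Four-phase memberships from two level sets.

    M1 = H(phi1)H(phi2), M2 = H(phi1)(1-H(phi2)),
    M3 = (1-H(phi1))H(phi2), M4 = (1-H(phi1))(1-H(phi2)); they sum to 1.
    """
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    if phi1.shape != phi2.shape:
        raise ValueError("phi1 and phi2 must share a shape")
    h1 = heaviside_eps(phi1, eps)
    h2 = heaviside_eps(phi2, eps)
    return h1 * h2, h1 * (1.0 - h2), (1.0 - h1) * h2, (1.0 - h1) * (1.0 - h2)
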