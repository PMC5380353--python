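"""Region statistics, bias-field estimation, fitted images and SPF forces.

The observed image is modelled as I = b * J + n with a smooth multiplicative
bias field b and a piecewise-constant true image J.  Each phase i carries a
global mean m_i (plain average under the soft membership M_i) and a local
mean c_i (Gaussian-kernel weighted, bias-aware).  From these two families of
means the solver builds two reconstructions of the image:

* the bias local fitted image   I_bLFI = b * sum_i c_i M_i
* the global fitted image       I_GFI  =     sum_i m_i M_i

and turns the residuals I - I_bLFI and I - I_GFI into signed pressure force
(SPF) fields normalized to [-1, 1], which set the direction (expand or
shrink) of the contour motion while keeping the flow bounded.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np

from .core import KernelSpec, gaussian_smooth

__all__ = [
    "BIAS_FLOOR",
    "FittedImages",
    "SPFField",
    "global_means",
    "local_means",
    "bias_field",
    "fitted_images",
    "fitted_images_2p",
    "fitted_images_4p",
    "lspf",
    "gspf",
]

#: positive floor applied to the bias field before any division by b or b^2
BIAS_FLOOR = 1e-3

#: a phase whose membership mass falls below this is treated as empty
_DEGENERATE_MASS = 1e-12


class FittedImages(NamedTuple):
    """Per-pixel reconstructions of the image from the phase means."""

    bias_local: np.ndarray  # b * sum(c_i M_i)
    global_: np.ndarray  # sum(m_i M_i)


class SPFField(NamedTuple):
    """An SPF array in [-1, 1] plus a flag set when the residual vanished
    identically (a converged / degenerate configuration)."""

    values: np.ndarray
    vanished: bool


def global_means(image: np.ndarray, M: Sequence[np.ndarray]) -> list[float]:
    """Global intensity mean of each phase, m_i = sum(I*M_i) / sum(M_i).

    An (almost) empty phase falls back to the overall image mean with a
    warning, so downstream flow terms stay finite during early iterations.
    """
    image = np.asarray(image, dtype=float)
    out = []
    for i, Mi in enumerate(M):
        mass = float(np.sum(Mi))
        if mass < _DEGENERATE_MASS:
            warnings.warn(f"phase {i + 1} is empty; using the global image mean")
            out.append(float(image.mean()))
        else:
            out.append(float(np.sum(image * Mi) / mass))
    return out


def local_means(
    image: np.ndarray,
    bias: np.ndarray,
    M: Sequence[np.ndarray],
    kernel: KernelSpec | float,
    fallback: Sequence[float] | None = None,
) -> list[float]:
    """Kernel-weighted, bias-aware mean of each phase:

        c_i = sum( (K * b) I M_i ) / sum( (K * b^2) M_i )

    (the kernel smooths the bias factors, not the image).  With b = 1 this
    reduces exactly to the global means for any kernel width.  A vanishing
    denominator (e.g. when b is identically 0) falls back to ``fallback``
    (typically the global means) or the image mean.
    """
    image = np.asarray(image, dtype=float)
    bias = np.asarray(bias, dtype=float)
    num_field = gaussian_smooth(bias, kernel) * image
    den_field = gaussian_smooth(bias * bias, kernel)
    out = []
    for i, Mi in enumerate(M):
        den = float(np.sum(den_field * Mi))
        if den < _DEGENERATE_MASS:
            fb = float(fallback[i]) if fallback is not None else float(image.mean())
            out.append(fb)
        else:
            out.append(float(np.sum(num_field * Mi) / den))
    return out


def bias_field(
    image: np.ndarray,
    local: Sequence[float],
    M: Sequence[np.ndarray],
    kernel: KernelSpec | float,
    floor: float = BIAS_FLOOR,
) -> np.ndarray:
    """Multiplicative bias field estimate

        b = sum_i K * (I c_i M_i)  /  sum_i K * (c_i^2 M_i)

    smooth by construction (a ratio of Gaussian-convolved fields) and
    clamped below by ``floor`` so that divisions by b and b^2 are safe.
    """
    image = np.asarray(image, dtype=float)
    if all(abs(c) < _DEGENERATE_MASS for c in local):
        warnings.warn("all local means are zero; bias field set to 1")
        return np.ones_like(image)
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    for ci, Mi in zip(local, M):
        num += gaussian_smooth(image * (ci * np.asarray(Mi, dtype=float)), kernel)
        den += gaussian_smooth((ci * ci) * np.asarray(Mi, dtype=float), kernel)
    b = num / np.maximum(den, _DEGENERATE_MASS)
    return np.maximum(b, floor)


def fitted_images(
    bias: np.ndarray,
    local: Sequence[float],
    global_: Sequence[float],
    M: Sequence[np.ndarray],
) -> FittedImages:
    """Build I_bLFI = b * sum(c_i M_i) and I_GFI = sum(m_i M_i)."""
    local_part = np.zeros_like(np.asarray(M[0], dtype=float))
    global_part = np.zeros_like(local_part)
    for ci, mi, Mi in zip(local, global_, M):
        Mi = np.asarray(Mi, dtype=float)
        local_part += ci * Mi
        global_part += mi * Mi
    return FittedImages(np.asarray(bias, dtype=float) * local_part, global_part)


def fitted_images_2p(bias, local, global_, M) -> FittedImages:
    """Two-phase fitted images (one level set, memberships M1, M2)."""
    if len(M) != 2:
        raise ValueError("two-phase fitting expects 2 membership fields")
    return fitted_images(bias, local, global_, M)


def fitted_images_4p(bias, local, global_, M) -> FittedImages:
    """Four-phase fitted images (two level sets, memberships M1..M4)."""
    if len(M) != 4:
        raise ValueError("four-phase fitting expects 4 membership fields")
    return fitted_images(bias, local, global_, M)


def _spf(image: np.ndarray, fitted: np.ndarray) -> SPFField:
    image = np.asarray(image, dtype=float)
    diff = image - np.asarray(fitted, dtype=float)
    peak = float(np.max(np.abs(diff)))
    if peak == 0.0:
        return SPFField(np.zeros_like(diff), True)
    spf = diff / peak
    spf[image == 0] = 0.0  # zero-intensity pixels exert no pressure
    return SPFField(spf, False)


def lspf(image: np.ndarray, fitted: FittedImages) -> SPFField:
    """Local SPF: (I - I_bLFI) / max|I - I_bLFI|, zero where I = 0.

    Concentrated near region boundaries; it is the term that pulls the
    contour onto intensity-inhomogeneous objects.
    """
    return _spf(image, fitted.bias_local)


def gspf(image: np.ndarray, fitted: FittedImages) -> SPFField:
    """Global SPF: (I - I_GFI) / max|I - I_GFI|, zero where I = 0.

    Signed by which side of the two global means a pixel lies on; it drives
    fast convergence over homogeneous regions.
    """
    return _spf(image, fitted.global_)
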