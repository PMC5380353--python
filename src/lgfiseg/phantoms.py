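"""Seeded synthetic phantoms with ground truth for labels and bias field.

All phantoms realize the multiplicative image model I = b * J + n: a
piecewise-constant true image J (one intensity level per labelled region),
a smooth positive bias field b normalized to unit mean, and additive
Gaussian noise n.  Intensities follow the 8-bit 0-255 convention and the
final image is clipped to that range, which is the one departure from the
unbounded model.  Regeneration with the same seed is bit-identical.

Three families are provided:

* :func:`make_two_region` — one object on a background, with a controllable
  smooth intensity ramp inside the object (from perfectly homogeneous to
  strongly inhomogeneous).
* :func:`make_combo` — the five object/background homogeneity scenarios,
  including a nested inhomogeneous region inside an inhomogeneous object.
* :func:`make_multiregion` — 3- or 4-class piecewise-constant images
  (including a concentric brain-like layout) under a smooth multiplicative
  bias field, for the four-phase solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .core import circle_region, rect_region

__all__ = [
    "Phantom",
    "COMBO_CASES",
    "make_two_region",
    "make_combo",
    "make_multiregion",
    "smooth_bias",
]

DEFAULT_SHAPE = (250, 250)  # matches the working image size of the method

COMBO_CASES = (
    "hom-obj/hom-bg",
    "inhom-obj/hom-bg",
    "hom-obj/inhom-bg",
    "inhom-obj/inhom-bg",
    "nested-inhom",
)


@dataclass(frozen=True)
class Phantom:
    """A generated image with its ground truth."""

    image: np.ndarray
    labels: np.ndarray  # integer map, 0 = background
    true_bias: np.ndarray  # smooth positive field, unit mean
    noise_sigma: float
    seed: int
    spec: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share a shape")
        if np.any(self.true_bias <= 0):
            raise ValueError("true bias field must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def object_mask(self) -> np.ndarray:
        """Union of all non-background regions."""
        return self.labels > 0


def _check_level(level: float, name: str) -> float:
    if not 0 <= level <= 255:
        raise ValueError(f"{name} must lie in [0, 255], got {level}")
    return float(level)


def _resolve_geometry(shape, geometry) -> np.ndarray:
    """Accept a boolean mask or a ('circle', r, c, radius) / ('rect', ...) tuple."""
    if geometry is None:
        r = min(shape) / 4.5
        return circle_region(shape, (shape[0] - 1) / 2, (shape[1] - 1) / 2, r)
    if isinstance(geometry, np.ndarray):
        if geometry.shape != tuple(shape):
            raise ValueError("geometry mask shape mismatch")
        return geometry.astype(bool)
    kind, *args = geometry
    if kind == "circle":
        return circle_region(shape, *args)
    if kind == "rect":
        return rect_region(shape, *args)
    raise ValueError(f"unknown geometry kind {kind!r}")


def _ramp(shape, mask: np.ndarray, direction=(0.3, 1.0)) -> np.ndarray:
    """Smooth in-object ramp in [0, 1], attaining both extremes on ``mask``."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    t = direction[0] * yy + direction[1] * xx
    tm = t[mask]
    lo, hi = tm.min(), tm.max()
    if hi == lo:
        return np.zeros(shape)
    return np.clip((t - lo) / (hi - lo), 0.0, 1.0)


def smooth_bias(
    shape: tuple[int, int],
    kind: str = "gaussian",
    strength: float = 0.3,
    center: tuple[float, float] | None = None,
    width: float | None = None,
    direction: tuple[float, float] = (0.5, 1.0),
) -> np.ndarray:
    """Smooth positive bias-field profile normalized to unit mean.

    ``kind='gaussian'`` is a broad bump (std ``width``, default 60% of the
    smaller image side) of relative amplitude ``strength`` centered at
    ``center``; ``kind='linear'`` is a planar ramp of total relative span
    ``strength`` along ``direction``.
    """
    h, w = shape
    if strength < 0 or strength >= 1:
        raise ValueError("strength must lie in [0, 1)")
    yy, xx = np.mgrid[0:h, 0:w]
    if kind == "gaussian":
        cy, cx = center if center is not None else ((h - 1) / 2.8, (w - 1) / 1.8)
        s = width if width is not None else 0.6 * min(h, w)
        b = 1.0 + strength * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    elif kind == "linear":
        t = direction[0] * yy + direction[1] * xx
        t = (t - t.min()) / max(t.max() - t.min(), 1.0)
        b = 1.0 + strength * (t - 0.5)
    elif kind == "none":
        b = np.ones(shape)
    else:
        raise ValueError(f"unknown bias kind {kind!r}")
    return b / b.mean()


def _assemble(J, labels, bias, noise_sigma, seed, spec) -> Phantom:
    rng = np.random.default_rng(seed)
    image = bias * J
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=J.shape)
    image = np.clip(image, 0.0, 255.0)
    return Phantom(
        image=image,
        labels=labels.astype(np.int32),
        true_bias=bias,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
        spec=dict(spec),
    )


def make_two_region(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    object_geometry=None,
    fg_level: float = 170.0,
    bg_level: float = 85.0,
    inhomogeneity_strength: float = 0.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
    bias_spec: Mapping[str, Any] | None = None,
) -> Phantom:
    """One object on a homogeneous background.

    ``inhomogeneity_strength`` in [0, 1] is the relative amplitude of a
    smooth intensity ramp inside the object: 0 gives a piecewise-constant
    two-value image, s makes the object intensity span s * |fg - bg|, so at
    1 the dim end of the object touches the background level.
    ``bias_spec`` (forwarded to :func:`smooth_bias`) multiplies the whole
    scene by a smooth unit-mean gain field.
    """
    fg = _check_level(fg_level, "fg_level")
    bg = _check_level(bg_level, "bg_level")
    s = float(inhomogeneity_strength)
    if not 0 <= s <= 1:
        raise ValueError("inhomogeneity_strength must lie in [0, 1]")
    mask = _resolve_geometry(shape, object_geometry)
    J = np.full(shape, bg)
    ramp = _ramp(shape, mask)
    J[mask] = (fg - s * (fg - bg) * ramp)[mask]
    labels = mask.astype(np.int32)
    bias = smooth_bias(shape, **bias_spec) if bias_spec else np.ones(shape)
    return _assemble(
        J, labels, bias, noise_sigma, seed,
        {"family": "two_region", "fg": fg, "bg": bg, "strength": s,
         "bias_spec": dict(bias_spec) if bias_spec else None},
    )


def make_combo(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    case: str = "hom-obj/hom-bg",
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> Phantom:
    """The five object/background homogeneity scenarios.

    Cases (``COMBO_CASES``): homogeneous object on homogeneous background;
    inhomogeneous object on homogeneous background; homogeneous object on
    inhomogeneous background; both inhomogeneous; and a homogeneous
    background holding two inhomogeneous objects, one of which contains an
    extra, distinctly-labelled inhomogeneous region nested within it.
    """
    if case not in COMBO_CASES:
        raise ValueError(f"unknown case {case!r}; choose one of {COMBO_CASES}")
    h, w = shape
    bg, fg = 85.0, 170.0
    spec = {"family": "combo", "case": case}

    if case == "nested-inhom":
        r = min(h, w) * 0.16
        obj_a = circle_region(shape, h * 0.5, w * 0.28, r)
        obj_b = circle_region(shape, h * 0.5, w * 0.72, r * 1.25)
        nested = circle_region(shape, h * 0.5, w * 0.72, r * 0.55)
        labels = np.zeros(shape, dtype=np.int32)
        labels[obj_a] = 1
        labels[obj_b] = 2
        labels[nested] = 3
        J = np.full(shape, bg)
        J[obj_a] = (150.0 + 50.0 * _ramp(shape, obj_a))[obj_a]
        J[obj_b] = (150.0 + 50.0 * _ramp(shape, obj_b, (1.0, -0.4)))[obj_b]
        J[nested] = (215.0 + 40.0 * _ramp(shape, nested))[nested]
        return _assemble(J, labels, np.ones(shape), noise_sigma, seed, spec)

    obj = _resolve_geometry(shape, None)
    labels = obj.astype(np.int32)
    J = np.full(shape, bg)
    if case in ("inhom-obj/hom-bg", "inhom-obj/inhom-bg"):
        J[obj] = (fg - 0.7 * (fg - bg) * _ramp(shape, obj))[obj]
    else:
        J[obj] = fg
    bias = np.ones(shape)
    if case in ("hom-obj/inhom-bg", "inhom-obj/inhom-bg"):
        # background inhomogeneity: a smooth multiplicative field that
        # tapers to 1 near the object, so the field stays smooth everywhere
        # and the object keeps its own intensity profile
        from scipy import ndimage

        ramp = smooth_bias(shape, "linear", strength=0.35) - 1.0
        dist = ndimage.distance_transform_edt(~obj)
        taper = 1.0 - np.exp(-(dist**2) / (2 * 15.0**2))
        bias = 1.0 + ramp * taper
        bias = bias / bias.mean()
    return _assemble(J, labels, bias, noise_sigma, seed, spec)


def _multiregion_labels(shape, n_classes: int, geometry: str) -> np.ndarray:
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    if geometry == "concentric":
        # brain-like nested ellipses: outer ring, middle ring, core
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2
        rr = np.sqrt(((yy - cy) / (0.40 * h)) ** 2 + ((xx - cx) / (0.34 * w)) ** 2)
        radii = np.linspace(1.0, 0.35, n_classes - 1)
        for i, r in enumerate(radii, start=1):
            labels[rr <= r] = i
    elif geometry == "disks":
        r = min(h, w) * 0.16
        centers = [
            (h * 0.30, w * 0.30),
            (h * 0.30, w * 0.70),
            (h * 0.72, w * 0.50),
        ]
        for i in range(1, n_classes):
            cy, cx = centers[i - 1]
            labels[circle_region(shape, cy, cx, r)] = i
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    return labels


def make_multiregion(
    shape: tuple[int, int] = DEFAULT_SHAPE,
    n_regions: int = 4,
    level_list: Sequence[float] = (10.0, 80.0, 150.0, 220.0),
    bias_spec: Mapping[str, Any] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    geometry: str = "disks",
) -> Phantom:
    """Piecewise-constant multi-class phantom under a smooth bias field.

    ``n_regions`` counts the intensity classes including the background;
    ``level_list[k]`` is the true level of label k (label 0 = background).
    ``bias_spec`` is forwarded to :func:`smooth_bias` (``None`` means unit
    bias); ``geometry`` is 'disks' (disjoint objects on a background) or
    'concentric' (brain-like nested ellipses).
    """
    if n_regions not in (3, 4):
        raise ValueError("n_regions must be 3 or 4")
    if len(level_list) != n_regions:
        raise ValueError("level_list length must equal n_regions")
    levels = [_check_level(v, f"level_list[{i}]") for i, v in enumerate(level_list)]
    labels = _multiregion_labels(shape, n_regions, geometry)
    J = np.asarray(levels, dtype=float)[labels]
    bias = smooth_bias(shape, **bias_spec) if bias_spec else np.ones(shape)
    return _assemble(
        J, labels, bias, noise_sigma, seed,
        {"family": "multiregion", "n_regions": n_regions, "levels": levels,
         "geometry": geometry, "bias_spec": dict(bias_spec) if bias_spec else None},
    )
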