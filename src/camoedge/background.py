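"""Leaf-litter background scenes.

A scene is built by sequentially stamping randomly oriented leaf-shaped
masks (a pointed-ellipse / vesica silhouette) at random positions, each
filled with a colour drawn from the constrained LAB population.  Later
stamps occlude earlier ones.  When shadows are on, each leaf first casts a
flat shadow to its left — the leaf silhouette translated leftward by a
half-normally distributed width — darkening whatever is already painted
there by 70% in linear intensity, as if the scene were lit from the
viewer's upper right.

Sizes and the pixel↔degree scale follow the search-display geometry:
20 px = 0.62° of visual angle, leaf lengths from a positively skewed
distribution with hard minimum 20 px, mode 21 px and 95th percentile
46 px, widths ≈ 20% of length.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import optimize, stats

from .colors import ColorPopulation, _srgb_decode, _srgb_encode, lab_to_display

__all__ = [
    "DEG_PER_PX",
    "PX_PER_DEG",
    "px_to_deg",
    "deg_to_px",
    "LeafShapeParams",
    "ShadowSpec",
    "SceneCanvas",
    "sample_leaf_length",
    "sample_shadow_widths",
    "leaf_mask",
    "render_background",
    "save_scene",
    "load_scene",
]

#: Experiment 1–2 display scale: 20 px subtend 0.62 degrees of visual angle.
DEG_PER_PX = 0.62 / 20.0
PX_PER_DEG = 20.0 / 0.62


def px_to_deg(px: float, deg_per_px: float = DEG_PER_PX) -> float:
    """Convert pixels to degrees of visual angle (small-angle linear scale)."""
    return px * deg_per_px


def deg_to_px(deg: float, deg_per_px: float = DEG_PER_PX) -> float:
    return deg / deg_per_px


@dataclass(frozen=True)
class LeafShapeParams:
    """Leaf silhouette size law: shifted-gamma lengths, proportional widths.

    Lengths are ``min_len + Gamma(k, theta)`` with (k, theta) solved so the
    mode sits at ``mode_len`` and the 95th percentile at ``p95_len``; the
    gamma family is the simplest positively skewed law with enough freedom
    to pin all three quantities.  Width is ``width_fraction`` of length.
    """

    min_len: float = 20.0
    mode_len: float = 21.0
    p95_len: float = 46.0
    width_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (self.min_len <= self.mode_len < self.p95_len):
            raise ValueError("require min_len <= mode_len < p95_len")
        if not 0.0 < self.width_fraction < 1.0:
            raise ValueError("width_fraction must lie in (0, 1)")

    @property
    def gamma_params(self) -> tuple[float, float]:
        return _solve_gamma(self.min_len, self.mode_len, self.p95_len)


@functools.lru_cache(maxsize=None)
def _solve_gamma(min_len: float, mode_len: float, p95_len: float) -> tuple[float, float]:
    """Solve shape k and scale theta of the shifted gamma length law.

    Mode constraint (k−1)·theta = mode−min ties theta to k; the 95th
    percentile constraint is then a 1-D root find in k.
    """
    mode_excess = mode_len - min_len
    p95_excess = p95_len - min_len

    def p95_gap(k: float) -> float:
        theta = mode_excess / (k - 1.0)
        return stats.gamma.ppf(0.95, k, scale=theta) - p95_excess

    k = optimize.brentq(p95_gap, 1.001, 50.0, xtol=1e-12)
    return k, mode_excess / (k - 1.0)


def sample_leaf_length(
    params: LeafShapeParams, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Draw leaf lengths (px) from the calibrated positively skewed law."""
    k, theta = params.gamma_params
    return params.min_len + rng.gamma(k, theta, size)


@dataclass(frozen=True)
class ShadowSpec:
    """Flat leftward leaf shadows.

    Widths are half-normal, ``|Normal(width_mean, width_sd)|`` px; the
    shadow removes ``darkening`` of the linear intensity (0.70 leaves 30%
    of the light).
    """

    width_mean: float = 2.4
    width_sd: float = 3.0
    darkening: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.darkening <= 1.0:
            raise ValueError("darkening must lie in [0, 1]")
        if self.width_sd <= 0:
            raise ValueError("width_sd must be positive")


def sample_shadow_widths(
    spec: ShadowSpec, rng: np.random.Generator, size=None
) -> np.ndarray | float:
    """Draw shadow widths (px) as the absolute value of a normal deviate."""
    return np.abs(rng.normal(spec.width_mean, spec.width_sd, size))


@dataclass
class SceneCanvas:
    """A linear-RGB raster scene with a pixel↔degree scale.

    ``pixels`` is (height, width, 3) float, linear light in [0, 1].
    """

    pixels: np.ndarray
    deg_per_px: float = DEG_PER_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (h, w, 3)")
        if self.deg_per_px <= 0:
            raise ValueError("deg_per_px must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def px_per_deg(self) -> float:
        return 1.0 / self.deg_per_px

    @classmethod
    def uniform(
        cls, width: int, height: int, value: float = 0.5, deg_per_px: float = DEG_PER_PX
    ) -> "SceneCanvas":
        return cls(np.full((height, width, 3), value, dtype=float), deg_per_px)

    def copy(self) -> "SceneCanvas":
        return SceneCanvas(self.pixels.copy(), self.deg_per_px)


def leaf_mask(
    length: float, width: float, orientation: float
) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterise a pointed-ellipse (vesica) leaf silhouette.

    Returns a boolean mask cropped to its tight bounding box and the
    (row, col) offset of the mask origin relative to the leaf centre.  The
    silhouette is the intersection of two discs, giving a convex leaf shape
    with pointed tips whose oriented bounding box is length × width.
    """
    if length < 2 or width < 1:
        raise ValueError("degenerate leaf size")
    # circle geometry: tips at +-length/2 on the major axis, width across
    c = (length**2 - width**2) / (4.0 * width)
    R = c + width / 2.0
    half = int(np.ceil(length / 2.0)) + 1
    rows = np.arange(-half, half + 1, dtype=float)[:, None]
    cols = np.arange(-half, half + 1, dtype=float)[None, :]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = cols * ct + rows * st  # along major axis
    v = -cols * st + rows * ct
    mask = (np.hypot(u, v - c) <= R) & (np.hypot(u, v + c) <= R)
    if not mask.any():  # sub-pixel sliver: keep the centre pixel
        mask[half, half] = True
    rr = np.flatnonzero(mask.any(axis=1))
    cc = np.flatnonzero(mask.any(axis=0))
    cropped = mask[rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1]
    return cropped, (int(rr[0] - half), int(cc[0] - half))


def _stamp(pixels: np.ndarray, mask: np.ndarray, top: int, left: int, fn) -> None:
    """Apply ``fn`` to the pixels under ``mask`` placed at (top, left), clipped."""
    h, w = pixels.shape[:2]
    mh, mw = mask.shape
    r0, c0 = max(top, 0), max(left, 0)
    r1, c1 = min(top + mh, h), min(left + mw, w)
    if r0 >= r1 or c0 >= c1:
        return
    sub = mask[r0 - top : r1 - top, c0 - left : c1 - left]
    region = pixels[r0:r1, c0:c1]
    region[sub] = fn(region[sub])


def render_background(
    canvas: SceneCanvas,
    n_leaves: int,
    pop: ColorPopulation,
    rng: np.random.Generator,
    *,
    shadows: bool = False,
    shadow_spec: ShadowSpec = ShadowSpec(),
    leaf_params: LeafShapeParams = LeafShapeParams(),
) -> SceneCanvas:
    """Stamp ``n_leaves`` coloured leaves (with optional shadows) onto a copy.

    Leaves are placed sequentially at uniform random positions with uniform
    random orientation; each later leaf occludes whatever lies beneath it.
    A leaf's shadow is stamped immediately before the leaf itself: the leaf
    silhouette shifted left by the sampled width, minus the leaf, with the
    linear intensity there multiplied by (1 − darkening).
    """
    if n_leaves < 0:
        raise ValueError("n_leaves must be non-negative")
    out = canvas.copy()
    px = out.pixels
    h, w = out.height, out.width
    keep_light = 1.0 - shadow_spec.darkening
    for _ in range(n_leaves):
        length = float(sample_leaf_length(leaf_params, rng))
        width = max(1.0, leaf_params.width_fraction * length)
        orientation = rng.uniform(0.0, np.pi)
        mask, (dr, dc) = leaf_mask(length, width, orientation)
        row = int(rng.integers(0, h))
        col = int(rng.integers(0, w))
        top, left = row + dr, col + dc
        if shadows:
            shift = int(round(float(sample_shadow_widths(shadow_spec, rng))))
            if shift > 0:
                shadow = np.zeros(
                    (mask.shape[0], mask.shape[1] + shift), dtype=bool
                )
                shadow[:, :-shift][mask] = True  # leaf moved left
                shadow[:, shift:][mask] = False  # minus the leaf itself
                _stamp(px, shadow, top, left - shift, lambda v: v * keep_light)
        rgb, _ = lab_to_display(pop[int(rng.integers(0, len(pop)))])
        _stamp(px, mask, top, left, lambda v: rgb)
    return out


def save_scene(canvas: SceneCanvas, path, meta: dict | None = None) -> None:
    """Write the scene as 8-bit sRGB PNG plus a JSON parameter sidecar."""
    encoded = np.round(_srgb_encode(canvas.pixels) * 255.0).astype(np.uint8)
    Image.fromarray(encoded, mode="RGB").save(path)
    sidecar = dict(meta or {})
    sidecar.setdefault("deg_per_px", canvas.deg_per_px)
    sidecar.setdefault("shape", [canvas.height, canvas.width])
    with open(f"{path}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_scene(path, deg_per_px: float = DEG_PER_PX) -> SceneCanvas:
    """Read an 8-bit sRGB PNG back into a linear-RGB canvas."""
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=float) / 255.0
    return SceneCanvas(_srgb_decode(arr), deg_per_px)
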