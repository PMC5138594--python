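"""Disruptive camouflage texture: band-pass noise, posterisation, edge
enhancement, and target compositing.

The camouflage pattern starts as white noise filtered in the Fourier domain
by a radial Gaussian amplitude profile, giving an isotropic band-pass
texture whose dominant patch scale matches the modal leaf length (≈ 21 px).
Posterising at the median yields a two-colour patch map; edge enhancement
then reshapes the lightness (CIE L) profile near patch boundaries.

Edge enhancement is a two-parameter model: *offset*, the change in L added
to light patches and/or subtracted from dark patches at the boundary, and
*width*, the distance in px over which L ramps linearly back to the patch
colour.  Four variants are distinguished besides the unenhanced control:

``both``
    light patches ramp up to L+offset AND dark patches down to L−offset,
    so the boundary carries the highest contrast in the pattern;
``no_low``
    only the light gradient (light patches ramp up; dark patches flat);
``no_high``
    only the dark gradient (dark patches ramp down; light patches flat);
``square``
    flat bands of L±offset within ``width`` px of the boundary, no ramp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .colors import ColorPopulation, LabColor, PatchColorRule, sample_patch_colors
from .background import SceneCanvas
from .colors import lab_image_to_display

__all__ = [
    "FilterSpec",
    "PatchMap",
    "EdgeProfile",
    "TargetMask",
    "StimulusImage",
    "DegenerateTextureError",
    "PlacementError",
    "bandpass_noise",
    "posterise",
    "boundary_distance",
    "apply_edge_enhancement",
    "median_patch_breadth",
    "snake_mask",
    "make_target",
    "compose_stimulus",
    "clear_central_band",
]

EDGE_VARIANTS = ("none", "both", "no_low", "no_high", "square")


class DegenerateTextureError(ValueError):
    """Raised when a texture carries no structure to posterise."""


class PlacementError(ValueError):
    """Raised when a target cannot be placed inside its display cell."""


@dataclass(frozen=True)
class FilterSpec:
    """Radial Gaussian amplitude filter for the Fourier-domain noise shaping.

    ``mu`` (default 0.048) is the spectral centre in normalised frequency
    units where 1.0 is the Nyquist frequency — the convention of the
    numerical environment the stimulus recipe originates from — so the
    effective centre is ``mu/2`` cycles/px (pass-band wavelength ≈ 42 px,
    posterised patch breadth ≈ 21 px, matching the modal leaf length).
    ``sigma`` is the recipe's verbatim width parameter, recorded for
    provenance; its unit convention is not recoverable, so the operative
    bandwidth is ``width`` (cycles/px), calibrated so the posterised patch
    breadth sits at the leaf scale while the filter stays genuinely
    band-pass (DC amplitude ≲ 6% of the pass-band peak).
    """

    mu: float = 0.048
    sigma: float = 120.0
    width: float = 0.010
    form: str = "gaussian"

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.width <= 0:
            raise ValueError("mu and width must be positive")
        if self.form != "gaussian":
            raise ValueError(f"unknown filter form {self.form!r}")

    @property
    def center_cycles_per_px(self) -> float:
        return self.mu / 2.0

    def radial_amplitude(self, d_cycles_per_px: np.ndarray) -> np.ndarray:
        """Amplitude gain at radial frequency ``d`` (cycles/px)."""
        d = np.asarray(d_cycles_per_px, dtype=float)
        return np.exp(-((d - self.center_cycles_per_px) ** 2) / (2.0 * self.width**2))


def bandpass_noise(
    shape: tuple[int, int], filt: FilterSpec, rng: np.random.Generator
) -> np.ndarray:
    """Generate zero-mean band-pass filtered white noise of the given shape."""
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("image must be at least 64x64")
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    amp = filt.radial_amplitude(np.hypot(fy, fx))
    out = np.fft.ifft2(np.fft.fft2(noise) * amp).real
    return out - out.mean()


def boundary_distance(labels: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance (px) to the nearest patch boundary.

    Measured as the centre-to-centre distance to the nearest opposite-label
    pixel minus one pixel (the two half-pixels flanking the boundary), so
    boundary-adjacent pixels sit at distance 0 exactly and the distance
    grows by 1 px per pixel into a patch interior.
    """
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("both patch classes must be present")
    dist = np.empty(labels.shape, dtype=float)
    for cls in np.unique(labels):
        inside = labels == cls
        dist[inside] = ndimage.distance_transform_edt(inside)[inside] - 1.0
    return dist


@dataclass
class PatchMap:
    """Binary patch labels (dark=0, light=1) plus boundary distances."""

    labels: np.ndarray
    dist: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(np.uint8)
        if set(np.unique(self.labels)) != {0, 1}:
            raise ValueError("both patch classes must be present")
        if np.any(self.dist < 0):
            raise ValueError("distances must be non-negative")

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "PatchMap":
        return cls(labels, boundary_distance(labels))


def posterise(
    tex: np.ndarray, dark: LabColor, light: LabColor
) -> tuple[PatchMap, np.ndarray]:
    """Median-split a texture into a two-colour LAB image.

    Pixels at or below the texture median become the dark colour (ties to
    dark), pixels above become the light colour; on a continuous texture
    with an even pixel count each class holds exactly half the pixels.
    """
    tex = np.asarray(tex, dtype=float)
    if tex.min() == tex.max():
        raise DegenerateTextureError("constant texture cannot be posterised")
    labels = (tex > np.median(tex)).astype(np.uint8)
    if labels.min() == labels.max():
        raise DegenerateTextureError("median split left a single class")
    pm = PatchMap.from_labels(labels)
    lab = np.where(
        labels[..., None].astype(bool), light.as_array(), dark.as_array()
    )
    return pm, lab


@dataclass(frozen=True)
class EdgeProfile:
    """Edge-enhancement condition: variant plus (offset, width) parameters."""

    variant: str = "none"
    offset: float = 0.0
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in EDGE_VARIANTS:
            raise ValueError(f"unknown edge variant {self.variant!r}")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.variant != "none" and self.width < 1:
            raise ValueError("width must be >= 1 px")

    @property
    def label(self) -> str:
        if self.variant == "none":
            return "none"
        return f"{self.variant}_w{self.width:g}_o{self.offset:g}"


def apply_edge_enhancement(
    pm: PatchMap, dark: LabColor, light: LabColor, prof: EdgeProfile
) -> tuple[np.ndarray, bool]:
    """Apply an edge-enhancement lightness profile to a posterised patch map.

    A and B always keep the patch colour; L follows the variant.  Ramping
    variants shift L by ``offset * max(0, 1 - dist/width)``: the full offset
    at the boundary, the plain patch colour at and beyond ``width``.  L is
    clipped to [0, 100]; the second return value reports whether clipping
    occurred (gamut flag).
    """
    light_px = pm.labels.astype(bool)
    dark_px = ~light_px
    L = np.where(light_px, light.L, dark.L).astype(float)
    if prof.variant != "none" and prof.offset > 0:
        ramp = np.maximum(0.0, 1.0 - pm.dist / prof.width)
        if prof.variant == "square":
            band = (pm.dist < prof.width).astype(float)
            L = L + prof.offset * band * np.where(light_px, 1.0, -1.0)
        elif prof.variant == "both":
            L = L + prof.offset * ramp * np.where(light_px, 1.0, -1.0)
        elif prof.variant == "no_low":  # light gradient only
            L = np.where(light_px, L + prof.offset * ramp, L)
        elif prof.variant == "no_high":  # dark gradient only
            L = np.where(dark_px, L - prof.offset * ramp, L)
    clipped = bool(np.any(L < 0.0) or np.any(L > 100.0))
    L = np.clip(L, 0.0, 100.0)
    A = np.where(light_px, light.A, dark.A)
    B = np.where(light_px, light.B, dark.B)
    return np.stack([L, A, B], axis=-1), clipped


def median_patch_breadth(labels: np.ndarray) -> float:
    """Median same-label run length along rows and columns, in px.

    A mean-intercept granulometry: the typical breadth of a posterised
    patch, used to check that the texture scale matches the leaf scale.
    """
    labels = np.asarray(labels)
    runs: list[np.ndarray] = []
    for arr in (labels, labels.T):
        for row in arr:
            changes = np.flatnonzero(np.diff(row)) + 1
            runs.append(np.diff(np.concatenate(([0], changes, [row.size]))))
    return float(np.median(np.concatenate(runs)))


@dataclass
class TargetMask:
    """A snake-silhouette boolean mask with its major-axis length."""

    mask: np.ndarray
    length: float
    orientation: float = 0.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("empty target mask")


def snake_mask(
    length: float,
    orientation: float = 0.0,
    *,
    body_fraction: float = 0.12,
    periods: float = 2.0,
    amplitude_fraction: float = 0.06,
) -> TargetMask:
    """Rasterise a snake silhouette: an undulating tapered tube.

    The body is a sinusoidal centreline (``periods`` full undulations over
    the length) fleshed out to ``body_fraction`` of the length at the
    middle with an elliptical taper towards the two tips.  ``orientation``
    rotates the major axis; the extent along it is ``length`` ± 1 px.
    """
    if length < 8:
        raise ValueError("snake length must be at least 8 px")
    half_body = body_fraction * length / 2.0
    amp = amplitude_fraction * length
    half = int(np.ceil(length / 2.0)) + 2
    rows = np.arange(-half, half + 1, dtype=float)[:, None]
    cols = np.arange(-half, half + 1, dtype=float)[None, :]
    ct, st = np.cos(orientation), np.sin(orientation)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    xi = u / (length / 2.0)  # -1..1 along the body
    center = amp * np.sin(2.0 * np.pi * periods * (xi + 1.0) / 2.0)
    halfwidth = half_body * np.sqrt(np.clip(1.0 - xi**2, 0.0, None))
    # keep at least the centreline pixel so the tips reach the full length
    halfwidth = np.maximum(halfwidth, 0.71)
    mask = (np.abs(xi) <= 1.0) & (np.abs(v - center) <= halfwidth)
    rr = np.flatnonzero(mask.any(axis=1))
    cc = np.flatnonzero(mask.any(axis=0))
    return TargetMask(
        mask[rr[0] : rr[-1] + 1, cc[0] : cc[-1] + 1], length, orientation
    )


def make_target(
    pop: ColorPopulation,
    rule: PatchColorRule,
    filt: FilterSpec,
    prof: EdgeProfile,
    length: float,
    orientation: float,
    rng: np.random.Generator,
) -> tuple[TargetMask, np.ndarray]:
    """Build the camouflaged snake: texture, enhancement, silhouette crop.

    Returns the snake mask and the edge-enhanced LAB texture over the
    mask's bounding box (pixels outside the mask are present but unused by
    compositing).  Deterministic under ``rng``.
    """
    target = snake_mask(length, orientation)
    h, w = target.mask.shape
    tex = bandpass_noise((max(64, h), max(64, w)), filt, rng)[:h, :w]
    dark, light = sample_patch_colors(pop, rule, rng)
    pm, _ = posterise(tex, dark, light)
    lab, _ = apply_edge_enhancement(pm, dark, light, prof)
    return target, lab


@dataclass
class StimulusImage:
    """A composed search stimulus with ground truth for the analysis join."""

    canvas: SceneCanvas
    target_bbox: tuple[int, int, int, int]  # (top, left, bottom, right), exclusive
    target_cell: int | str
    condition: tuple[EdgeProfile, bool]  # (edge profile, shadows flag)


def _cell_bounds(
    canvas: SceneCanvas, cell: int | str, n_cols: int = 4, n_rows: int = 2
) -> tuple[int, int, int, int]:
    if cell == "center":
        return 0, 0, canvas.height, canvas.width
    cell = int(cell)
    if not 1 <= cell <= n_cols * n_rows:
        raise ValueError(f"cell must be 1..{n_cols * n_rows} or 'center'")
    r, c = divmod(cell - 1, n_cols)
    ch, cw = canvas.height // n_rows, canvas.width // n_cols
    return r * ch, c * cw, (r + 1) * ch, (c + 1) * cw


def compose_stimulus(
    bg: SceneCanvas,
    target: tuple[TargetMask, np.ndarray],
    cell: int | str,
    rng: np.random.Generator,
    *,
    condition: tuple[EdgeProfile, bool] | None = None,
    n_cols: int = 4,
    n_rows: int = 2,
) -> StimulusImage:
    """Copy the masked target texture into a display cell of the background.

    Target pixels replace background pixels with no blending.  Placement is
    uniform over positions keeping the target bounding box inside the cell
    (the centre for ``cell='center'``).  Raises :class:`PlacementError`
    when the target does not fit.
    """
    mask_obj, lab = target
    mask = mask_obj.mask
    th, tw = mask.shape
    r0, c0, r1, c1 = _cell_bounds(bg, cell, n_cols, n_rows)
    if th > r1 - r0 or tw > c1 - c0:
        raise PlacementError("target larger than its display cell")
    if cell == "center":
        top = (bg.height - th) // 2
        left = (bg.width - tw) // 2
    else:
        top = int(rng.integers(r0, r1 - th + 1))
        left = int(rng.integers(c0, c1 - tw + 1))
    out = bg.copy()
    rgb, _ = lab_image_to_display(lab)
    region = out.pixels[top : top + th, left : left + tw]
    region[mask] = rgb[mask]
    return StimulusImage(
        out,
        (top, left, top + th, left + tw),
        cell,
        condition if condition is not None else (EdgeProfile(), False),
    )


def clear_central_band(
    scene: SceneCanvas, base: SceneCanvas, band_deg: tuple[float, float]
) -> SceneCanvas:
    """Restore a leaf-free central band (width° × height°) from the base canvas.

    Used by the depth-judgement layout, where the area surrounding the
    target must contain no leaves so occlusion cannot act as a depth cue.
    """
    bw = int(round(band_deg[0] / scene.deg_per_px))
    bh = int(round(band_deg[1] / scene.deg_per_px))
    out = scene.copy()
    top = max(0, (scene.height - bh) // 2)
    left = max(0, (scene.width - bw) // 2)
    out.pixels[top : top + bh, left : left + bw] = base.pixels[
        top : top + bh, left : left + bw
    ]
    return out
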