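"""CIE-LAB colour populations for leaves and camouflage patches.

The background leaves and the two camouflage patch colours are drawn from a
single constrained population of CIE-LAB colours emulating a calibrated
photograph of leaf litter on a forest floor.  Two constraints shape the
population downstream:

* chromatic trimming — colours further than one standard deviation from the
  population mean on the A (green–red) or B (blue–yellow) axis are removed,
  keeping the palette chromatically homogeneous;
* patch-colour bands — the dark camouflage patch colour is drawn from the
  35th–45th percentile band of lightness L, the light one from the
  55th–65th band, guaranteeing moderate luminance contrast between patches
  while both remain typical of the background.

Because the original calibrated photograph is not redistributable, a
parametric synthetic population with earth-tone statistics stands in for it
(:func:`synth_forest_population`); image-derived populations can be supplied
through the CSV interface instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage import color as _skcolor

__all__ = [
    "LabColor",
    "ColorPopulation",
    "PatchColorRule",
    "DegeneratePopulationError",
    "filter_population",
    "percentile_ranks",
    "sample_patch_colors",
    "synth_forest_population",
    "lab_to_display",
    "display_to_lab",
    "lab_image_to_display",
]


class DegeneratePopulationError(ValueError):
    """Raised when a percentile band of the population is empty."""


@dataclass(frozen=True)
class LabColor:
    """A single CIE-LAB colour (D65 white point).

    L is lightness in 0–100 CIE-L units; A and B are the green–red and
    blue–yellow opponent axes (unbounded in principle, earth tones in
    practice).
    """

    L: float
    A: float
    B: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.A, self.B], dtype=float)


@dataclass
class ColorPopulation:
    """An ordered collection of LAB colours with a provenance tag.

    ``lab`` is an (n, 3) float array of rows (L, A, B).  ``origin`` records
    where the colours came from (``"synthetic"`` or ``"image-derived"``).
    """

    lab: np.ndarray
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.lab = np.asarray(self.lab, dtype=float)
        if self.lab.ndim != 2 or self.lab.shape[1] != 3:
            raise ValueError("lab must be an (n, 3) array")
        if len(self.lab) == 0:
            raise ValueError("population must be non-empty")
        L = self.lab[:, 0]
        if np.any(L < 0) or np.any(L > 100):
            raise ValueError("all L values must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.lab)

    def __getitem__(self, i: int) -> LabColor:
        L, A, B = self.lab[i]
        return LabColor(L, A, B)

    @property
    def L(self) -> np.ndarray:
        return self.lab[:, 0]

    @property
    def A(self) -> np.ndarray:
        return self.lab[:, 1]

    @property
    def B(self) -> np.ndarray:
        return self.lab[:, 2]

    def to_csv(self, path) -> None:
        pd.DataFrame(self.lab, columns=["L", "A", "B"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, origin: str = "image-derived") -> "ColorPopulation":
        df = pd.read_csv(path)
        return cls(df[["L", "A", "B"]].to_numpy(dtype=float), origin=origin)


@dataclass(frozen=True)
class PatchColorRule:
    """Lightness percentile bands for the two camouflage patch colours."""

    dark_percentile_range: tuple[float, float] = (35.0, 45.0)
    light_percentile_range: tuple[float, float] = (55.0, 65.0)

    def __post_init__(self) -> None:
        d_lo, d_hi = self.dark_percentile_range
        l_lo, l_hi = self.light_percentile_range
        if not (d_lo < d_hi and l_lo < l_hi):
            raise ValueError("percentile ranges must be increasing")
        if d_hi >= l_lo:
            raise ValueError("dark band must lie strictly below the light band")


def filter_population(pop: ColorPopulation, k_sd: float = 1.0) -> ColorPopulation:
    """Trim colours beyond ``k_sd`` standard deviations on the A and B axes.

    Sample statistics (mean, SD with n−1 denominator) are computed once on
    the input population; both axes are filtered jointly in a single pass.
    Boundary colours (exactly ``k_sd`` SD away) are retained; order is
    preserved.
    """
    if len(pop) < 2:
        raise ValueError("need at least 2 colours for a defined SD")
    A, B = pop.A, pop.B
    keep = (np.abs(A - A.mean()) <= k_sd * A.std(ddof=1)) & (
        np.abs(B - B.mean()) <= k_sd * B.std(ddof=1)
    )
    if not keep.any():
        raise ValueError("filter removed every colour")
    return ColorPopulation(pop.lab[keep], origin=pop.origin)


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Percentile rank of each value on the empirical CDF, 0–100.

    Linear interpolation convention: the smallest value ranks 0, the largest
    100; ties share their average rank.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for percentile ranks")
    return 100.0 * (stats.rankdata(values, method="average") - 1.0) / (n - 1.0)


def sample_patch_colors(
    pop: ColorPopulation,
    rule: PatchColorRule,
    rng: np.random.Generator,
) -> tuple[LabColor, LabColor]:
    """Draw the (dark, light) camouflage patch colours from the L bands.

    Each colour is drawn uniformly from the colours whose L percentile rank
    falls in the band (endpoints inclusive).  Raises
    :class:`DegeneratePopulationError` when a band is empty or the bands
    provide no luminance contrast (e.g. a population of identical colours).
    """
    ranks = percentile_ranks(pop.L)
    d_lo, d_hi = rule.dark_percentile_range
    l_lo, l_hi = rule.light_percentile_range
    dark_idx = np.flatnonzero((ranks >= d_lo) & (ranks <= d_hi))
    light_idx = np.flatnonzero((ranks >= l_lo) & (ranks <= l_hi))
    if len(dark_idx) == 0 or len(light_idx) == 0:
        raise DegeneratePopulationError("empty L percentile band")
    dark = pop[int(rng.choice(dark_idx))]
    light = pop[int(rng.choice(light_idx))]
    if not light.L > dark.L:
        raise DegeneratePopulationError("bands provide no luminance contrast")
    return dark, light


def synth_forest_population(
    n: int,
    rng: np.random.Generator,
    *,
    L_mean: float = 45.0,
    L_sd: float = 12.0,
    A_mean: float = 12.0,
    A_sd: float = 4.0,
    B_mean: float = 25.0,
    B_sd: float = 6.0,
    outlier_frac: float = 0.10,
    outlier_scale: float = 5.0,
) -> ColorPopulation:
    """Synthetic earth-tone LAB population standing in for a forest-floor image.

    Lightness is normal; each chromatic axis is a contaminated normal — a
    dominant earth-tone mode (brownish A, yellowish B) plus a small fraction
    of wide-spread outliers emulating atypical pixels (bright foliage, wet
    dark patches) that the one-SD chromatic trim then removes.  L is clipped
    to the valid [0, 100] range.  Deterministic under the supplied ``rng``.
    """
    if n < 100:
        raise ValueError("n must be >= 100 for reliable percentile bands")
    L = np.clip(rng.normal(L_mean, L_sd, n), 0.0, 100.0)

    def contaminated(mean: float, sd: float) -> np.ndarray:
        x = rng.normal(mean, sd, n)
        wide = rng.random(n) < outlier_frac
        x[wide] = rng.normal(mean, outlier_scale * sd, wide.sum())
        return x

    A = contaminated(A_mean, A_sd)
    B = contaminated(B_mean, B_sd)
    return ColorPopulation(np.column_stack([L, A, B]), origin="synthetic")


# ---------------------------------------------------------------------------
# LAB <-> linear display RGB

_GAMUT_TOL = 0.01  # L-unit round-trip tolerance counted as in-gamut


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    """sRGB electro-optical transfer: encoded [0,1] -> linear [0,1]."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    """Linear [0,1] -> sRGB-encoded [0,1]."""
    v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def lab_to_display(c: LabColor) -> tuple[np.ndarray, bool]:
    """Convert a LAB colour to a linear-RGB triple (D65 sRGB primaries).

    Out-of-gamut colours are clipped channel-wise; the second return value
    is True when the colour was in gamut (round-trip error below 0.01 L/A/B
    units) and False when clipping occurred.
    """
    lab = c.as_array().reshape(1, 1, 3)
    srgb = np.clip(_skcolor.lab2rgb(lab), 0.0, 1.0)
    back = _skcolor.rgb2lab(srgb)
    in_gamut = bool(np.max(np.abs(back - lab)) <= _GAMUT_TOL)
    return _srgb_decode(srgb[0, 0]), in_gamut


def display_to_lab(rgb_linear: np.ndarray) -> LabColor:
    """Inverse of :func:`lab_to_display` for a linear-RGB triple."""
    srgb = _srgb_encode(np.asarray(rgb_linear, dtype=float)).reshape(1, 1, 3)
    L, A, B = _skcolor.rgb2lab(srgb)[0, 0]
    return LabColor(float(np.clip(L, 0.0, 100.0)), float(A), float(B))


def lab_image_to_display(lab_image: np.ndarray) -> tuple[np.ndarray, bool]:
    """Vectorised LAB -> linear RGB for an (h, w, 3) image, with gamut flag."""
    lab_image = np.asarray(lab_image, dtype=float)
    srgb = np.clip(_skcolor.lab2rgb(lab_image), 0.0, 1.0)
    back = _skcolor.rgb2lab(srgb)
    in_gamut = bool(np.max(np.abs(back - lab_image)) <= _GAMUT_TOL)
    return _srgb_decode(srgb), in_gamut
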