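"""Muscle-fiber morphometry from stained cross-section images.

The pipeline mirrors standard histological practice for boundary-stained
(WGA-like) sections: grayscale conversion, Gaussian denoising, binarization,
morphological cleanup, connected-component labeling, and per-fiber filtering
by area and circularity.  Accepted fibers yield cross-sectional areas (CSA),
from which summary statistics — mean CSA, the hypertrophy fraction (share of
fibers above a CSA threshold) — and slow/fast fiber-type proportions (from
ATPase-like dark/light staining) are derived.

Circularity is the isoperimetric ratio 4*pi*A/P**2 (ImageJ's definition),
with the perimeter estimated by a Crofton-style estimator by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import scipy.ndimage as ndi
import scipy.stats
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk

__all__ = [
    "ImageGrid",
    "MorphometryConfig",
    "FiberRegion",
    "MorphometrySummary",
    "FiberTypingResult",
    "preprocess",
    "segment_fibers",
    "classify_region",
    "circularity",
    "summarize",
    "hypertrophy_fraction",
    "fiber_typing",
    "compare_groups",
]

# Digitization makes the isoperimetric ratio of near-circular regions
# overshoot 1 slightly; values are clipped to [0, 1 + CIRCULARITY_EPS] and the
# same slack is granted above ``circularity_max`` when filtering.
CIRCULARITY_EPS = 0.05

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageGrid:
    """A single-channel intensity raster with optional spatial calibration.

    Parameters
    ----------
    pixels:
        2-D array of intensities (a 3-D RGB array is accepted by
        :func:`preprocess`, which converts it to luminance first).
    bit_depth:
        8 or 16; intensities must fit the corresponding range.
    um_per_px:
        Optional micrometres per pixel.  When present, areas are also
        reported in µm² (area_px * um_per_px**2).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    um_per_px: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be a 2-D (or RGB 3-D) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one row and column")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo, hi = 0, 2**self.bit_depth - 1
        if self.pixels.dtype.kind in "uif":
            pmin, pmax = float(self.pixels.min()), float(self.pixels.max())
            if pmin < lo or pmax > hi:
                raise ValueError(
                    f"intensities [{pmin}, {pmax}] exceed {self.bit_depth}-bit range"
                )
        if self.um_per_px is not None and self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


@dataclass
class MorphometryConfig:
    """Parameters of the fiber segmentation and filtering pipeline.

    Defaults follow the study design this package implements: candidate
    fibers must have an area between 1400 and 80 000 px and a circularity
    between 0.2 and 1.0 (closed intervals).
    """

    gaussian_sigma_px: float = 1.0
    binarization: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: Optional[float] = None
    area_min_px: int = 1400
    area_max_px: int = 80000
    circularity_min: float = 0.2
    circularity_max: float = 1.0
    adhesion_opening_radius_px: int = 3
    fill_holes: bool = True
    perimeter_method: Literal["crofton", "classic"] = "crofton"
    equal_var_ttest: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be >= 0")
        if self.area_min_px >= self.area_max_px:
            raise ValueError(
                f"area_min_px ({self.area_min_px}) must be < area_max_px "
                f"({self.area_max_px})"
            )
        if not (0 <= self.circularity_min <= self.circularity_max):
            raise ValueError("require 0 <= circularity_min <= circularity_max")
        if self.circularity_max > 1.0 + CIRCULARITY_EPS:
            raise ValueError(
                f"circularity_max must be <= {1.0 + CIRCULARITY_EPS}"
            )
        if self.binarization == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed binarization requires fixed_threshold")
        if self.adhesion_opening_radius_px < 0:
            raise ValueError("adhesion_opening_radius_px must be >= 0")


#: rejection reasons, in the (fixed) order they are checked
REJECTION_ORDER = ("border_touching", "too_small", "too_large", "non_circular")


@dataclass
class FiberRegion:
    """One segmented fiber candidate with its measurements and filter verdict."""

    label: int
    pixel_count: int
    perimeter_px: float
    circularity: float
    centroid: tuple[float, float]
    status: Literal["accepted", "rejected"]
    reason: Optional[str] = None
    area_um2: Optional[float] = None

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"


@dataclass
class MorphometrySummary:
    """CSA summary over the accepted fibers of one image."""

    n_accepted: int
    csa_values: np.ndarray
    mean_csa: Optional[float]
    csa_sd: Optional[float]
    units: str = "px"

    def hypertrophy_fraction(self, threshold: float) -> Optional[float]:
        """Fraction of accepted fibers with CSA strictly above ``threshold``."""
        if self.n_accepted == 0:
            return None
        return hypertrophy_fraction(self.csa_values, threshold)


def circularity(
    area_px: float, perimeter_px: float, eps: float = CIRCULARITY_EPS
) -> float:
    """Isoperimetric circularity 4*pi*A/P**2, clipped to [0, 1 + eps].

    An ideal disk gives exactly 1.0; elongated shapes approach 0.  The clip
    absorbs the small overshoot that discrete perimeter estimators produce
    for near-circular digitized regions.
    """
    if area_px <= 0 or perimeter_px <= 0:
        raise ValueError("area and perimeter must be positive")
    value = 4.0 * np.pi * area_px / perimeter_px**2
    return float(np.clip(value, 0.0, 1.0 + eps))


def preprocess(image: ImageGrid, config: MorphometryConfig) -> ImageGrid:
    """Grayscale conversion, Gaussian smoothing and binarization.

    Foreground (value 1) marks candidate fiber interiors, which in
    boundary-stained material are *darker* than the stained boundary
    network, so pixels *below* the threshold become foreground.

    Raises
    ------
    ValueError
        If the image is constant ("no contrast": no threshold separates
        fibers from boundary).
    """
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim == 3:
        px = px[..., :3] @ _LUMA
    if np.ptp(px) == 0:
        raise ValueError("no contrast: image is constant")
    if config.gaussian_sigma_px > 0:
        px = gaussian(px, sigma=config.gaussian_sigma_px, preserve_range=True)
    if config.binarization == "fixed":
        thr = float(config.fixed_threshold)
    else:
        thr = float(threshold_otsu(px))
    binary = (px < thr).astype(np.uint8)
    return ImageGrid(binary, bit_depth=image.bit_depth, um_per_px=image.um_per_px)


def classify_region(
    area_px: int,
    circ: float,
    touches_border: bool,
    config: MorphometryConfig,
) -> tuple[str, Optional[str]]:
    """Apply the acceptance filters to one region's measurements.

    Checks run in a fixed order — border_touching, too_small, too_large,
    non_circular — and the first failure is the recorded rejection reason.
    Area and circularity bounds are closed intervals; circularity is allowed
    ``CIRCULARITY_EPS`` of digitization slack above ``circularity_max``.
    """
    if touches_border:
        return "rejected", "border_touching"
    if area_px < config.area_min_px:
        return "rejected", "too_small"
    if area_px > config.area_max_px:
        return "rejected", "too_large"
    if not (
        config.circularity_min <= circ <= config.circularity_max + CIRCULARITY_EPS
    ):
        return "rejected", "non_circular"
    return "accepted", None


def segment_fibers(
    binary: ImageGrid, config: MorphometryConfig
) -> list[FiberRegion]:
    """Label candidate fibers in a binary image and filter them.

    Morphological opening (disk of ``adhesion_opening_radius_px``) severs
    thin bridges between adhered fibers before labeling; holes are filled
    per region when ``fill_holes``.  Every connected component is returned
    with measurements and an accepted/rejected status.
    """
    mask = np.asarray(binary.pixels) > 0
    if not mask.any():
        return []
    if config.adhesion_opening_radius_px > 0:
        mask = ndi.binary_opening(mask, structure=disk(config.adhesion_opening_radius_px))
    labeled = cc_label(mask, connectivity=1)
    if config.fill_holes:
        filled = ndi.binary_fill_holes(labeled > 0)
        # filling may not bridge separate components (they are disjoint),
        # so relabel the filled mask to keep labels consistent
        labeled = cc_label(filled, connectivity=1)
    nrows, ncols = labeled.shape
    regions: list[FiberRegion] = []
    for prop in regionprops(labeled):
        area = int(prop.area)
        if config.perimeter_method == "crofton":
            perim = float(prop.perimeter_crofton)
        else:
            perim = float(prop.perimeter)
        if perim <= 0:  # single-pixel specks: define circularity as 0
            circ = 0.0
        else:
            circ = circularity(area, perim)
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        status, reason = classify_region(area, circ, touches, config)
        area_um2 = (
            area * binary.um_per_px**2 if binary.um_per_px is not None else None
        )
        regions.append(
            FiberRegion(
                label=int(prop.label),
                pixel_count=area,
                perimeter_px=perim,
                circularity=circ,
                centroid=tuple(float(c) for c in prop.centroid),
                status=status,
                reason=reason,
                area_um2=area_um2,
            )
        )
    return regions


def hypertrophy_fraction(csa_values: Sequence[float], threshold: float) -> float:
    """Share of fibers whose CSA is strictly greater than ``threshold``.

    A non-increasing step function of the threshold: 1 below the smallest
    CSA, 0 above the largest.
    """
    values = np.asarray(csa_values, dtype=float)
    if values.size == 0:
        raise ValueError("no CSA values")
    return float(np.mean(values > threshold))


def summarize(
    regions: Sequence[FiberRegion],
    um_per_px: Optional[float] = None,
) -> MorphometrySummary:
    """Mean/SD of CSA over accepted regions (µm² when calibrated, else px)."""
    accepted = [r for r in regions if r.accepted]
    if um_per_px is not None:
        values = np.array([r.pixel_count * um_per_px**2 for r in accepted])
        units = "um2"
    else:
        values = np.array([float(r.pixel_count) for r in accepted])
        units = "px"
    if len(accepted) == 0:
        return MorphometrySummary(0, values, None, None, units)
    return MorphometrySummary(
        n_accepted=len(accepted),
        csa_values=values,
        mean_csa=float(values.mean()),
        csa_sd=float(values.std(ddof=1)) if len(accepted) > 1 else 0.0,
        units=units,
    )


@dataclass
class FiberTypingResult:
    proportion_slow: float
    n_slow: int
    n_total: int
    interior_means: np.ndarray = field(default_factory=lambda: np.array([]))
    is_slow: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


def fiber_typing(
    image: ImageGrid,
    config: Optional[MorphometryConfig] = None,
    min_separation: float = 30.0,
) -> FiberTypingResult:
    """Slow-twitch proportion from an ATPase-style dark/light image.

    Fibers are segmented as usual (with a three-class threshold so that both
    dark slow and grey fast fibers count as foreground against the light
    background), then classified by the Otsu split of their mean interior
    intensities: darker class = slow twitch.

    The slow/fast split is placed in the middle of the largest gap of the
    sorted interior means.  If that gap is below ``min_separation`` grey
    levels the intensities are treated as unimodal: a warning is raised and
    all fibers go to one class, chosen by comparing their mean intensity
    with 60% of the mean background intensity (dark = slow).
    """
    if config is None:
        config = MorphometryConfig()
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim == 3:
        px = px[..., :3] @ _LUMA
    if np.ptp(px) == 0:
        raise ValueError("no contrast: image is constant")
    smoothed = (
        gaussian(px, sigma=config.gaussian_sigma_px, preserve_range=True)
        if config.gaussian_sigma_px > 0
        else px
    )
    try:
        thr = float(threshold_multiotsu(smoothed, classes=3)[-1])
    except ValueError:  # fewer than 3 distinct grey levels
        thr = float(threshold_otsu(smoothed))
    binary = ImageGrid(
        (smoothed < thr).astype(np.uint8),
        bit_depth=image.bit_depth,
        um_per_px=image.um_per_px,
    )
    regions = segment_fibers(binary, config)
    accepted = [r for r in regions if r.accepted]
    if not accepted:
        return FiberTypingResult(float("nan"), 0, 0)

    # mean original intensity inside each accepted fiber
    mask = np.asarray(binary.pixels) > 0
    if config.adhesion_opening_radius_px > 0:
        mask = ndi.binary_opening(mask, structure=disk(config.adhesion_opening_radius_px))
    labeled = cc_label(
        ndi.binary_fill_holes(mask) if config.fill_holes else mask, connectivity=1
    )
    means = np.array(
        ndi.labeled_comprehension(
            px, labeled, [r.label for r in accepted], np.mean, float, np.nan
        )
    )
    order = np.sort(means)
    gaps = np.diff(order)
    if len(means) < 2 or gaps.max(initial=0.0) < min_separation:
        warnings.warn(
            "fiber interior intensities look unimodal; assigning all fibers "
            "to a single type",
            stacklevel=2,
        )
        background = float(px[labeled == 0].mean())
        is_slow = means < 0.6 * background
    else:
        g = int(np.argmax(gaps))
        split = 0.5 * (order[g] + order[g + 1])
        is_slow = means < split
    n_slow = int(is_slow.sum())
    return FiberTypingResult(
        proportion_slow=n_slow / len(accepted),
        n_slow=n_slow,
        n_total=len(accepted),
        interior_means=means,
        is_slow=is_slow,
    )


def compare_groups(
    values_by_group: Sequence[Sequence[float]],
    design: Literal["two_sample_t", "one_way_anova"] = "two_sample_t",
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sided group comparison of CSA-type measurements.

    ``two_sample_t`` is the independent-sample t-test (equal-variance by
    default), ``one_way_anova`` the one-way F-test.  Degenerate input where
    every observation is identical returns (0.0, 1.0) with a warning.
    """
    groups = [np.asarray(g, dtype=float) for g in values_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    if design == "two_sample_t" and len(groups) != 2:
        raise ValueError("two_sample_t requires exactly 2 groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        warnings.warn("all observations identical; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    if design == "two_sample_t":
        stat, p = scipy.stats.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    elif design == "one_way_anova":
        stat, p = scipy.stats.f_oneway(*groups)
    else:
        raise ValueError(f"unknown design {design!r}")
    if np.isnan(p):  # zero within-group variance but distinct groups
        warnings.warn("degenerate variance structure; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    return float(stat), float(p)
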