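"""Quantitative phenotyping of compound-eye images.

The wild-type fly eye tiles ~750 ommatidia in a regular hexagonal lattice, so
each interior ommatidium has six equidistant neighbors and the six vectors
from its center to those neighbors are separated by 60 degree angles.
Developmental perturbation roughens the lattice, and that disorder is what
this module quantifies:

1. :func:`detect_ommatidia` finds ommatidial centers as local maxima of the
   smoothed image, refined to sub-pixel precision by an intensity-weighted
   centroid.
2. :func:`neighbor_fans` builds, for every center, the fan of vectors to its
   six nearest neighbors, flagging interior centers whose fans are not
   distorted by the eye margin.
3. :func:`od_scores` summarizes the fans into two ommatidial-disorderliness
   (OD) subscores -- the coefficient of variation of the six vector lengths
   (distance OD) and the mean deviation of consecutive angular gaps from 60
   degrees (angle OD) -- and their sum, the composite phenotypic score.
   A perfect lattice scores exactly (0, 0, 0); both subscores are invariant
   under translation, rotation and uniform scaling of the center set.

Necrotic-patch area (dark tissue not reflected in the lattice scores) and
stained-cell counting round out the phenotyping toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

__all__ = [
    "EyeImage",
    "DetectionParams",
    "OmmatidiaSet",
    "FanSet",
    "ODScores",
    "load_image",
    "detect_ommatidia",
    "neighbor_fans",
    "od_scores",
    "necrotic_patch_area",
    "count_labeled_cells",
    "score_image",
    "UnscorableImageError",
]

INTERIOR_FACTOR = 1.8  # k-th neighbor cutoff, multiples of median NN distance
INTERIOR_MAX_GAP = 100.0  # degrees; interior fans must surround their center


class UnscorableImageError(ValueError):
    """Raised when an image has no interior ommatidia to score."""


@dataclass(frozen=True)
class EyeImage:
    """Grayscale image; x points right, y down, origin at the top-left pixel."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(
                f"expected a single-channel 2-D image, got shape {px.shape}; "
                "multi-channel input is not supported"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if px.size and (px.min() < 0 or px.max() > 2**self.bit_depth - 1):
            raise ValueError("intensities exceed the declared bit depth")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DetectionParams:
    smooth_sigma: float = 2.0  # px
    min_separation: float = 6.0  # px, minimum Euclidean distance between centers
    threshold_mode: str = "otsu"  # "otsu" | "absolute"
    absolute_threshold: float = 0.0  # intensity units, absolute mode only

    def __post_init__(self) -> None:
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be nonnegative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.threshold_mode not in ("otsu", "absolute"):
            raise ValueError("threshold_mode must be 'otsu' or 'absolute'")


@dataclass(frozen=True)
class OmmatidiaSet:
    centers: np.ndarray  # (n, 2) sub-pixel (x, y)
    n_detected: int

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if c.size == 0:
            c = c.reshape(0, 2)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "n_detected", int(c.shape[0]))


@dataclass(frozen=True)
class FanSet:
    """Per-center k-nearest-neighbor vector fans.

    ``lengths``/``angles`` have shape (n, k); angles are degrees in [0, 360),
    measured from +x toward +y.  ``interior`` marks centers whose fan does
    not span the eye margin: the k-th neighbor lies within
    ``INTERIOR_FACTOR`` times the median nearest-neighbor distance *and* the
    neighbors surround the center (largest sorted angular gap at most
    ``INTERIOR_MAX_GAP`` degrees).  On a perfect hexagonal lattice the
    distance rule alone admits lattice-edge sites (their 6th neighbor sits at
    sqrt(3) x spacing = 1.73 x spacing), so the coverage condition is what
    guarantees a perfect lattice scores exactly zero, while still retaining
    interior sites next to a dropped-out ommatidium (largest gap 90 degrees).
    """

    centers: np.ndarray
    lengths: np.ndarray
    angles: np.ndarray
    interior: np.ndarray
    k: int


@dataclass(frozen=True)
class ODScores:
    distance_od: float
    angle_od: float
    composite_score: float
    n_detected: int
    n_interior: int
    per_center: pd.DataFrame | None = None


def load_image(path) -> EyeImage:
    """Read an 8-bit PNG or 8/16-bit TIFF grayscale image."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return EyeImage(pixels=arr, bit_depth=bit_depth)


def _as_pixels(image) -> np.ndarray:
    if isinstance(image, EyeImage):
        return np.asarray(image.pixels, dtype=float)
    return np.asarray(image, dtype=float)


def _enforce_separation(coords: np.ndarray, values: np.ndarray, min_sep: float):
    """Greedily keep maxima in decreasing intensity order, Euclidean spacing."""
    order = np.lexsort((coords[:, 1], coords[:, 0], -values))
    kept: list[np.ndarray] = []
    min_sep2 = min_sep**2
    for i in order:
        c = coords[i]
        if all(((c - k) ** 2).sum() >= min_sep2 for k in kept):
            kept.append(c)
    return np.array(kept, dtype=float).reshape(-1, 2)


def detect_ommatidia(image, params: DetectionParams = DetectionParams()) -> OmmatidiaSet:
    """Detect ommatidial centers as smoothed local maxima above threshold.

    Centers are refined to sub-pixel position by an intensity-weighted
    centroid in a window of half-width ``round(min_separation)``; the result
    is deterministic.  A constant image yields an empty set.
    """
    px = _as_pixels(image)
    if px.size == 0:
        return OmmatidiaSet(np.empty((0, 2)), 0)
    smoothed = ndimage.gaussian_filter(px, params.smooth_sigma)
    if np.ptp(smoothed) == 0:
        return OmmatidiaSet(np.empty((0, 2)), 0)
    if params.threshold_mode == "otsu":
        thr = threshold_otsu(smoothed)
    else:
        thr = params.absolute_threshold
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(np.floor(params.min_separation / np.sqrt(2)))),
        threshold_abs=thr,
        exclude_border=False,
    )  # (row, col)
    if peaks.size == 0:
        return OmmatidiaSet(np.empty((0, 2)), 0)
    vals = smoothed[peaks[:, 0], peaks[:, 1]]
    coords = _enforce_separation(peaks.astype(float), vals, params.min_separation)

    # sub-pixel refinement: intensity-weighted centroid above the threshold
    half = max(1, int(round(params.min_separation)))
    h, w = smoothed.shape
    refined = []
    for r, c in coords:
        r, c = int(r), int(c)
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        win = smoothed[r0:r1, c0:c1] - thr
        win = np.clip(win, 0.0, None)
        total = win.sum()
        if total <= 0:
            refined.append((float(c), float(r)))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        refined.append(((win * cc).sum() / total, (win * rr).sum() / total))
    centers = np.asarray(refined, dtype=float)
    order = np.lexsort((centers[:, 1], centers[:, 0]))
    return OmmatidiaSet(centers[order], centers.shape[0])


def neighbor_fans(centers, k: int = 6) -> FanSet:
    """Vector fans to the k nearest neighbors of each center.

    Neighbors are ranked by Euclidean distance with ties broken by smaller
    index under lexicographic center ordering, so the result is deterministic
    and matches an exhaustive all-pairs search.  With fewer than k+1 centers
    an empty FanSet is returned with a warning.
    """
    if isinstance(centers, OmmatidiaSet):
        pts = centers.centers
    else:
        pts = np.atleast_2d(np.asarray(centers, dtype=float))
    n = pts.shape[0]
    empty = FanSet(
        pts,
        np.empty((0, k)),
        np.empty((0, k)),
        np.zeros(0, dtype=bool),
        k,
    )
    if n < k + 1:
        warnings.warn(
            f"need at least {k + 1} centers to build {k}-neighbor fans, got {n}",
            stacklevel=2,
        )
        return empty

    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    diff = pts[None, :, :] - pts[:, None, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    # stable argsort on distance -> ties broken by smaller lexicographic index
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    rows = np.arange(n)[:, None]
    lengths = d[rows, nn]
    vecs = pts[nn] - pts[:, None, :]
    angles = np.degrees(np.arctan2(vecs[..., 1], vecs[..., 0])) % 360.0

    first_nn = d.min(axis=1)
    close_enough = lengths[:, k - 1] <= INTERIOR_FACTOR * np.median(first_nn)
    srt = np.sort(angles, axis=1)
    gaps = np.column_stack([np.diff(srt, axis=1), 360.0 - (srt[:, -1] - srt[:, 0])])
    surrounded = gaps.max(axis=1) <= INTERIOR_MAX_GAP
    return FanSet(pts, lengths, angles, close_enough & surrounded, k)


def _length_cv(lengths: np.ndarray) -> np.ndarray:
    """Population coefficient of variation of each fan's vector lengths."""
    mean = lengths.mean(axis=1)
    sd = lengths.std(axis=1)  # population (n-divisor) SD
    return sd / mean


def _angle_deviation(angles: np.ndarray) -> np.ndarray:
    """Mean |gap - 60| / 60 over the wraparound-consecutive angular gaps."""
    k = angles.shape[1]
    srt = np.sort(angles, axis=1)
    gaps = np.diff(srt, axis=1)
    wrap = 360.0 - (srt[:, -1] - srt[:, 0])
    gaps = np.column_stack([gaps, wrap])
    return np.abs(gaps - 360.0 / k).mean(axis=1) / (360.0 / k)


def od_scores(fans: FanSet, per_center: bool = False) -> ODScores:
    """Distance/angle ommatidial-disorderliness subscores and composite score.

    Per interior center: length disorderliness = population SD of the k
    vector lengths over their mean; angle disorderliness = mean over the k
    wraparound-consecutive angular gaps of |gap - 60 deg| / 60 deg.  The
    subscores are 100x the mean per-center disorderliness over interior
    centers, and composite = distance OD + angle OD.
    """
    if fans.lengths.shape[0] == 0 or not fans.interior.any():
        raise UnscorableImageError(
            "no interior ommatidia: the image cannot be scored"
        )
    cv = _length_cv(fans.lengths)
    ang = _angle_deviation(fans.angles)
    mask = fans.interior
    distance_od = 100.0 * float(cv[mask].mean())
    angle_od = 100.0 * float(ang[mask].mean())
    table = None
    if per_center:
        table = pd.DataFrame(
            {
                "x": fans.centers[:, 0],
                "y": fans.centers[:, 1],
                "interior": fans.interior,
                "length_cv": cv,
                "angle_dev": ang,
            }
        )
    return ODScores(
        distance_od=distance_od,
        angle_od=angle_od,
        composite_score=distance_od + angle_od,
        n_detected=fans.centers.shape[0],
        n_interior=int(mask.sum()),
        per_center=table,
    )


def necrotic_patch_area(image, dark_threshold: float, min_size: int = 10) -> int:
    """Total area (px^2) of dark connected patches below ``dark_threshold``.

    Pixels strictly below the threshold are grouped with 8-connectivity and
    components larger than ``min_size`` pixels are summed; small speckle is
    ignored.  Deterministic; an image with no dark patches returns 0.
    """
    px = _as_pixels(image)
    if isinstance(image, EyeImage):
        if not 0 <= dark_threshold <= 2**image.bit_depth - 1:
            raise ValueError("dark_threshold outside the bit-depth range")
    mask = px < dark_threshold
    if not mask.any():
        return 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())[1:]
    return int(sizes[sizes > min_size].sum())


def count_labeled_cells(
    image,
    strategy: str = "components",
    smooth_sigma: float = 2.0,
    min_separation: float = 5.0,
) -> int:
    """Count stained cells (e.g. dcp1/pH3-positive nuclei) in a micrograph.

    ``components`` counts above-threshold connected components after Gaussian
    smoothing (AnalyzeParticles-style); ``maxima`` counts smoothed local
    maxima with a minimum separation (nuclei-counter-style).  Both are
    deterministic and return 0 on a blank image.
    """
    if strategy not in ("components", "maxima"):
        raise ValueError("strategy must be 'components' or 'maxima'")
    px = _as_pixels(image)
    if px.size == 0:
        return 0
    smoothed = ndimage.gaussian_filter(px, smooth_sigma)
    if np.ptp(smoothed) == 0:
        return 0
    thr = threshold_otsu(smoothed)
    if strategy == "components":
        _, n = ndimage.label(smoothed > thr, structure=np.ones((3, 3), dtype=int))
        return int(n)
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(min_separation))),
        threshold_abs=thr,
        exclude_border=False,
    )
    return int(peaks.shape[0])


def score_image(
    image,
    params: DetectionParams = DetectionParams(),
    k: int = 6,
    dark_threshold: float | None = None,
) -> dict:
    """Detect, fan, and score one image; returns a flat summary record."""
    detected = detect_ommatidia(image, params)
    fans = neighbor_fans(detected, k=k)
    scores = od_scores(fans)
    rec = {
        "n_detected": scores.n_detected,
        "n_interior": scores.n_interior,
        "distance_od": scores.distance_od,
        "angle_od": scores.angle_od,
        "composite_score": scores.composite_score,
    }
    if dark_threshold is not None:
        rec["necrotic_area_px2"] = necrotic_patch_area(image, dark_threshold)
    return rec
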