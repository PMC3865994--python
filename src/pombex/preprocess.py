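"""Shading correction and nucleus / background region detection.

The bright-field channel is first flattened by subtracting a disk-mean
filtered version of itself (local shading correction).  Background is
then found as the low-texture part of the image: Otsu's threshold on the
gradient-magnitude image separates flat background from the textured
cell regions.  Nuclei come from Otsu thresholding of the (shading
corrected) fluorescence channels; their mean bright-field intensity
``mu_N`` and the background mean ``mu_B`` drive the focus-gradient
correction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from skimage import filters, measure, morphology

from .exceptions import DegenerateHistogramError

# Fraction of the image a non-border-touching low-gradient component must
# cover to count as background; enclosed cell interiors are far smaller.
_MIN_BACKGROUND_COMPONENT_FRACTION = 0.01


@dataclass
class RegionMasks:
    """Background / nucleus masks plus per-nucleus summaries.

    ``background`` and ``nuclei`` are disjoint boolean rasters; centroids
    are ``(x, y)`` pixel coordinates of each nucleus component and
    ``nucleus_trans_means`` the mean bright-field intensity over each
    component (same ordering).
    """

    background: np.ndarray
    nuclei: np.ndarray
    nucleus_centroids: List[Tuple[float, float]] = field(default_factory=list)
    nucleus_trans_means: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.background & self.nuclei):
            raise ValueError("background and nucleus masks must be disjoint")


def disk_kernel(radius: int) -> np.ndarray:
    """Normalized disk averaging kernel of the given pixel radius."""
    footprint = morphology.disk(radius).astype(np.float64)
    return footprint / footprint.sum()


def shading_correct(image: np.ndarray, radius: int = 40) -> np.ndarray:
    """Subtract the local mean (disk kernel) from the image.

    Removes slowly varying illumination so that intensity thresholds are
    comparable across the field.  Reflect padding avoids the dark halo a
    zero-padded mean filter would leave at the borders.
    """
    image = np.asarray(image, dtype=np.float64)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if min(image.shape) < 2 * radius + 1:
        raise ValueError(
            f"image shape {image.shape} smaller than kernel diameter "
            f"{2 * radius + 1}"
        )
    padded = np.pad(image, radius, mode="reflect")
    local_mean = signal.fftconvolve(padded, disk_kernel(radius), mode="same")
    local_mean = local_mean[radius:-radius, radius:-radius]
    out = image - local_mean
    # FFT roundoff leaves ~1e-13 residue on perfectly flat fields, which
    # would read as phantom texture downstream; snap it to zero.
    eps = 1e-9 * max(float(np.abs(image).max()), 1.0)
    out[np.abs(out) < eps] = 0.0
    return out


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold of a sample: exact between-class-variance
    maximisation over the empirical histogram.

    Candidate thresholds are the midpoints between consecutive distinct
    sample values; the one maximising ``w0*w1*(m0 - m1)^2`` is returned
    (the lowest such midpoint on an exact tie).  Working on the exact
    sample rather than a fixed-bin histogram keeps the threshold
    independent of binning choices.  Raises
    :class:`DegenerateHistogramError` when the sample has no spread.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    n = v.size
    if n == 0 or v[-1] == v[0]:
        raise DegenerateHistogramError("histogram has a single value")
    split = np.nonzero(np.diff(v) > 0)[0]  # lower class is v[:i+1]
    csum = np.cumsum(v)
    k = split + 1.0
    w0 = k / n
    m0 = csum[split] / k
    m1 = (csum[-1] - csum[split]) / (n - k)
    between = w0 * (1.0 - w0) * (m0 - m1) ** 2
    j = int(np.argmax(between))
    return float((v[split[j]] + v[split[j] + 1]) / 2.0)


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude (the 'gradient image')."""
    return filters.sobel(np.asarray(image, dtype=np.float64))


def detect_background(trans: np.ndarray) -> np.ndarray:
    """Low-texture background mask of a shading-corrected trans image.

    Pixels whose Sobel gradient magnitude falls below the Otsu threshold
    of the gradient image are background candidates; of these, only
    connected components that touch the image border or cover at least
    1% of the frame are kept, so that flat cell interiors enclosed by the
    high-gradient membrane ring are not absorbed into the background.
    """
    grad = gradient_magnitude(trans)
    thr = otsu_threshold(grad)
    candidate = grad < thr
    # The trough line of a membrane ring is locally flat, producing a
    # 1-px low-gradient ridge that can bridge to the background
    # component; an opening removes such thin structures while leaving
    # the extended flat background intact.
    candidate = morphology.opening(candidate, morphology.disk(1))
    labels = measure.label(candidate, connectivity=2)
    if labels.max() == 0:
        return candidate  # empty mask
    keep = np.zeros(labels.max() + 1, dtype=bool)
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    keep[border_labels] = True
    counts = np.bincount(labels.ravel())
    keep |= counts >= _MIN_BACKGROUND_COMPONENT_FRACTION * labels.size
    keep[0] = False
    return keep[labels]


def detect_nuclei(fluor: Sequence[np.ndarray] | np.ndarray,
                  min_nucleus_area: float = 20.0,
                  ) -> Tuple[np.ndarray, List[Tuple[float, float]]]:
    """Threshold fluorescence channel(s) into a nucleus mask + centroids.

    Each channel is Otsu-thresholded independently; with two channels the
    union of the masks is used (the markers label the same nuclei, and a
    union is robust to one channel being dark).  Components smaller than
    ``min_nucleus_area`` are discarded.  Centroids are returned as
    ``(x, y)`` tuples.
    """
    channels = [fluor] if isinstance(fluor, np.ndarray) else list(fluor)
    if not channels:
        raise ValueError("at least one fluorescence channel is required")
    mask = np.zeros(np.asarray(channels[0]).shape, dtype=bool)
    for ch in channels:
        ch = np.asarray(ch, dtype=np.float64)
        thr = otsu_threshold(ch)
        mask |= ch > thr
    mask = morphology.remove_small_objects(
        mask, max_size=int(min_nucleus_area) - 1, connectivity=2)
    labels = measure.label(mask, connectivity=2)
    centroids = [(p.centroid[1], p.centroid[0])
                 for p in measure.regionprops(labels)]
    return mask, centroids


def build_region_masks(trans: np.ndarray, background: np.ndarray,
                       nuclei: Optional[np.ndarray] = None,
                       centroids: Optional[List[Tuple[float, float]]] = None,
                       ) -> RegionMasks:
    """Assemble a :class:`RegionMasks`, subtracting nuclei from background
    and summarising each nucleus component's bright-field intensity."""
    trans = np.asarray(trans, dtype=np.float64)
    background = np.asarray(background, dtype=bool)
    if nuclei is None:
        nuclei = np.zeros_like(background)
        centroids = []
    nuclei = np.asarray(nuclei, dtype=bool)
    background = background & ~nuclei

    labels = measure.label(nuclei, connectivity=2)
    props = measure.regionprops(labels, intensity_image=trans)
    if centroids is None:
        centroids = [(p.centroid[1], p.centroid[0]) for p in props]
    trans_means = [float(p.intensity_mean) for p in props]
    # Keep centroid ordering aligned with component ordering.
    if len(centroids) != len(trans_means):
        centroids = [(p.centroid[1], p.centroid[0]) for p in props]
    return RegionMasks(background=background, nuclei=nuclei,
                       nucleus_centroids=list(centroids),
                       nucleus_trans_means=trans_means)


def region_means(trans: np.ndarray, masks: RegionMasks) -> Tuple[float, float]:
    """Mean bright-field intensity over nuclei (``mu_N``) and background
    (``mu_B``)."""
    trans = np.asarray(trans, dtype=np.float64)
    if not masks.nuclei.any():
        raise ValueError("nucleus mask is empty")
    if not masks.background.any():
        raise ValueError("background mask is empty")
    mu_n = float(trans[masks.nuclei].mean())
    mu_b = float(trans[masks.background].mean())
    return mu_n, mu_b
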