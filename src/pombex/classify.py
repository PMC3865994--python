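"""Four-class pixel classification and ambiguous-pixel resolution.

After focus/contrast correction the bright-field image has cell
interiors brighter than the background and membranes darker, so pixels
split into four sets: background ``B`` (the low-texture mask from
preprocessing), membrane ``M`` (below an adaptive threshold computed
from the sub-histogram of pixels darker than the background mean),
interior ``C`` (above the nucleus mean), and ambiguous ``X`` (the rest).
Ambiguous pixels are then resolved by an iterative distance-transform
region growing (similar in spirit to watershed) in which background and
interior expand into ``X`` while the membrane set acts as a barrier.
The resolved interior components seed the snakes and the membrane set
becomes the edge map driving the gradient-vector-flow field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from scipy.ndimage import gaussian_filter

from .contour import MIN_VERTICES, SnakeContour, resample_closed
from .exceptions import DegenerateHistogramError
from .preprocess import otsu_threshold

logger = logging.getLogger(__name__)

BACKGROUND = 0
INTERIOR = 1
MEMBRANE = 2
AMBIGUOUS = 3

CLASS_NAMES = {BACKGROUND: "background", INTERIOR: "interior",
               MEMBRANE: "membrane", AMBIGUOUS: "ambiguous"}


@dataclass
class PixelClassMap:
    """Per-pixel class labels plus the thresholds used (for provenance)."""

    labels: np.ndarray
    t_membrane: Optional[float] = None
    t_interior: Optional[float] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = np.isin(self.labels, (BACKGROUND, INTERIOR, MEMBRANE,
                                      AMBIGUOUS))
        if not valid.all():
            raise ValueError("labels contain values outside the four classes")

    def mask(self, cls: int) -> np.ndarray:
        return self.labels == cls

    @property
    def n_ambiguous(self) -> int:
        return int(np.count_nonzero(self.labels == AMBIGUOUS))


def classify_pixels(image: np.ndarray, background_mask: np.ndarray,
                    mu_n: float, mu_b: float) -> PixelClassMap:
    """Assign every pixel to background / membrane / interior / ambiguous.

    Membrane pixels are those below the Otsu threshold of the
    sub-histogram of pixels darker than ``mu_b``; interior pixels are
    strictly brighter than ``mu_n``.  Precedence on overlap is
    background, then membrane, then interior; everything else is
    ambiguous.
    """
    image = np.asarray(image, dtype=np.float64)
    background_mask = np.asarray(background_mask, dtype=bool)
    if background_mask.shape != image.shape:
        raise ValueError("background mask shape mismatch")

    dark = image[image < mu_b]
    t_membrane: Optional[float] = None
    if dark.size == 0:
        logger.warning("no pixels darker than the background mean; "
                       "membrane set is empty (blank field?)")
        membrane = np.zeros_like(background_mask)
    else:
        try:
            t_membrane = otsu_threshold(dark)
        except DegenerateHistogramError:
            logger.warning("dark sub-histogram degenerate; membrane empty")
            membrane = np.zeros_like(background_mask)
        else:
            membrane = image < t_membrane

    labels = np.full(image.shape, AMBIGUOUS, dtype=np.uint8)
    interior = image > mu_n
    labels[interior] = INTERIOR
    labels[membrane] = MEMBRANE
    labels[background_mask] = BACKGROUND
    return PixelClassMap(labels=labels, t_membrane=t_membrane, t_interior=mu_n)


def _remove_isolated(mask: np.ndarray) -> np.ndarray:
    return morphology.remove_small_objects(mask, max_size=1, connectivity=2)


def smooth_classes(cmap: PixelClassMap, se_radius: int = 1) -> PixelClassMap:
    """Morphological close-open of each class and isolated-pixel removal.

    Each of B, M, C is smoothed independently with a disk structuring
    element; pixels vacated by smoothing become ambiguous, and collisions
    are resolved with precedence B > M > C.
    """
    selem = morphology.disk(se_radius)
    smoothed = {}
    for cls in (BACKGROUND, MEMBRANE, INTERIOR):
        m = cmap.mask(cls)
        m = morphology.opening(morphology.closing(m, selem), selem)
        smoothed[cls] = _remove_isolated(m)
    labels = np.full(cmap.labels.shape, AMBIGUOUS, dtype=np.uint8)
    labels[smoothed[INTERIOR]] = INTERIOR
    labels[smoothed[MEMBRANE]] = MEMBRANE
    labels[smoothed[BACKGROUND]] = BACKGROUND
    return PixelClassMap(labels=labels, t_membrane=cmap.t_membrane,
                         t_interior=cmap.t_interior)


def _distance_to(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance to the nearest True pixel (inf if mask empty)."""
    if not mask.any():
        return np.full(mask.shape, np.inf)
    return ndimage.distance_transform_edt(~mask)


def resolve_ambiguous(cmap: PixelClassMap,
                      record_steps: bool = False) -> PixelClassMap | tuple:
    """Grow background and interior into the ambiguous set.

    Iteratively: compute Euclidean distance transforms ``D_b``, ``D_c``,
    ``D_m`` of the three resolved sets, then reassign each ambiguous
    pixel to background if ``D_b <= D_c`` and ``D_b < D_m`` (ties go to
    background) or to interior if ``D_c < D_b`` and ``D_c < D_m``;
    repeat until the ambiguous set stops changing.  Pixels that remain
    ambiguous (closer to membrane than to either region) are assigned to
    membrane on exit, so the result has no ambiguous pixels.

    Only ambiguous pixels are ever relabelled, so the procedure
    terminates in at most ``|X_0|`` iterations.

    With ``record_steps=True`` also returns the list of label rasters
    after each iteration.
    """
    labels = cmap.labels.copy()
    steps: List[np.ndarray] = []
    while True:
        amb = labels == AMBIGUOUS
        if not amb.any():
            break
        d_b = _distance_to(labels == BACKGROUND)
        d_c = _distance_to(labels == INTERIOR)
        d_m = _distance_to(labels == MEMBRANE)
        to_b = amb & (d_b <= d_c) & (d_b < d_m)
        to_c = amb & (d_c < d_b) & (d_c < d_m)
        if not (to_b.any() or to_c.any()):
            break
        labels[to_b] = BACKGROUND
        labels[to_c] = INTERIOR
        if record_steps:
            steps.append(labels.copy())
    labels[labels == AMBIGUOUS] = MEMBRANE
    if record_steps:
        steps.append(labels.copy())
    out = PixelClassMap(labels=labels, t_membrane=cmap.t_membrane,
                        t_interior=cmap.t_interior)
    return (out, steps) if record_steps else out


def initial_contours(cmap: PixelClassMap, min_area: float = 50.0,
                     spacing: float = 2.0) -> List[SnakeContour]:
    """Trace one closed contour per connected interior component.

    Components (8-connected) smaller than ``min_area`` are dropped; each
    remaining component's boundary is traced at the 0.5 level and
    resampled to roughly equal ``spacing`` (px) between vertices.
    """
    comp_labels = measure.label(cmap.mask(INTERIOR), connectivity=2)
    contours: List[SnakeContour] = []
    for prop in measure.regionprops(comp_labels):
        if prop.area < min_area:
            continue
        # Pad so components touching the frame still trace closed curves.
        minr, minc, maxr, maxc = prop.bbox
        comp = np.pad((comp_labels[minr:maxr, minc:maxc] == prop.label)
                      .astype(float), 1)
        traces = measure.find_contours(comp, 0.5)
        if not traces:
            continue
        trace = max(traces, key=len)
        # (row, col) in padded bbox frame -> (x, y) in image frame
        xy = np.column_stack([trace[:, 1] - 1 + minc, trace[:, 0] - 1 + minr])
        if np.allclose(xy[0], xy[-1]):
            xy = xy[:-1]
        verts = resample_closed(xy, spacing=spacing,
                                min_vertices=MIN_VERTICES)
        contours.append(SnakeContour(verts))
    return contours


def membrane_edge_map(cmap: PixelClassMap, sigma: float = 1.0) -> np.ndarray:
    """Edge map f(x, y) for the GVF field: the membrane indicator
    smoothed with a small Gaussian and rescaled to [0, 1]."""
    f = gaussian_filter(cmap.mask(MEMBRANE).astype(np.float64), sigma=sigma)
    fmax = f.max()
    if fmax > 0:
        f = f / fmax
    return f
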