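"""Focus-gradient correction by intensity complementation.

Under a tilted specimen plane, defocus ``z`` varies linearly across the
frame and flips the bright-field contrast polarity: positively defocused
cells have bright interiors and dark membranes, negatively defocused
cells the opposite, with the background mean ``mu_B`` as the axis of
symmetry.  The correction (i) models ``z`` as a bilinear plane
``z(x, y) = a + b*x + c*y`` fitted to nucleus centroids (using each
nucleus' bright-field intensity minus ``mu_B`` as a proxy for ``z``),
(ii) complements every pixel on the negative side, ``j = 2*mu_B - i``,
and (iii) linearly rescales the whole image about ``mu_B`` so the
nucleus-to-background contrast matches a dataset-wide target.  Because
the complement fixes ``mu_B``, intensity remains C0-continuous across
the ``z = 0`` line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

from .exceptions import PlaneFitError


@dataclass
class FocusModel:
    """Bilinear defocus plane plus the region statistics it was fitted to.

    ``coeffs = (a, b, c)`` define ``z(x, y) = a + b*x + c*y`` in
    intensity-difference units (nucleus minus background).  ``r_squared``
    is the fraction of nucleus-z variance the plane explains.
    """

    coeffs: Tuple[float, float, float]
    mu_b: float = 0.0
    mu_n: float = 0.0
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("plane coefficients must be finite")

    def z(self, x, y) -> np.ndarray:
        a, b, c = self.coeffs
        return a + b * np.asarray(x, float) + c * np.asarray(y, float)

    def z_grid(self, shape: Tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        return self.z(xx, yy)


def fit_focus_plane(samples: Iterable[Tuple[float, float, float]],
                    mu_b: float = 0.0, mu_n: float = 0.0) -> FocusModel:
    """Least-squares fit of ``z = a + b*x + c*y`` to ``(x, y, z)`` samples.

    Samples are nucleus centroids with ``z`` the nucleus' mean
    bright-field intensity minus ``mu_B``.  At least three non-collinear
    centroids are required; otherwise :class:`PlaneFitError` is raised
    and the pipeline falls back to global correction only.
    """
    pts = np.asarray(list(samples), dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise PlaneFitError(
            f"need >= 3 (x, y, z) samples, got {0 if pts.ndim != 2 else pts.shape[0]}"
        )
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    design = np.column_stack([np.ones_like(x), x, y])
    if np.linalg.matrix_rank(design) < 3:
        raise PlaneFitError("centroids are collinear; plane fit is rank-deficient")
    coeffs, *_ = np.linalg.lstsq(design, z, rcond=None)
    fitted = design @ coeffs
    ss_res = float(np.sum((z - fitted) ** 2))
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FocusModel(coeffs=(float(coeffs[0]), float(coeffs[1]),
                              float(coeffs[2])),
                      mu_b=mu_b, mu_n=mu_n, r_squared=r2)


def complement_negative_region(image: np.ndarray,
                               model: FocusModel) -> np.ndarray:
    """Complement intensities about ``mu_B`` where the plane is negative.

    Pixels with ``z(x, y) < 0`` map ``i -> 2*mu_B - i``; the rest are
    unchanged.  ``mu_B`` itself is a fixed point, so the map is an
    involution and keeps intensity continuous across the ``z = 0`` line
    wherever local intensity is near ``mu_B``.
    """
    image = np.asarray(image, dtype=np.float64)
    z = model.z_grid(image.shape)
    out = image.copy()
    neg = z < 0
    out[neg] = 2.0 * model.mu_b - image[neg]
    return out


def global_contrast_adjust(image: np.ndarray, mu_n: float, mu_b: float,
                           delta: float) -> np.ndarray:
    """Affine contrast normalisation anchored at the background mean.

    Maps ``I -> mu_B + (I - mu_B) * delta / (mu_N - mu_B)`` so that the
    nucleus-to-background difference of the output equals ``delta``.
    When ``mu_N < mu_B`` (globally inverted contrast) the negative scale
    factor also flips polarity, i.e. it complements the image as part of
    the same linear map.
    """
    if mu_n == mu_b:
        raise ValueError("mu_N == mu_B: contrast adjustment undefined; "
                         "caller should skip this step")
    image = np.asarray(image, dtype=np.float64)
    return mu_b + (image - mu_b) * (delta / (mu_n - mu_b))


def detect_focus_gradient(samples: Sequence[Tuple[float, float, float]],
                          image_shape: Tuple[int, int],
                          mu_b: float = 0.0, mu_n: float = 0.0,
                          min_r_squared: float = 0.3,
                          ) -> Tuple[bool, Optional[FocusModel]]:
    """Decide whether the field has a correctable focus gradient.

    True iff the fitted plane (a) takes both signs within the frame --
    otherwise there is nothing to complement -- and (b) explains at
    least ``min_r_squared`` of the nucleus-z variance, guarding against
    noise-driven flips.  Returns ``(decision, model)``; the model is
    ``None`` when fewer than three usable samples exist.
    """
    samples = list(samples)
    if len(samples) < 3:
        return False, None
    try:
        model = fit_focus_plane(samples, mu_b=mu_b, mu_n=mu_n)
    except PlaneFitError:
        return False, None
    _, b, c = model.coeffs
    if b == 0 and c == 0:
        return False, model
    z = model.z_grid(image_shape)
    has_both_signs = bool((z < 0).any() and (z >= 0).any())
    if not has_both_signs:
        return False, model
    if model.r_squared < min_r_squared:
        return False, model
    return True, model
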