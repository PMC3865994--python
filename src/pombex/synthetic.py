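"""Synthetic bright-field scenes of rod-shaped cells with ground truth.

Emulates the imaging situation the pipeline targets: spherocylindrical
(rod-shaped) fission-yeast cells on a flat background, with a dark
membrane ring and a bright interior, a nucleus that is slightly darker
than the surrounding cytoplasm in bright field and bright in a
fluorescence channel, additive Gaussian camera noise, and optionally a
linear focus-gradient plane that inverts the contrast polarity on one
side of the ``z = 0`` line.  Every scene ships its ground truth:
per-cell instance masks, nucleus mask/centers, the exact
background/interior/membrane class map, and the embedded focus plane.

Noiseless intensity levels (all relative to the background level
``mu_B``): membrane ring ``mu_B - membrane_depth``, cytoplasm
``mu_B + interior_lift``, nucleus ``mu_B + nucleus_lift``.  With the
defaults (30 / 30 / 20) the measured nucleus-to-background contrast is
+20 and interior pixels sit 10 units above the nucleus mean, so the
downstream ``i > mu_N`` interior rule holds by construction.  Cells are
rendered on a 4x supersampled grid and block-averaged, giving
anti-aliased sub-pixel edges.  Interior texture (correlated speckle with
amplitude proportional to the noise sigma) makes cells separable from
the flat background by gradient thresholding, as real cytoplasm is.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .classify import (AMBIGUOUS, BACKGROUND, INTERIOR, MEMBRANE,
                       PixelClassMap)
from .contour import SnakeContour, mask_to_contour
from .exceptions import PlacementError
from .io import FieldImages

_SUPERSAMPLE = 4
_FLUOR_BASELINE = 5.0
_FLUOR_AMPLITUDE = 120.0
_FLUOR_NOISE = 2.0


@dataclass
class SceneSpec:
    """Parameters of one synthetic field of view.

    Lengths are in microns (converted by ``um_per_px``); widths and radii
    in pixels.  ``seed`` fully determines the scene.
    """

    shape: Tuple[int, int] = (512, 512)
    n_cells: int = 12
    length_um: Tuple[float, float] = (7.0, 14.0)
    um_per_px: float = 0.2
    width_px: float = 17.0
    membrane_width_px: float = 3.0
    membrane_depth: float = 30.0
    interior_lift: float = 30.0
    nucleus_lift: float = 20.0
    background_level: float = 120.0
    noise_sigma: float = 3.0
    texture_factor: float = 2.0
    focus_plane: Optional[Tuple[float, float, float]] = None
    nucleus_radius_px: float = 4.0
    nucleus_fraction: float = 1.0
    septation_fraction: float = 0.0
    min_gap_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if not (0.0 <= self.nucleus_fraction <= 1.0):
            raise ValueError("nucleus_fraction must be in [0, 1]")
        if self.membrane_width_px >= self.width_px / 2:
            raise ValueError("membrane ring wider than the cell half-width")


@dataclass
class Scene:
    """A generated field plus its ground truth."""

    images: FieldImages
    instances: np.ndarray            # 0 = background, k = cell k
    nucleus_mask: np.ndarray
    nucleus_centers: List[Tuple[float, float]]
    class_map: PixelClassMap         # exact B/C/M truth partition
    spec: SceneSpec
    plane: Optional[Tuple[float, float, float]] = None
    cells: List[dict] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return int(self.instances.max())

    def instance_mask(self, label: int) -> np.ndarray:
        return self.instances == label


def _point_segment_distance(points: np.ndarray, center: np.ndarray,
                            axis: np.ndarray, half_len: float) -> np.ndarray:
    """Distance from (n, 2) points to a segment through ``center`` along
    unit ``axis`` with half-length ``half_len``; also returns the axial
    coordinate t."""
    rel = points - center
    t = rel @ axis
    tc = np.clip(t, -half_len, half_len)
    closest = center + tc[:, None] * axis
    return np.hypot(*(points - closest).T), t


def _segments_too_close(c1, a1, h1, c2, a2, h2, min_dist: float) -> bool:
    """Conservative segment-segment proximity via dense endpoint sampling."""
    s1 = c1 + np.linspace(-h1, h1, 25)[:, None] * a1
    s2 = c2 + np.linspace(-h2, h2, 25)[:, None] * a2
    d1, _ = _point_segment_distance(s1, c2, a2, h2)
    d2, _ = _point_segment_distance(s2, c1, a1, h1)
    return min(d1.min(), d2.min()) < min_dist


def _place_cells(spec: SceneSpec, rng: np.random.Generator,
                 max_attempts: int = 4000) -> List[dict]:
    """Rejection-sample non-overlapping rod placements."""
    h, w = spec.shape
    lmin = spec.length_um[0] / spec.um_per_px
    lmax = spec.length_um[1] / spec.um_per_px
    cells: List[dict] = []
    attempts = 0
    n_sept = int(round(spec.septation_fraction * spec.n_cells))
    while len(cells) < spec.n_cells and attempts < max_attempts:
        attempts += 1
        length = rng.uniform(lmin, lmax)
        theta = rng.uniform(0, np.pi)
        axis = np.array([np.cos(theta), np.sin(theta)])
        half = max((length - spec.width_px) / 2.0, 0.0)
        margin = spec.width_px / 2.0 + 2.0
        span = half * np.abs(axis)
        lo = margin + span
        hi = np.array([w, h]) - 1 - margin - span
        if np.any(hi <= lo):
            continue
        center = rng.uniform(lo, hi)
        min_dist = spec.width_px + spec.min_gap_px
        if any(_segments_too_close(center, axis, half, c["center"],
                                   c["axis"], c["half"], min_dist)
               for c in cells):
            continue
        cells.append({"center": center, "axis": axis, "half": half,
                      "length": length, "septating": len(cells) < n_sept})
    if len(cells) < spec.n_cells:
        raise PlacementError(
            f"placed only {len(cells)} of {spec.n_cells} cells after "
            f"{max_attempts} attempts"
        )
    return cells


def _downsample(arr: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    h, w = shape
    ss = _SUPERSAMPLE
    return arr.reshape(h, ss, w, ss).mean(axis=(1, 3))


def generate_scene(spec: SceneSpec) -> Scene:
    """Render one bright-field scene with ground truth (pure function of
    ``spec``, including the seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    cells = _place_cells(spec, rng)

    h_ss, w_ss = h * _SUPERSAMPLE, w * _SUPERSAMPLE
    body_ss = np.zeros((h_ss, w_ss), dtype=bool)
    interior_ss = np.zeros((h_ss, w_ss), dtype=bool)
    instance_ss = np.zeros((h_ss, w_ss), dtype=np.int32)

    r_out = spec.width_px / 2.0
    r_in = r_out - spec.membrane_width_px
    next_label = 1
    nucleus_sites: List[Tuple[np.ndarray, int]] = []  # (center, instance)

    for cell in cells:
        # Work on the cell's supersampled bounding box only.
        reach = cell["half"] + r_out + 2.0
        x0 = max(int((cell["center"][0] - reach) * _SUPERSAMPLE), 0)
        x1 = min(int((cell["center"][0] + reach) * _SUPERSAMPLE) + 2, w_ss)
        y0 = max(int((cell["center"][1] - reach) * _SUPERSAMPLE), 0)
        y1 = min(int((cell["center"][1] + reach) * _SUPERSAMPLE) + 2, h_ss)
        xs = (np.arange(x0, x1) + 0.5) / _SUPERSAMPLE - 0.5
        ys = (np.arange(y0, y1) + 0.5) / _SUPERSAMPLE - 0.5
        xx, yy = np.meshgrid(xs, ys)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        box = np.s_[y0:y1, x0:x1]
        d, t = _point_segment_distance(pts, cell["center"], cell["axis"],
                                       cell["half"])
        d = d.reshape(xx.shape)
        t = t.reshape(xx.shape)
        body = d <= r_out
        interior = d <= r_in
        if cell["septating"]:
            septum = np.abs(t) <= spec.membrane_width_px / 2.0
            interior = interior & ~septum
            labels = (next_label, next_label + 1)
            instance_ss[box][body & (t < 0)] = labels[0]
            instance_ss[box][body & (t >= 0)] = labels[1]
            offset = max(cell["half"] / 2.0, r_out)
            for sign, lab in zip((-1, 1), labels):
                nucleus_sites.append(
                    (cell["center"] + sign * offset * cell["axis"], lab))
            next_label += 2
        else:
            instance_ss[box][body] = next_label
            nucleus_sites.append((cell["center"], next_label))
            next_label += 1
        body_ss[box] |= body
        interior_ss[box] |= interior

    # Which instances carry a fluorescent nucleus.
    n_instances = next_label - 1
    n_fluor = int(round(spec.nucleus_fraction * len(nucleus_sites)))
    fluor_idx = set(rng.permutation(len(nucleus_sites))[:n_fluor].tolist())

    nucleus_ss = np.zeros((h_ss, w_ss), dtype=bool)
    for center, _ in nucleus_sites:
        r_ss = spec.nucleus_radius_px + 1.0
        x0 = max(int((center[0] - r_ss) * _SUPERSAMPLE), 0)
        x1 = min(int((center[0] + r_ss) * _SUPERSAMPLE) + 2, w_ss)
        y0 = max(int((center[1] - r_ss) * _SUPERSAMPLE), 0)
        y1 = min(int((center[1] + r_ss) * _SUPERSAMPLE) + 2, h_ss)
        xs = (np.arange(x0, x1) + 0.5) / _SUPERSAMPLE - 0.5
        ys = (np.arange(y0, y1) + 0.5) / _SUPERSAMPLE - 0.5
        bx, by = np.meshgrid(xs, ys)
        dx = bx - center[0]
        dy = by - center[1]
        nucleus_ss[y0:y1, x0:x1] |= \
            (dx * dx + dy * dy) <= spec.nucleus_radius_px ** 2
    nucleus_ss &= interior_ss

    body_cov = _downsample(body_ss.astype(float), spec.shape)
    interior_cov = _downsample(interior_ss.astype(float), spec.shape)
    nucleus_cov = _downsample(nucleus_ss.astype(float), spec.shape)
    ring_cov = np.clip(body_cov - interior_cov, 0.0, 1.0)

    mu_b = spec.background_level
    trans = (mu_b
             + spec.interior_lift * np.clip(interior_cov - nucleus_cov, 0, 1)
             + spec.nucleus_lift * nucleus_cov
             - spec.membrane_depth * ring_cov)

    # Correlated interior speckle; amplitude tied to the noise level so a
    # noiseless spec stays exactly piecewise-constant.
    if spec.noise_sigma > 0 and spec.texture_factor > 0:
        speckle = gaussian_filter(rng.standard_normal(spec.shape), 1.5)
        speckle /= max(speckle.std(), 1e-12)
        trans = trans + (spec.texture_factor * spec.noise_sigma
                         * speckle * interior_cov)

    if spec.noise_sigma > 0:
        trans = trans + rng.normal(0.0, spec.noise_sigma, spec.shape)

    # Fluorescence channel: Gaussian blobs at the flagged nuclei.
    sigma_n = spec.nucleus_radius_px / 1.5
    fluor = np.full(spec.shape, _FLUOR_BASELINE)
    yy_px, xx_px = np.mgrid[0:h, 0:w]
    fluor_centers: List[Tuple[float, float]] = []
    for i, (center, _) in enumerate(nucleus_sites):
        if i not in fluor_idx:
            continue
        fluor_centers.append((float(center[0]), float(center[1])))
        r2 = (xx_px - center[0]) ** 2 + (yy_px - center[1]) ** 2
        fluor = fluor + _FLUOR_AMPLITUDE * np.exp(-r2 / (2 * sigma_n ** 2))
    if spec.noise_sigma > 0:
        fluor = fluor + rng.normal(0.0, _FLUOR_NOISE, spec.shape)

    # Truth class partition at pixel resolution.
    class_labels = np.full(spec.shape, BACKGROUND, dtype=np.uint8)
    class_labels[interior_cov >= 0.5] = INTERIOR
    class_labels[ring_cov >= 0.5] = MEMBRANE
    class_map = PixelClassMap(labels=class_labels)

    # Instance labels at pixel resolution (majority vote of subpixels).
    instances = np.zeros(spec.shape, dtype=np.int32)
    for lab in range(1, n_instances + 1):
        cov = _downsample((instance_ss == lab).astype(float), spec.shape)
        instances[cov >= 0.5] = lab

    nucleus_mask = nucleus_cov >= 0.5

    scene = Scene(images=FieldImages(trans=trans, fluor=[fluor]),
                  instances=instances, nucleus_mask=nucleus_mask,
                  nucleus_centers=fluor_centers, class_map=class_map,
                  spec=spec, plane=None, cells=cells)
    if spec.focus_plane is not None:
        scene = apply_focus_plane(scene, spec.focus_plane)
    return scene


def apply_focus_plane(scene: Scene,
                      plane: Tuple[float, float, float]) -> Scene:
    """Invert contrast polarity on the negative side of a focus plane.

    For pixels with ``a + b*x + c*y < 0`` the bright-field deviation from
    the background level is negated (interior becomes darker than
    background, membrane brighter) -- exactly the distortion the focus
    corrector must undo.  Applying the same plane twice restores the
    original image bit-identically (double negation).
    """
    a, b, c = plane
    h, w = scene.images.trans.shape
    yy, xx = np.mgrid[0:h, 0:w]
    z = a + b * xx + c * yy
    mu_b = scene.spec.background_level
    trans = scene.images.trans.copy()
    neg = z < 0
    trans[neg] = 2.0 * mu_b - trans[neg]
    images = FieldImages(trans=trans, fluor=[f.copy()
                                             for f in scene.images.fluor])
    return replace(scene, images=images, plane=(float(a), float(b), float(c)))


# ---------------------------------------------------------------------------
# Named presets mirroring common fission-yeast phenotypes.

def scene_preset(name: str, seed: int = 0, **overrides) -> SceneSpec:
    """Named SceneSpec presets: short rods (``wildtype``), elongated rods
    (``cdc``), mixed sizes (``mixed``), septating pairs (``septating``),
    and ``gradient`` (wildtype with an embedded sign-changing focus
    plane)."""
    presets: Dict[str, dict] = {
        "wildtype": dict(n_cells=25, length_um=(7.0, 12.0)),
        "cdc": dict(n_cells=12, length_um=(14.0, 24.0)),
        "mixed": dict(n_cells=20, length_um=(5.0, 18.0),
                      nucleus_fraction=0.8),
        "septating": dict(n_cells=14, length_um=(9.0, 14.0),
                          septation_fraction=0.5),
        "gradient": dict(n_cells=25, length_um=(7.0, 12.0),
                         focus_plane=(-256.0, 1.0, 0.0)),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(presets)}")
    params = dict(presets[name])
    params.update(overrides)
    return SceneSpec(seed=seed, **params)


# ---------------------------------------------------------------------------
# Labelled contours for validator training.

def _cut_mask(mask: np.ndarray, center: np.ndarray, axis: np.ndarray,
              keep_sign: int) -> np.ndarray:
    h, w = mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    t = (xx - center[0]) * axis[0] + (yy - center[1]) * axis[1]
    return mask & ((t * keep_sign) > 0)


def scene_contrast(scene: Scene) -> float:
    """Measured nucleus-to-background contrast of a scene's trans image,
    used to normalise intensity features."""
    trans = scene.images.trans
    if scene.nucleus_mask.any():
        return float(trans[scene.nucleus_mask].mean()
                     - scene.spec.background_level)
    return scene.spec.nucleus_lift


def make_validation_training_set(seed: int = 0, n_scenes: int = 18,
                                 ) -> List[Tuple[np.ndarray, str]]:
    """Generate a labelled (features, verdict) set from synthetic scenes.

    Valid examples are ground-truth cell outlines; merged examples are
    the full body of a septating pair traced as one contour; partial
    examples are cells cut in half (the cut edge crosses bright
    cytoplasm, the signature of a truncated segmentation); artifacts are
    random blob contours over background.  Labels are ground truth by
    construction.
    """
    from .validate import extract_features

    rng = np.random.default_rng(seed)
    labeled: List[Tuple[np.ndarray, str]] = []
    for k in range(n_scenes):
        spec = SceneSpec(shape=(256, 256), n_cells=7,
                         septation_fraction=0.45,
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        scene = generate_scene(spec)
        trans = scene.images.trans
        mu_b = spec.background_level
        contrast = scene_contrast(scene)

        def feats(contour):
            return extract_features(contour, trans, mu_b,
                                    scene.nucleus_mask, contrast=contrast)

        all_labels = [lab for lab in range(1, scene.n_instances + 1)
                      if (scene.instances == lab).sum() > 50]
        # hull-merges of neighbouring cells (the other merge morphology)
        for lab in all_labels[:2]:
            pair = merged_pair_mask(scene, lab, all_labels)
            if pair is not None:
                labeled.append((feats(mask_to_contour(pair)), "merged"))
        label = 1
        for cell in scene.cells:
            if cell["septating"]:
                pair = (scene.instances == label) | \
                       (scene.instances == label + 1)
                if pair.any():
                    labeled.append((feats(mask_to_contour(pair)), "merged"))
                # Each compartment alone is a valid (small) cell.
                for lab in (label, label + 1):
                    m = scene.instances == lab
                    if m.sum() > 30:
                        labeled.append((feats(mask_to_contour(m)), "valid"))
                label += 2
            else:
                m = scene.instances == label
                if m.sum() > 30:
                    labeled.append((feats(mask_to_contour(m)), "valid"))
                    half = _cut_mask(m, cell["center"], cell["axis"],
                                     keep_sign=int(rng.choice([-1, 1])))
                    if half.sum() > 30:
                        labeled.append((feats(mask_to_contour(half)),
                                        "partial"))
                label += 1

        # Artifact blobs over background.
        background = scene.instances == 0
        yy, xx = np.mgrid[0:256, 0:256]
        for _ in range(4):
            for _attempt in range(50):
                cx, cy = rng.uniform(20, 236, size=2)
                r = rng.uniform(4, 10)
                blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
                if (blob & background).sum() > 0.9 * blob.sum():
                    labeled.append((feats(mask_to_contour(blob)), "artifact"))
                    break
    return labeled


def merged_pair_mask(scene: Scene, lab: int,
                     candidates) -> Optional[np.ndarray]:
    """A cell united with its nearest neighbour through a narrow bridge
    -- the waisted blob a snake that merged the two would enclose
    (characteristically low solidity)."""
    from scipy import ndimage as _ndi
    from skimage import measure as _measure
    from skimage.morphology import closing, convex_hull_image, disk

    m = scene.instances == lab
    candidates = [l for l in candidates if l != lab]
    if not candidates or not m.any():
        return None
    d = _ndi.distance_transform_edt(~m)
    partner = min(candidates, key=lambda l: d[scene.instances == l].min())
    union = m | (scene.instances == partner)
    gap = float(d[scene.instances == partner].min())
    pair = closing(union, disk(int(np.ceil(gap / 2.0)) + 2))
    if _measure.label(pair, connectivity=2).max() != 1:
        pair = convex_hull_image(union)   # distant partner: hull fallback
    return pair


def inject_error_records(scene: Scene, seed: int = 0, n_each: int = 2):
    """Deliberately wrong contour records for one scene.

    Emulates the three error classes a snake pipeline can produce --
    merged neighbouring cells (union of a cell with its nearest
    neighbour), partial segmentations (cells cut in half), and artifact
    contours over background -- with features extracted the same way the
    pipeline extracts them.  Used to benchmark the validation filter:
    ground truth says all of these are erroneous.
    """
    from .validate import make_record

    rng = np.random.default_rng(seed)
    trans = scene.images.trans
    mu_b = scene.spec.background_level
    contrast = scene_contrast(scene)
    h, w = trans.shape
    records = []

    labels = [lab for lab in range(1, scene.n_instances + 1)
              if (scene.instances == lab).sum() > 50]
    rng.shuffle(labels)

    # merged: the hull of a cell united with its nearest neighbour
    for lab in labels[:n_each]:
        pair = merged_pair_mask(scene, lab, labels)
        if pair is None:
            continue
        rec = make_record(mask_to_contour(pair), trans, mu_b,
                          scene.nucleus_mask, contrast=contrast)
        rec.verdict = "unvalidated"
        records.append(("merged", rec))

    # partial: cells truncated across their long axis (the typical way a
    # snake under-covers a rod); truncate the largest remaining cells so
    # the halves are cell-sized, as real truncation errors are
    from skimage import measure as _measure
    remaining = sorted(labels[n_each:],
                       key=lambda lab: -(scene.instances == lab).sum())
    for i, lab in enumerate(remaining[:n_each]):
        m = scene.instances == lab
        ys, xs = np.nonzero(m)
        center = np.array([xs.mean(), ys.mean()])
        props = _measure.regionprops(m.astype(np.uint8))[0]
        theta = props.orientation
        # regionprops orientation is against the row axis; convert to x/y
        axis = np.array([np.sin(theta), np.cos(theta)])
        # cut off-centre so the kept piece is clearly a fragment (~1/3)
        offset = center + 0.15 * props.axis_major_length * axis
        half = _cut_mask(m, offset, axis, keep_sign=1)
        if half.sum() < 50:
            half = _cut_mask(m, offset, axis, keep_sign=-1)
        if half.sum() < 50:
            continue
        rec = make_record(mask_to_contour(half), trans, mu_b,
                          scene.nucleus_mask, contrast=contrast)
        rec.verdict = "unvalidated"
        records.append(("partial", rec))

    # artifact: blobs over background
    yy, xx = np.mgrid[0:h, 0:w]
    background = scene.instances == 0
    made = 0
    for _ in range(200):
        if made >= n_each:
            break
        cx, cy = rng.uniform(20, w - 20), rng.uniform(20, h - 20)
        r = rng.uniform(5, 10)
        blob = (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2
        if (blob & background).sum() > 0.9 * blob.sum():
            rec = make_record(mask_to_contour(blob), trans, mu_b,
                              scene.nucleus_mask, contrast=contrast)
            rec.verdict = "unvalidated"
            records.append(("artifact", rec))
            made += 1
    return records
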