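"""End-to-end orchestration of the segmentation pipeline.

Stage order: shading correction -> background/nucleus detection ->
focus-gradient correction (adaptive complement + global contrast
normalisation) -> four-class pixel classification with distance-
transform resolution -> GVF snake evolution -> contour validation.
Degenerate-histogram conditions downgrade to warnings with documented
fallbacks (skip correction, ``mu_N = mu_B``), so a blank or unusual
field produces an empty result rather than a crash.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import classify as _classify
from . import focus as _focus
from . import preprocess as _pre
from . import snake as _snake
from .config import PipelineConfig
from .exceptions import DegenerateHistogramError, PlaneFitError
from .io import FieldImages
from .validate import CellRecord, ValidationModel, filter_contours, make_record

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Per-stage timings, counts and decisions of one pipeline run."""

    timings: Dict[str, float] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    config: Optional[dict] = None
    focus_gradient_detected: bool = False
    focus_plane: Optional[Tuple[float, float, float]] = None
    mu_n: float = 0.0
    mu_b: float = 0.0
    target_contrast: float = 0.0
    warnings: List[str] = field(default_factory=list)


def run(field_images: FieldImages, config: Optional[PipelineConfig] = None,
        model: Optional[ValidationModel] = None,
        ) -> Tuple[List[CellRecord], np.ndarray, RunReport]:
    """Segment one field of view.

    Returns all contour records (verdicts filled in when a validation
    model is supplied, ``"unvalidated"`` otherwise), the instance label
    mask of all final contours (record *i* has label *i+1*), and a
    :class:`RunReport`.  Deterministic for fixed inputs and config.
    """
    config = config or PipelineConfig()
    report = RunReport(config=config.to_dict())
    t_start = time.perf_counter()

    def tick(stage: str, t0: float) -> float:
        t1 = time.perf_counter()
        report.timings[stage] = t1 - t0
        return t1

    # --- preprocess ---------------------------------------------------
    t0 = time.perf_counter()
    trans = _pre.shading_correct(field_images.trans, config.shading_radius)
    try:
        background = _pre.detect_background(trans)
    except DegenerateHistogramError as exc:
        report.warnings.append(f"background detection degenerate: {exc}")
        logger.warning("background detection degenerate (%s); blank field?",
                       exc)
        return [], np.zeros(trans.shape, dtype=np.int32), report

    nuclei_mask = None
    centroids: Optional[list] = None
    use_fluor = config.use_fluorescence and len(field_images.fluor) > 0
    if config.use_fluorescence and not field_images.fluor:
        report.warnings.append("no fluorescence channels supplied; "
                               "falling back to mu_N = mu_B mode")
    if use_fluor:
        try:
            fluor_corrected = [_pre.shading_correct(f, config.shading_radius)
                               for f in field_images.fluor]
            nuclei_mask, centroids = _pre.detect_nuclei(
                fluor_corrected, min_nucleus_area=config.min_nucleus_area)
            if not nuclei_mask.any():
                raise DegenerateHistogramError("no nuclei above threshold")
        except DegenerateHistogramError as exc:
            report.warnings.append(f"nucleus detection failed: {exc}; "
                                   "using mu_N = mu_B")
            logger.warning("nucleus detection failed (%s); mu_N = mu_B", exc)
            nuclei_mask, centroids = None, None
            use_fluor = False

    masks = _pre.build_region_masks(trans, background, nuclei_mask, centroids)
    mu_b = float(trans[masks.background].mean()) if masks.background.any() \
        else float(trans.mean())
    if use_fluor and masks.nuclei.any():
        mu_n, mu_b = _pre.region_means(trans, masks)
    else:
        mu_n = mu_b  # no-fluorescence fallback: skip focus correction
    report.counts["nuclei"] = len(masks.nucleus_centroids)
    t0 = tick("preprocess", t0)

    # --- focus correction --------------------------------------------
    corrected = trans
    if use_fluor and config.focus_correction_mode != "off" and mu_n != mu_b:
        samples = [(x, y, m - mu_b) for (x, y), m in
                   zip(masks.nucleus_centroids, masks.nucleus_trans_means)]
        detected, fmodel = _focus.detect_focus_gradient(
            samples, trans.shape, mu_b=mu_b, mu_n=mu_n)
        apply_complement = (config.focus_correction_mode == "on") or detected
        if apply_complement and fmodel is None and len(samples) >= 3:
            try:
                fmodel = _focus.fit_focus_plane(samples, mu_b=mu_b, mu_n=mu_n)
            except PlaneFitError as exc:
                report.warnings.append(f"plane fit failed: {exc}; "
                                       "global correction only")
                fmodel = None
        report.focus_gradient_detected = bool(detected)
        if fmodel is not None:
            report.focus_plane = fmodel.coeffs
        if apply_complement and fmodel is not None:
            corrected = _focus.complement_negative_region(trans, fmodel)
            # Region statistics change under the complement; refresh.
            mu_n, mu_b = _pre.region_means(corrected, masks)

    delta = config.resolve_target_contrast(np.ptp(corrected))
    report.target_contrast = delta
    if mu_n != mu_b:
        corrected = _focus.global_contrast_adjust(corrected, mu_n, mu_b, delta)
        mu_n, mu_b = _pre.region_means(corrected, masks) if masks.nuclei.any()\
            else (mu_b + delta, mu_b)
    else:
        report.warnings.append("mu_N == mu_B; contrast adjustment skipped")
    report.mu_n, report.mu_b = mu_n, mu_b
    t0 = tick("focus_correct", t0)

    # --- pixel classification ----------------------------------------
    cmap = _classify.classify_pixels(corrected, masks.background, mu_n, mu_b)
    cmap = _classify.smooth_classes(cmap, config.smooth_radius)
    cmap = _classify.resolve_ambiguous(cmap)
    t0 = tick("pixel_classify", t0)

    # --- snake segmentation -------------------------------------------
    contours, label_mask = _snake.segment_cells(cmap, config)
    report.counts["initial_contours"] = len(contours)
    report.counts["final_contours"] = len(contours)
    t0 = tick("gvf_snake", t0)

    # --- validation ----------------------------------------------------
    contrast = (mu_n - mu_b) if mu_n != mu_b else 1.0
    records = [make_record(c, corrected, mu_b, masks.nuclei,
                           contrast=contrast)
               for c in contours]
    if model is not None:
        accepted, rejected = filter_contours(records, model)
        report.counts["accepted"] = len(accepted)
        report.counts["rejected"] = len(rejected)
    else:
        report.warnings.append("no validation model; contours unvalidated")
        logger.warning("no validation model supplied; skipping validation")
        report.counts["accepted"] = 0
        report.counts["rejected"] = 0
    tick("validate", t0)
    report.timings["total"] = time.perf_counter() - t_start
    return records, label_mask, report
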