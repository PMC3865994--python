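"""Pipeline configuration.

All tunable parameters of the segmentation pipeline live in
:class:`PipelineConfig`.  Snake/GVF weights default to the published
operating point (``lambda1 = lambda2 = 1``, ``alpha = 0.03``,
``beta = 0.2``, ``mu_gvf = 0.8``); everything else is exposed so a user
can adapt the pipeline to other magnifications or cameras.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class PipelineConfig:
    """Parameters controlling every stage of the segmentation pipeline.

    Attributes
    ----------
    shading_radius : int
        Radius (pixels) of the disk kernel used for local shading
        correction (image minus its disk-mean-filtered version).
    target_contrast : float or None
        Target nucleus-minus-background intensity difference enforced by
        the global contrast adjustment.  ``None`` means "0.15 x the input
        dynamic range", resolved per image at run time.
    focus_correction_mode : str
        ``auto`` (correct only when a focus gradient is detected), ``on``
        (always fit the plane and complement) or ``off``.
    use_fluorescence : bool
        When False the nucleus channel is ignored: ``mu_N`` is set equal
        to ``mu_B`` and focus correction is skipped entirely.
    min_cell_area : float
        Minimum area (px^2) of an interior component that seeds a snake.
    min_nucleus_area : float
        Minimum area (px^2) of a fluorescence component kept as a nucleus.
    smooth_radius : int
        Disk radius for the morphological close-open smoothing of the
        pixel-class maps.
    lambda1, lambda2 : float
        Relative weighting of internal vs external snake energy.
    alpha, beta : float
        Snake tension and rigidity.
    mu_gvf : float
        Regularisation weight of the gradient-vector-flow functional.
    gvf_iters, snake_iters : int
        Iteration caps of the GVF diffusion and the snake evolution.
        The GVF default (20) gives the force field a diffusion reach of
        ~3 px, matching the gap between the interior components that
        seed the snakes and the membrane ridge; longer diffusion
        flattens the near-ridge force and biases contours inward.
    gvf_dt : float or None
        Explicit GVF time step; ``None`` picks ``0.9 * 0.25 / mu_gvf``,
        safely inside the stability bound ``dt <= 1/(4 mu_gvf)``.
    snake_dt : float
        Snake evolution time step (semi-implicit scheme).
    contour_spacing : float
        Target vertex spacing (px) when (re)sampling contours.
    resample_every : int
        Snake iterations between vertex resampling passes.
    rng_seed : int
        Seed for every stochastic component (validator training etc.).
    """

    shading_radius: int = 40
    target_contrast: Optional[float] = None
    focus_correction_mode: str = "auto"
    use_fluorescence: bool = True
    min_cell_area: float = 50.0
    min_nucleus_area: float = 20.0
    smooth_radius: int = 1
    lambda1: float = 1.0
    lambda2: float = 1.0
    alpha: float = 0.03
    beta: float = 0.2
    mu_gvf: float = 0.8
    gvf_iters: int = 20
    snake_iters: int = 200
    gvf_dt: Optional[float] = None
    snake_dt: float = 1.0
    contour_spacing: float = 2.0
    resample_every: int = 10
    border_contact_threshold: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.focus_correction_mode not in ("auto", "on", "off"):
            raise ValueError(
                f"focus_correction_mode must be auto/on/off, "
                f"got {self.focus_correction_mode!r}"
            )
        for name in ("shading_radius", "min_cell_area", "min_nucleus_area",
                     "smooth_radius", "gvf_iters", "snake_iters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.mu_gvf <= 0:
            raise ValueError("mu_gvf must be strictly positive")
        if self.gvf_dt is not None and self.gvf_dt > 1.0 / (4.0 * self.mu_gvf):
            raise ValueError(
                f"gvf_dt={self.gvf_dt} violates the explicit-scheme "
                f"stability bound 1/(4*mu_gvf)={1.0 / (4.0 * self.mu_gvf)}"
            )

    @property
    def effective_gvf_dt(self) -> float:
        if self.gvf_dt is not None:
            return self.gvf_dt
        return 0.9 * 0.25 / self.mu_gvf

    def resolve_target_contrast(self, dynamic_range: float) -> float:
        """Return the target contrast, defaulting to 15% of the image's
        dynamic range when not set explicitly."""
        if self.target_contrast is not None:
            return float(self.target_contrast)
        return 0.15 * float(dynamic_range)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
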