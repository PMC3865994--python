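"""Exception types shared across pipeline stages."""


class DegenerateHistogramError(ValueError):
    """An intensity histogram has no contrast to threshold (e.g. a blank
    field, or a gradient image that is constant)."""


class PlaneFitError(ValueError):
    """The bilinear focus-plane fit is underdetermined (fewer than three
    usable nuclei, or all centroids collinear)."""


class DegenerateContourError(RuntimeError):
    """A snake contour degenerated below the minimum vertex count."""


class PlacementError(RuntimeError):
    """The synthetic-scene generator could not place the requested number
    of non-overlapping cells."""
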