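"""Exceptions shared across the pipeline."""


class MammodenseError(Exception):
    """Base class for all package errors."""


class NoThresholdFound(MammodenseError):
    """Breast/background separation found no threshold giving two components."""


class DegenerateHistogram(MammodenseError):
    """Breast intensities are constant or the stretch anchors coincide."""


class ShapeMismatch(MammodenseError):
    """Arrays that must share a grid do not."""


class InvalidParams(MammodenseError):
    """Segmentation parameters outside their configured boxes."""


class EmptyBreast(MammodenseError):
    """Operation requires a nonempty breast mask."""


class AnnotatorCountMismatch(MammodenseError):
    """Annotator-indexed structures disagree on the number of annotators."""


class InsufficientPatients(MammodenseError):
    """Too few patients to honor the requested split fractions."""


class DivergedLoss(MammodenseError):
    """Training loss became non-finite."""


class EmptyLoader(MammodenseError):
    """No training samples available."""


class DegenerateVariance(MammodenseError):
    """Correlation undefined: an input series has zero variance."""


class InsufficientSamples(MammodenseError):
    """Not enough masks to form the requested distributional distance."""


class UnsatisfiableSpec(MammodenseError):
    """Phantom constraints could not be met within the resampling budget."""
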