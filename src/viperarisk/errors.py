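"""Exception hierarchy for the viperarisk pipeline.

Every stage raises a subclass of :class:`ViperaRiskError` so callers (and the
CLI) can report which stage failed without catching bare exceptions.
"""


class ViperaRiskError(Exception):
    """Base class for all viperarisk errors."""


class ConfigurationError(ViperaRiskError):
    """Invalid configuration, missing predictor/layer names, unknown keys."""


class SamplingError(ViperaRiskError):
    """Requested more points than the grid can supply."""


class FittingError(ViperaRiskError):
    """A niche model failed to fit; the message names the algorithm."""


class EvaluationError(ViperaRiskError):
    """Split or metric computation impossible (e.g. single-class input)."""


class SelectionError(ViperaRiskError):
    """Predictor screening removed every candidate."""


class ThresholdingError(ViperaRiskError):
    """No usable occurrence cell when deriving the MPA threshold."""


class AlignmentError(ViperaRiskError):
    """Two rasters do not share grid geometry."""


class EnsembleError(ViperaRiskError):
    """Ensemble construction failed (e.g. non-positive member AUC)."""
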