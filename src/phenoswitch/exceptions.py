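"""Exception hierarchy. All package errors derive from :class:`PhenoswitchError`."""


class PhenoswitchError(Exception):
    """Base class for all phenoswitch errors."""


class ValidationError(PhenoswitchError, ValueError):
    """Invalid parameter, specification, or out-of-range input."""


class DegenerateDataError(ValidationError):
    """Data unusable for the requested statistic (too few points, zero variance)."""


class ParticleCSVError(PhenoswitchError, ValueError):
    """Malformed particle-diameter CSV; the message names the offending row."""


class StepSizeError(PhenoswitchError, RuntimeError):
    """Euler step too large: a single step changed M by more than 50%."""


class NotConvergedError(PhenoswitchError, RuntimeError):
    """An iterative fit did not converge and downstream use was refused."""


class FitError(PhenoswitchError, RuntimeError):
    """Grid-search fit failed (e.g. every grid point diverged)."""


class PipelineError(PhenoswitchError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
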