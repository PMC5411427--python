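"""Exception hierarchy shared across the pipeline."""


class VVLungError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VVLungError, ValueError):
    """A function received an argument outside its documented domain."""


class InsufficientDataError(VVLungError):
    """Not enough observations to compute the requested statistic."""


class IllConditionedFitError(VVLungError):
    """The least-squares design matrix is rank deficient or near singular."""


class UnidentifiableFitError(VVLungError):
    """The volume excursion of a cycle is too small to identify E2."""


class UndefinedIndexError(VVLungError):
    """The %E2 nonlinearity index is undefined (zero total tidal elastance)."""


class UndefinedKappaError(VVLungError):
    """Cohen's kappa is undefined because expected agreement equals 1."""


class MissingCalibratorError(VVLungError):
    """No calibrator-group Ct values exist for the requested lung side."""


class ConfigError(VVLungError):
    """A configuration file violates the documented schema."""


class InvalidPlanError(VVLungError):
    """A statistical-test plan names an unknown test."""
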