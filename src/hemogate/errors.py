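"""Package-wide exception types."""


class HemogateError(Exception):
    """Base class for all package errors."""


class SizingError(HemogateError):
    """Requested lesion geometry is incompatible with the phantom grid."""


class DegenerateScanError(HemogateError):
    """Skull stripping produced an empty brain mask."""


class OutOfFieldError(HemogateError):
    """Lesion voxels fall outside the fixed resampling/cropping grid."""


class NoLesionError(HemogateError):
    """An operation that requires a nonempty lesion mask received an empty one."""


class StratificationError(HemogateError):
    """A split or fold cannot preserve class representation."""


class BalancingError(HemogateError):
    """Class balancing was requested on single-class data."""


class SeparationError(HemogateError):
    """Logistic fit failed due to (quasi-)complete separation."""


class UndefinedMetricError(HemogateError):
    """A metric's denominator is zero and the value is undefined."""


class DegenerateTestError(HemogateError):
    """A statistical comparison has zero variance and no distribution."""


class ModelUsageError(HemogateError):
    """A model was used before training or with mismatched inputs."""


class ConfigError(HemogateError):
    """Configuration failed validation; ``errors`` lists every violation."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
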