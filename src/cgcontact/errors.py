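"""Exception and warning types shared across the package."""


class CgContactError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CgContactError):
    """A configuration file is invalid (overlapping regions, bad references...)."""


class TrajectoryFormatError(CgContactError):
    """A trajectory file violates the expected format."""


class TopologyLookupError(CgContactError, KeyError):
    """A residue index, region, anchor or special set could not be resolved."""


class InputError(CgContactError, ValueError):
    """Invalid argument combination at an analysis entry point."""


class ConditioningError(CgContactError):
    """A numerical problem is too degenerate to solve (e.g. collinear fit atoms)."""


class ConstructionError(CgContactError):
    """Synthetic system could not be packed without hard-sphere overlap."""


class UndefinedStatisticError(CgContactError):
    """A statistic was requested on an empty sample (e.g. lifetimes of no events)."""


class PipelineError(CgContactError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


class CalibrationWarning(UserWarning):
    """Calibration produced a suspicious (e.g. non-monotone) result."""
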