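"""Exception taxonomy.

Every failure mode a batch screen has to isolate gets its own type so
the pipeline can attach a machine-readable reject reason instead of a
bare traceback.
"""


class Co2ScreenError(Exception):
    """Base class for all package errors."""


class InputError(Co2ScreenError):
    """Unreadable, empty or malformed user input."""


class EmptyInputError(InputError):
    """An input file yielded zero valid records."""


class FormatError(InputError):
    """A structure file violates its format; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PatternError(Co2ScreenError):
    """The nucleophilic structure pattern could not be assigned."""


class PatternAbsentError(PatternError):
    """No carbanionic site (carbon with formal charge -1) present."""


class PatternMismatchError(PatternError):
    """A carbanionic site exists but lacks exactly two carbon neighbors."""


class AmbiguousPatternError(PatternError):
    """More than one candidate carbanionic site; never auto-picked."""


class GeometryError(Co2ScreenError):
    """Embedding failure or degenerate geometry."""


class DegenerateGeometryError(GeometryError):
    """A geometric operation received no usable atoms."""


class BackendError(Co2ScreenError):
    """Electronic-structure backend failures."""


class CapabilityError(BackendError):
    """Backend asked for a capability it does not declare."""


class ConvergenceError(BackendError):
    """Engine did not converge; carries engine diagnostics."""


class ParseError(Co2ScreenError):
    """Engine output file truncated or malformed; names the section."""


class MissingPropertyError(ParseError):
    """A requested property section is absent from the output file."""


class ConsistencyError(Co2ScreenError):
    """Quantities combined across incompatible settings presets."""


class ModelingError(Co2ScreenError):
    """Statistical-modeling failures."""


class CollinearityError(ModelingError):
    """Rank-deficient design matrix; names the offending features."""

    def __init__(self, features):
        self.features = list(features)
        super().__init__(f"collinear features: {', '.join(self.features)}")


class SplitError(ModelingError):
    """Invalid train/test or cross-validation partition."""


class FeatureError(ModelingError):
    """A model feature is missing from the supplied descriptor row."""


class DegenerateInputError(ModelingError):
    """Regression input with no variance (e.g. constant predictor)."""


class RegistryError(Co2ScreenError):
    """Unknown fixture case or output dialect."""


class SpecError(Co2ScreenError):
    """Invalid synthetic-data specification."""


class PipelineError(Co2ScreenError):
    """Workflow-level configuration or orchestration failure."""
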