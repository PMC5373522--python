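"""Exception hierarchy for the aecg package.

Every error raised deliberately by the package derives from :class:`AecgError`
so callers (in particular the pipeline, which logs and skips bad records) can
catch one base class.
"""


class AecgError(Exception):
    """Base class for all aecg errors."""


class LeadError(AecgError):
    """Missing, unknown, or wrongly ordered ECG leads."""


class EcgParseError(AecgError):
    """Non-numeric or non-finite sample values in an ECG file."""


class CohortError(AecgError):
    """Malformed per-patient metadata table (e.g. duplicate subject ids)."""


class DetectionError(AecgError):
    """QRS detection found no usable beats."""


class AveragingError(AecgError):
    """All beats rejected during signal averaging."""


class FiducialError(AecgError):
    """A wave landmark could not be located.

    ``landmark`` names the missing fiducial (e.g. ``"t_offset"``).
    """

    def __init__(self, landmark: str, message: str | None = None):
        self.landmark = landmark
        super().__init__(message or f"could not locate fiducial: {landmark}")


class ConfigError(AecgError):
    """Invalid configuration (bad matrix shape, nonsensical simulator parameters...)."""


class DomainError(AecgError):
    """Mathematically undefined request (zero-magnitude vector angle, ELI pole...)."""


class ScoringError(AecgError):
    """A risk-score input is missing or non-finite; names the offending feature."""


class FitError(AecgError):
    """Statistical model failed to converge or inputs are degenerate."""


class NetworkError(AecgError):
    """Graph-level contract violation (mismatched node sets etc.)."""


class PipelineError(AecgError):
    """End-to-end orchestration failure (zero usable inputs, empty join)."""
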