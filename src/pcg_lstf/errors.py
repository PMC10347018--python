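"""Exception and warning hierarchy for the pcg_lstf package."""


class PCGError(Exception):
    """Base class for all package errors."""


class FormatError(PCGError, ValueError):
    """An input file could not be parsed in its declared format."""


class DegenerateInputError(PCGError, ValueError):
    """An input is structurally valid but empty or otherwise unusable."""


class ParameterError(PCGError, ValueError):
    """A parameter violates an operation's precondition."""


class ManifestError(PCGError, ValueError):
    """A dataset manifest is malformed (duplicate paths, bad labels, ...)."""


class NoPeaksError(PCGError, ValueError):
    """Candidate peak detection found nothing above threshold."""


class SegmentationFailureError(PCGError, RuntimeError):
    """Extra-peak rejection could not produce a physiological peak train.

    Carries ``gap_ms`` — the (start, end) of the offending inter-peak gap.
    """

    def __init__(self, message: str, gap_ms: tuple[float, float] | None = None):
        super().__init__(message)
        self.gap_ms = gap_ms


class InsufficientPeaksError(PCGError, ValueError):
    """Fewer retained peaks than the labeling step requires."""


class InsufficientCyclesError(PCGError, ValueError):
    """Too few complete cardiac cycles for interval statistics."""


class PipelineError(PCGError, RuntimeError):
    """The end-to-end pipeline could not produce a report."""


class PCGWarning(UserWarning):
    """Base class for package warnings (degenerate inputs, tie-breaks...)."""
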