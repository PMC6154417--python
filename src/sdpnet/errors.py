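"""Exception hierarchy shared across the package."""


class SdpnetError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(SdpnetError):
    """Records in an aligned FASTA do not all have the same length."""


class IdentityError(SdpnetError):
    """Duplicate or missing sequence/leaf identifier."""


class ContentError(SdpnetError):
    """Disallowed character in a sequence record."""


class IndexingError(SdpnetError):
    """Column or reference-position index out of range (indices are 1-based)."""


class UndefinedColumnError(SdpnetError):
    """A per-column statistic is undefined (e.g. all-gap column)."""


class CladeError(SdpnetError):
    """Invalid clade assignment or tree for the requested operation."""


class RuleConfigError(SdpnetError):
    """A scrutiny rule cannot be resolved against the alignment."""


class SpecError(SdpnetError):
    """Infeasible synthetic-data specification."""


class PipelineError(SdpnetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
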