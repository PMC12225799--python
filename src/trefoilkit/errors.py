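"""Exception hierarchy shared across the pipeline stages."""


class TrefoilkitError(Exception):
    """Base class for all errors raised by trefoilkit."""


class InvalidParameterError(TrefoilkitError, ValueError):
    """A function argument violates its documented precondition."""


class ConfigError(TrefoilkitError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class StructureParseError(TrefoilkitError, ValueError):
    """A coordinate file could not be parsed; message names the line."""


class EmptyStructureError(StructureParseError):
    """A coordinate file contained no usable ATOM records."""


class TableDialectError(TrefoilkitError, ValueError):
    """A search-result table does not match the expected column layout."""


class TableParseError(TrefoilkitError, ValueError):
    """A search-result row failed numeric parsing; message names the row."""


class RaggedAlignmentError(TrefoilkitError, ValueError):
    """Aligned sequences of unequal length."""


class DuplicateLabelError(TrefoilkitError, ValueError):
    """Two alignment records share the same label."""


class UnderdeterminedError(TrefoilkitError, ValueError):
    """Too few points / taxa / columns for the requested computation."""


class AllGapColumnError(TrefoilkitError, ValueError):
    """Entropy requested for a column with no non-gap residues."""


class NewickParseError(TrefoilkitError, ValueError):
    """Malformed Newick input; message carries the reported location."""


class PipelineStageError(TrefoilkitError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
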