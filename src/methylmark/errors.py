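"""Exception hierarchy shared across the pipeline."""


class MethylmarkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethylmarkError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class FormatError(MethylmarkError, ValueError):
    """A malformed input file; the message carries file and row/column context."""


class DegenerateDataError(MethylmarkError, ValueError):
    """Input data too degenerate to fit (e.g. all values identical)."""


class NoProbesRetainedError(MethylmarkError, ValueError):
    """Every probe was removed by QC filtering."""


class DesignError(MethylmarkError, ValueError):
    """A rank-deficient or confounded design matrix."""


class StageError(MethylmarkError, RuntimeError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
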