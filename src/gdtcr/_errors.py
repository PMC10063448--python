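"""Exception hierarchy shared across the pipeline stages."""


class GdtcrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GdtcrError):
    """A simulation or pipeline configuration is invalid."""


class FormatError(GdtcrError):
    """An input file does not conform to the expected dialect."""


class UndefinedInputError(GdtcrError):
    """A statistic was requested on an input for which it is undefined."""


class PipelineError(GdtcrError):
    """A pipeline stage failed; the message names the stage."""
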