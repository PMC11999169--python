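"""Exception types shared across the pipeline."""


class KinopipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(KinopipeError):
    """A simulation or pipeline configuration violates its invariants."""


class FormatError(KinopipeError):
    """An input file does not conform to its documented format."""


class QCError(KinopipeError):
    """Quality control left nothing to analyze."""
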