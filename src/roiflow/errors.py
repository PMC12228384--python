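"""Exception types shared across the pipeline."""


class RoiflowError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(RoiflowError):
    """Invalid parameter or configuration value."""


class ParseError(RoiflowError):
    """Malformed input file; message carries the offending line number."""


class PipelineError(RoiflowError):
    """A stage failed; message names the stage and context."""
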