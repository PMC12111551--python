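"""Exception hierarchy for the pipeline."""


class PleioscanError(Exception):
    """Base class for all package errors."""


class ConfigError(PleioscanError):
    """Invalid configuration (bad dimensions, out-of-range parameters)."""


class FormatError(PleioscanError):
    """Malformed or incomplete input file."""


class StateError(PleioscanError):
    """Operation applied in the wrong pipeline state (e.g. double sign flip)."""


class PipelineError(PleioscanError):
    """A pipeline step produced an unusable result (e.g. zero SNP overlap)."""
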