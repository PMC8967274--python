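"""Exception hierarchy shared across pipeline stages."""


class ThermperfError(Exception):
    """Base class for all package errors."""


class ConfigError(ThermperfError):
    """Invalid simulation / model configuration."""


class DataError(ThermperfError):
    """Input records violate a stage precondition."""


class SchemaError(DataError):
    """A tabular input is missing or mistypes a required column."""


class ModelError(ThermperfError):
    """A statistical model cannot be fit as requested (e.g. rank deficiency)."""


class PipelineError(ThermperfError):
    """A pipeline stage cannot run, typically because an upstream artifact is missing."""
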