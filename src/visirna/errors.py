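"""Exception hierarchy shared across the pipeline."""


class VisirnaError(Exception):
    """Base class for all pipeline errors."""


class ParseError(VisirnaError, ValueError):
    """A file did not conform to its expected plain-text format."""


class TranslationError(VisirnaError, ValueError):
    """A coding sequence could not be translated (bad length, internal stop)."""


class SyntheticDataError(VisirnaError, ValueError):
    """A synthetic-data spec is infeasible or violated its own constraints."""


class ConfigError(VisirnaError, ValueError):
    """A run configuration contains unknown keys or invalid values."""
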