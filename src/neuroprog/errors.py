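"""Exception hierarchy shared across the package."""


class NeuroprogError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NeuroprogError):
    """A configuration value violates a documented bound."""


class GenerationError(NeuroprogError):
    """Synthetic-data generation failed (e.g. an atrophy block leaves the grid)."""


class DataError(NeuroprogError):
    """Input data violates a precondition (missing feature, empty visits, ...)."""


class EvaluationError(NeuroprogError):
    """An evaluation-protocol precondition failed (single class, degenerate metric, ...)."""
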