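"""Exception hierarchy shared across the pipeline.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class StressMmnError(Exception):
    """Base class for all package-specific errors."""


class ConstraintError(StressMmnError):
    """An infeasible paradigm/stimulus constraint set was requested."""


class ConfigError(StressMmnError):
    """Invalid or inconsistent configuration."""


class DataError(StressMmnError):
    """Input data do not satisfy a stage's preconditions."""
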