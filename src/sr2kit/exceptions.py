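"""Exception hierarchy.

All package errors derive from :class:`Sr2KitError` so callers can catch one
base class.  Schema/configuration problems are distinguished from statistical
failures (e.g. staircase non-convergence) because the CLI maps them to
different exit codes.
"""


class Sr2KitError(Exception):
    """Base class for all sr2kit errors."""


class ConfigurationError(Sr2KitError):
    """Inconsistent specification or configuration (bad track geometry, etc.)."""


class ValidationError(Sr2KitError):
    """A response or stimulus token outside the closed response set."""


class MalformedSessionError(Sr2KitError):
    """Trial data that do not form a valid track (wrong count, wrong TMRs)."""


class PairingError(Sr2KitError):
    """Colocated/separated results that cannot be paired (listener/run mismatch)."""


class NonConvergenceError(Sr2KitError):
    """Adaptive staircase failed to complete its reversals within the trial cap."""


class SchemaError(Sr2KitError):
    """Tabular input missing required columns, or empty."""


class DegenerateDesignError(Sr2KitError):
    """Singular regression/ANOVA design (constant covariate, missing cells)."""
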