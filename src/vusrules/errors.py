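"""Exception taxonomy.

All package exceptions derive from :class:`VusRulesError` so callers can
catch everything with one clause; the CLI maps subclasses to exit codes
(schema -> 2, statistical stage -> 3, I/O -> 4).
"""


class VusRulesError(Exception):
    """Base class for all errors raised by vusrules."""


class SchemaError(VusRulesError):
    """Input table violates the expected schema or vocabulary.

    Carries a ``rows`` attribute with per-row diagnostics when the failure
    is row-level (unknown tokens, out-of-range values).
    """

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows else []


class IntegrityError(VusRulesError):
    """Cross-record consistency violation (duplicates, dangling case ids)."""


class DomainError(VusRulesError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegenerateTableError(DomainError):
    """A contingency table with no observations at all."""


class InsufficientDataError(VusRulesError):
    """An analysis was requested on an empty (after filtering) input."""


class ConfigurationError(VusRulesError):
    """An unknown feature, outcome, or option name was requested."""


class DerivationError(VusRulesError):
    """Rule derivation is missing a required scan family."""
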