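"""Exception hierarchy shared by every module.

Errors are categorized so the command-line layer can map each class to a
distinct exit code: validation (malformed values), configuration (streams,
weights and config files that disagree with each other), lookup (references
to entities that do not exist), and limit (hard caps such as the
five-weight-set maximum).
"""


class RepurscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(RepurscoreError):
    """A value violates a contract (negative magnitude, bad span, ...)."""


class ConfigurationError(RepurscoreError):
    """Streams, weights or config entries are mutually inconsistent."""


class EntityLookupError(RepurscoreError):
    """A referenced entity (node, disease, link) does not exist."""


class LimitError(RepurscoreError):
    """A hard cardinality or size cap was exceeded."""
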