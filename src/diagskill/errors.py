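"""Exception hierarchy.

Validation problems (bad files, out-of-vocabulary categories, malformed
configs) and analysis problems (degenerate inputs a statistic cannot be
computed from) are kept distinct so the CLI can map them to exit codes.
"""


class DiagskillError(Exception):
    """Base class for all package errors."""


class SchemaError(DiagskillError):
    """A file or table does not have the required columns/structure."""


class VocabularyError(DiagskillError):
    """A category or aspect label is not part of the declared vocabulary."""


class DuplicateRecordError(DiagskillError):
    """Two records share the same (rater, item, aspect, session) key."""


class KeyCoverageError(DiagskillError):
    """A scored item is missing from the answer key."""


class ItemUniverseError(DiagskillError):
    """Two answer keys cover different item sets."""


class ConfigError(DiagskillError):
    """A simulation or pipeline configuration is invalid."""


class AnalysisError(DiagskillError):
    """A statistic is undefined for the given input (degenerate data)."""
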