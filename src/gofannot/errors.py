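"""Exception hierarchy shared across the package.

Every error raised by gofannot derives from :class:`GofannotError` so callers
(and the CLI) can distinguish package failures from programming errors.
"""


class GofannotError(Exception):
    """Base class for all gofannot errors."""


class ParseError(GofannotError):
    """A malformed input file (OBO stanza, GAF/TSV line, hit-table row)."""


class OntologyValidationError(GofannotError):
    """The ontology violates a structural contract (e.g. a cycle)."""


class UnknownTermError(GofannotError, KeyError):
    """A GO accession that is neither a canonical id nor a registered alt_id."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class ObsoleteTermError(GofannotError):
    """An operation that requires a live term was given an obsolete one."""


class UsageError(GofannotError):
    """Invalid arguments at the API level (empty inputs, missing universe...)."""


class UndefinedMetricError(GofannotError):
    """A metric has no defined value on this input (e.g. mean of zero genes)."""


class EmptyBenchmarkError(GofannotError):
    """No gold-standard gene overlaps the prediction universe."""
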