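"""Exception hierarchy shared across the package.

Every error raised deliberately by this package derives from
:class:`AdekbError`, so callers (and the CLI) can distinguish expected
domain failures from genuine bugs.
"""


class AdekbError(Exception):
    """Base class for all package errors."""


class VocabularyLoadError(AdekbError):
    """A vocabulary file violates a structural invariant (duplicate key,
    dangling mapping/ancestor endpoint, malformed row)."""


class UnknownConceptError(AdekbError):
    """A concept_id was requested that is not loaded in the store."""


class DomainError(AdekbError):
    """An argument is of the wrong kind (e.g. a non-RxNorm concept passed
    where a drug is required)."""


class ParseError(AdekbError):
    """A raw evidence or CDM file does not match its declared shape.

    Distinct from a mapping :class:`~adekb.etl.Rejection`, which is an
    expected coverage loss, not data corruption.
    """


class EtlError(AdekbError):
    """An ETL run cannot proceed (duplicate source/version without the
    replace flag, missing crosswalk, missing publication type, ...)."""


class AggregationError(AdekbError):
    """Conflicting per-pair statistics that cannot be aggregated
    (e.g. two different PRR values for one pair from one source)."""


class MintError(AdekbError):
    """A linkout was requested for which no annotation exists; dangling
    linkouts are forbidden."""


class NotFoundError(AdekbError):
    """An unknown linkout key or URL was passed to resolve()."""


class UsageError(AdekbError):
    """A query or report was requested with invalid arguments
    (no filters, overlapping overlap groups, unknown evidence types)."""
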