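"""Exception hierarchy.

Every error the library signals deliberately derives from
:class:`NeugraphError`, so callers (and the CLI) can distinguish domain
errors from programming bugs.
"""

from __future__ import annotations


class NeugraphError(Exception):
    """Base class for all errors raised by this package."""


class NotFoundError(NeugraphError):
    """A body id, cell type, or dataset entity does not exist in the store."""


class InputError(NeugraphError):
    """A query or edit argument is invalid (bad regex, unknown ROI, collision)."""


class IngestError(NeugraphError):
    """Raw bundle violates a schema or referential-integrity constraint.

    Carries the offending table and 0-based data row when known.
    """

    def __init__(self, message: str, *, table: str | None = None, row: int | None = None):
        loc = ""
        if table is not None:
            loc = f" [{table}" + (f", row {row}" if row is not None else "") + "]"
        super().__init__(message + loc)
        self.table = table
        self.row = row


class FormatError(NeugraphError):
    """A text format (e.g. SWC) is malformed; carries a 1-based line number."""

    def __init__(self, message: str, *, line: int | None = None):
        super().__init__(message + (f" (line {line})" if line is not None else ""))
        self.line = line


class UndefinedMetricError(NeugraphError):
    """A QC metric has an empty denominator (no links, empty ROI)."""


class SearchBudgetExceeded(NeugraphError):
    """Path search expanded more nodes than the configured cap.

    Raised instead of returning a silent partial answer.
    """

    def __init__(self, expanded: int, cap: int):
        super().__init__(f"path search expanded {expanded} nodes, exceeding the cap of {cap}")
        self.expanded = expanded
        self.cap = cap
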