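"""Exception hierarchy for hiertax.

All structural problems detected while *validating* are collected into a
:class:`~hiertax.model.ValidationReport`; exceptions are raised only when an
operation cannot produce a meaningful result.
"""

from __future__ import annotations


class HiertaxError(Exception):
    """Base class for all package-specific errors."""


class StructureError(HiertaxError):
    """A taxonomy/DAG construction precondition failed.

    Carries the offending :class:`~hiertax.model.ValidationReport` in
    ``report`` so callers can inspect individual violations.
    """

    def __init__(self, report, message: str | None = None):
        self.report = report
        super().__init__(message or "; ".join(v.message for v in report.violations))


class ConsistencyError(HiertaxError):
    """An encoded table violates the structural invariants of its model."""


class DelimiterError(HiertaxError):
    """A node id contains the materialized-path delimiter."""


class HeaderError(HiertaxError):
    """A tabular file does not carry the headers its model requires."""


class UnknownNodeError(HiertaxError, KeyError):
    """A query referenced a node id absent from the backend."""


class MultiparentError(HiertaxError):
    """A uniparental operation met a node with more than one parent."""


class MultirootError(HiertaxError):
    """A single-root serialization (Newick) was asked for a forest."""


class ParseError(HiertaxError):
    """A serialized tree string could not be parsed."""


class MissingValueError(HiertaxError):
    """Branch aggregation lacked values for some subtree members."""

    def __init__(self, missing_ids):
        self.missing_ids = tuple(missing_ids)
        super().__init__(f"no value supplied for nodes: {', '.join(self.missing_ids)}")


class EmptyInputError(HiertaxError):
    """The detector received no usable table rows."""


class InvalidMoveError(HiertaxError):
    """A node move would place a branch inside itself (cycle)."""


class UnknownVersionError(HiertaxError):
    """A version number outside 1..current_version was requested."""


class ParamError(HiertaxError):
    """Synthetic-generator parameters are out of range."""


class AmbiguousNameError(HiertaxError):
    """Duplicate names within one sibling context prevent path resolution."""


class OrphanPathError(HiertaxError):
    """A name path references a parent prefix absent from the input."""


class DuplicateRankOnPathError(HiertaxError):
    """Two ancestors on one root-to-node path carry the same rank."""
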