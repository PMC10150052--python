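"""Core domain objects: annotated BCR sequence records and repertoires.

A :class:`SequenceRecord` is one annotated heavy-chain read: the full
nucleotide sequence, its V/J germline gene assignments (with any tied
alternative calls kept in rank order), the CDR3 junction, productivity and
a copy number.  A :class:`Repertoire` is an ordered collection of records
with bookkeeping for junction-identical collapsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

__all__ = ["SequenceRecord", "Repertoire", "NegationSet"]

_NUC = set("ACGTN")


@dataclass(frozen=True)
class SequenceRecord:
    """One annotated BCR sequence.

    Parameters
    ----------
    id : unique sequence identifier.
    sequence : nucleotide string over ``{A,C,G,T,N}`` (uppercased).
    v_call, j_call : primary germline gene assignments.  When tied
        alternative candidates exist, ``v_call`` is the first element of
        the ranked candidate list and the rest live in ``v_alternatives``.
    junction : CDR3 junction nucleotide string.
    productive : whether the rearrangement is in-frame and stop-free.
    count : copy number (collapsed duplicate reads), >= 1.
    truth_clone : ground-truth clone label when known (simulations).
    """

    id: str
    sequence: str
    v_call: str
    j_call: str
    junction: str
    productive: bool = True
    v_alternatives: tuple[str, ...] = ()
    j_alternatives: tuple[str, ...] = ()
    count: int = 1
    truth_clone: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "junction", self.junction.upper())
        if self.count < 1:
            raise ValueError(f"record {self.id!r}: count must be >= 1, got {self.count}")
        bad = set(self.junction) - _NUC
        if bad:
            raise ValueError(f"record {self.id!r}: junction has non-nucleotide symbols {sorted(bad)}")

    @property
    def v_candidates(self) -> tuple[str, ...]:
        """Full ranked V candidate list (primary call first)."""
        return (self.v_call, *self.v_alternatives)

    @property
    def j_candidates(self) -> tuple[str, ...]:
        return (self.j_call, *self.j_alternatives)


@dataclass
class Repertoire:
    """Ordered collection of :class:`SequenceRecord` with collapse state."""

    records: list[SequenceRecord]
    collapsed: bool = False
    collapse_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dups = [r.id for r in self.records if r.id in seen or seen.add(r.id)]
        if dups:
            raise ValueError(f"duplicate sequence ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def junctions(self) -> list[str]:
        return [r.junction for r in self.records]

    @property
    def total_count(self) -> int:
        return sum(r.count for r in self.records)

    def with_records(self, records: Sequence[SequenceRecord], *, collapsed: Optional[bool] = None) -> "Repertoire":
        return Repertoire(
            records=list(records),
            collapsed=self.collapsed if collapsed is None else collapsed,
            collapse_map=dict(self.collapse_map),
        )

    def map_records(self, fn) -> "Repertoire":
        return self.with_records([fn(r) for r in self.records])


@dataclass
class NegationSet:
    """Sequences sampled from unrelated individuals, used to calibrate
    clustering thresholds for specificity (clones do not span individuals)."""

    records: list[SequenceRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)


def strip_allele(call: str) -> str:
    """Drop the ``*xx`` allele suffix from a gene call (``IGHV1-2*01`` -> ``IGHV1-2``)."""
    return call.split("*", 1)[0].strip()


def record_with(record: SequenceRecord, **changes) -> SequenceRecord:
    return replace(record, **changes)
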