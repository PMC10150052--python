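"""Reading, validating, filtering and collapsing annotated repertoire tables.

The canonical input dialect is the AIRR Rearrangement TSV (tab-separated,
one row per sequence, columns ``sequence_id``, ``sequence``, ``v_call``,
``j_call``, ``junction``, ``productive``; optional ``duplicate_count`` and
``truth_clone``).  Tied alternative gene calls may be given either in
dedicated ``v_alternatives``/``j_alternatives`` columns or as
comma-separated lists inside ``v_call``/``j_call`` (common annotator
output).  A ``fasta+table`` dialect reads raw sequences from FASTA and the
annotations from a side table keyed by sequence id.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .records import NegationSet, Repertoire, SequenceRecord, record_with, strip_allele

__all__ = [
    "SchemaError",
    "read_repertoire",
    "read_negation_set",
    "filter_productive",
    "resolve_ambiguous_calls",
    "collapse_identical_junctions",
    "write_repertoire",
    "write_partition",
    "read_partition",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sequence_id", "sequence", "v_call", "j_call", "junction", "productive")

_TRUE = {"t", "true", "1", "yes", "y"}
_FALSE = {"f", "false", "0", "no", "n", ""}


class SchemaError(ValueError):
    """Input table does not conform to the expected dialect."""


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise SchemaError(f"cannot interpret productive value {x!r}")


def _split_calls(raw: str) -> list[str]:
    return [c.strip() for c in str(raw).split(",") if c.strip()]


def _records_from_frame(df: pd.DataFrame, collapse_alleles: bool) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    n_empty_junction = 0
    for row in df.itertuples(index=False):
        junction = "" if pd.isna(row.junction) else str(row.junction).upper()
        if not junction:
            n_empty_junction += 1
            continue
        v_cands = _split_calls(row.v_call)
        j_cands = _split_calls(row.j_call)
        if hasattr(row, "v_alternatives") and not pd.isna(row.v_alternatives):
            v_cands += [c for c in _split_calls(row.v_alternatives) if c not in v_cands]
        if hasattr(row, "j_alternatives") and not pd.isna(row.j_alternatives):
            j_cands += [c for c in _split_calls(row.j_alternatives) if c not in j_cands]
        if collapse_alleles:
            v_cands = list(dict.fromkeys(strip_allele(c) for c in v_cands))
            j_cands = list(dict.fromkeys(strip_allele(c) for c in j_cands))
        if not v_cands:
            raise SchemaError(f"record {row.sequence_id!r} has no V gene candidate")
        if not j_cands:
            raise SchemaError(f"record {row.sequence_id!r} has no J gene candidate")
        count = 1
        if hasattr(row, "duplicate_count") and not pd.isna(row.duplicate_count):
            count = int(row.duplicate_count)
        truth = None
        if hasattr(row, "truth_clone") and not pd.isna(row.truth_clone):
            truth = str(row.truth_clone)
        records.append(
            SequenceRecord(
                id=str(row.sequence_id),
                sequence=str(row.sequence),
                v_call=v_cands[0],
                j_call=j_cands[0],
                v_alternatives=tuple(v_cands[1:]),
                j_alternatives=tuple(j_cands[1:]),
                junction=junction,
                productive=_parse_bool(row.productive),
                count=count,
                truth_clone=truth,
            )
        )
    if n_empty_junction:
        logger.warning("excluded %d records with empty junction", n_empty_junction)
    return records


def read_repertoire(
    path,
    dialect: str = "airr_tsv",
    annotations: Optional[object] = None,
    collapse_alleles: bool = True,
) -> Repertoire:
    """Read an annotated repertoire table into a :class:`Repertoire`.

    Parameters
    ----------
    path : TSV file (``airr_tsv`` dialect) or FASTA file (``fasta+table``).
    dialect : ``"airr_tsv"`` or ``"fasta+table"``.
    annotations : for ``fasta+table``, path to the annotation TSV
        (all required columns except ``sequence``).
    collapse_alleles : strip ``*xx`` allele suffixes from gene calls, so
        clones are defined at the gene level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "airr_tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    elif dialect == "fasta+table":
        if annotations is None:
            raise SchemaError("fasta+table dialect requires an annotation table")
        seqs = _read_fasta(path)
        df = pd.read_csv(annotations, sep="\t", dtype=str)
        required = [c for c in REQUIRED_COLUMNS if c != "sequence"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        absent = [i for i in df["sequence_id"] if i not in seqs]
        if absent:
            raise SchemaError(f"annotation rows without FASTA sequence: {absent[:5]}")
        df = df.assign(sequence=[seqs[i] for i in df["sequence_id"]])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if df.empty:
        raise SchemaError(f"{path} contains no records")
    dup = df["sequence_id"][df["sequence_id"].duplicated()].tolist()
    if dup:
        raise SchemaError(f"duplicate sequence_id values: {sorted(set(dup))}")
    return Repertoire(records=_records_from_frame(df, collapse_alleles))


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def read_negation_set(path, **kwargs) -> NegationSet:
    """Read a negation-sequence table (same dialect as a repertoire)."""
    rep = read_repertoire(path, **kwargs)
    return NegationSet(records=rep.records)


def filter_productive(rep: Repertoire) -> Repertoire:
    """Keep only records annotated as productive, preserving order."""
    kept = [r for r in rep.records if r.productive]
    if not kept:
        logger.warning("no productive records remain after filtering")
    return rep.with_records(kept)


def resolve_ambiguous_calls(rep: Repertoire, seed: int = 0) -> Repertoire:
    """Resolve tied top gene candidates to the alphabetically first one.

    When several germline genes are called with equal confidence, the
    primary call becomes the lexicographically smallest candidate and the
    remaining candidates are kept as alternatives in their original rank
    order.  ``seed`` is accepted for interface symmetry; the rule is
    deterministic.
    """
    del seed

    def _resolve(r: SequenceRecord) -> SequenceRecord:
        changes = {}
        if r.v_alternatives:
            cands = list(r.v_candidates)
            best = min(cands)
            changes["v_call"] = best
            changes["v_alternatives"] = tuple(c for c in cands if c != best)
        if r.j_alternatives:
            cands = list(r.j_candidates)
            best = min(cands)
            changes["j_call"] = best
            changes["j_alternatives"] = tuple(c for c in cands if c != best)
        return record_with(r, **changes) if changes else r

    return rep.map_records(_resolve)


def collapse_identical_junctions(rep: Repertoire, seed: int = 0) -> Repertoire:
    """Merge records sharing an identical junction into one representative.

    Identical junctions are assumed clonally related (two distinct clones
    almost never produce the same junction string).  The representative is
    chosen uniformly at random among members; its copy number becomes the
    sum of member counts, and the membership is recorded in
    ``collapse_map``.  Idempotent: collapsing twice is a no-op.
    """
    if rep.collapsed:
        return rep
    rng = np.random.default_rng(seed)
    groups: dict[str, list[SequenceRecord]] = {}
    order: list[str] = []
    for r in rep.records:
        if r.junction not in groups:
            groups[r.junction] = []
            order.append(r.junction)
        groups[r.junction].append(r)
    out: list[SequenceRecord] = []
    collapse_map: dict[str, list[str]] = {}
    for junction in order:
        members = groups[junction]
        pick = members[int(rng.integers(len(members)))] if len(members) > 1 else members[0]
        total = sum(m.count for m in members)
        out.append(record_with(pick, count=total))
        collapse_map[pick.id] = [m.id for m in members]
    return Repertoire(records=out, collapsed=True, collapse_map=collapse_map)


def write_repertoire(rep: Repertoire, path) -> None:
    """Write a repertoire as AIRR Rearrangement TSV."""
    rows = [
        {
            "sequence_id": r.id,
            "sequence": r.sequence,
            "v_call": r.v_call,
            "j_call": r.j_call,
            "v_alternatives": ",".join(r.v_alternatives),
            "j_alternatives": ",".join(r.j_alternatives),
            "junction": r.junction,
            "productive": "T" if r.productive else "F",
            "duplicate_count": r.count,
            "truth_clone": r.truth_clone if r.truth_clone is not None else "",
        }
        for r in rep.records
    ]
    cols = ["sequence_id", "sequence", "v_call", "j_call", "v_alternatives",
            "j_alternatives", "junction", "productive", "duplicate_count", "truth_clone"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_partition(partition, path) -> None:
    """Write a clonal partition as a two-column ``sequence_id``/``clone_id`` TSV."""
    df = pd.DataFrame(
        {"sequence_id": list(partition.assignment.keys()),
         "clone_id": list(partition.assignment.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path):
    """Read a partition TSV written by :func:`write_partition`."""
    from .clustering import ClonalPartition

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sequence_id", "clone_id"):
        if col not in df.columns:
            raise SchemaError(f"missing required column(s): {col}")
    return ClonalPartition(
        assignment=dict(zip(df["sequence_id"], df["clone_id"])),
        method="loaded",
        threshold=None,
        params={},
    )
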