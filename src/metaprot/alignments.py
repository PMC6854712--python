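"""Tabular alignment (BLAST/Diamond "outfmt 6" dialect) parsing and hit retention.

Consensus annotation works on many alignment hits per query rather than the
single best hit.  Which hits count is governed by two parameters: a bitscore
threshold (default 80) and a cap on the number of retained hits per query
(default 20).  Hits below the threshold are dropped first; the survivors are
sorted by descending bitscore (ties: ascending e-value, then file order) and
truncated to the cap.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "AlignmentHit",
    "FilterPolicy",
    "AlignmentParseError",
    "OUTFMT6_COLUMNS",
    "read_alignments",
    "group_by_query",
    "filter_hits",
]

#: Default 12-column BLAST/Diamond tabular layout.
OUTFMT6_COLUMNS: tuple[str, ...] = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

#: Same layout with a trailing subject-taxon-id column (Diamond ``staxids``).
OUTFMT6_TAX_COLUMNS: tuple[str, ...] = OUTFMT6_COLUMNS + ("staxids",)

# Accept both BLAST-style and descriptive column names.
_CANONICAL = {
    "qseqid": "query_id", "query_id": "query_id",
    "sseqid": "subject_id", "subject_id": "subject_id",
    "bitscore": "bitscore",
    "evalue": "evalue",
    "staxids": "subject_taxa", "subject_taxa": "subject_taxa",
}


class AlignmentParseError(ValueError):
    """A malformed row in a tabular alignment file; carries the line number."""

    def __init__(self, message: str, line_number: int, source: str = ""):
        where = f"{source}:" if source else "line "
        super().__init__(f"{where}{line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class AlignmentHit:
    """One row of tabular alignment output.

    ``subject_taxa`` holds the subject's taxon ids (possibly empty, never
    duplicated); ``raw_rank`` is the 0-based order of appearance within the
    hit's query block and serves as the final, file-order tie-break.
    ``evalue`` defaults to ``inf`` when the column is absent, so hits without
    one sort last among bitscore ties.
    """

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float = math.inf
    subject_taxa: tuple[int, ...] = ()
    raw_rank: int = 0

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore: {self.bitscore}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if len(set(self.subject_taxa)) != len(self.subject_taxa):
            raise ValueError(f"duplicate subject taxa: {self.subject_taxa}")


@dataclass(frozen=True)
class FilterPolicy:
    """Hit-retention policy: keep hits with ``bitscore >= min_bitscore``,
    at most ``max_hits`` per query."""

    min_bitscore: float = 80.0
    max_hits: int = 20

    def __post_init__(self):
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.min_bitscore < 0:
            raise ValueError("min_bitscore must be >= 0")


def _parse_taxa_cell(cell: str, line_number: int, source: str) -> tuple[int, ...]:
    taxa: list[int] = []
    seen: set[int] = set()
    for token in cell.split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            tid = int(token)
        except ValueError:
            raise AlignmentParseError(
                f"non-integer taxon id {token!r} in staxids cell", line_number, source
            ) from None
        if tid not in seen:
            seen.add(tid)
            taxa.append(tid)
    return tuple(taxa)


def read_alignments(
    source,
    columns: Sequence[str] = OUTFMT6_COLUMNS,
    delimiter: str = "\t",
) -> Iterator[AlignmentHit]:
    """Stream :class:`AlignmentHit` rows from a delimited alignment file.

    ``columns`` names the fields in order; it must include at least the
    query id, subject id and bitscore (BLAST-style ``qseqid``/``sseqid``/
    ``bitscore`` or descriptive names).  Unrecognized column names are
    parsed past and ignored.  Blank lines and lines starting with ``#``
    are skipped.  Hits are yielded in file order; ``raw_rank`` counts the
    hit's position within its query block.

    Raises :class:`AlignmentParseError` (with the 1-based line number) on
    short rows or non-numeric score fields.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from read_alignments(handle, columns=columns, delimiter=delimiter)
        return

    name = getattr(source, "name", "")
    if not isinstance(name, str):
        name = ""
    mapped = [_CANONICAL.get(c) for c in columns]
    required = {"query_id", "subject_id", "bitscore"}
    present = {m for m in mapped if m}
    missing = required - present
    if missing:
        raise ValueError(f"column spec lacks required fields: {sorted(missing)}")

    ranks: dict[str, int] = {}
    for line_number, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(delimiter)
        if len(fields) < len(columns):
            raise AlignmentParseError(
                f"expected {len(columns)} columns, found {len(fields)}",
                line_number, name,
            )
        row = {m: fields[i] for i, m in enumerate(mapped) if m}
        try:
            bitscore = float(row["bitscore"])
        except ValueError:
            raise AlignmentParseError(
                f"non-numeric bitscore {row['bitscore']!r}", line_number, name
            ) from None
        evalue = math.inf
        if "evalue" in row:
            try:
                evalue = float(row["evalue"])
            except ValueError:
                raise AlignmentParseError(
                    f"non-numeric evalue {row['evalue']!r}", line_number, name
                ) from None
        taxa = ()
        if "subject_taxa" in row:
            taxa = _parse_taxa_cell(row["subject_taxa"], line_number, name)
        query_id = row["query_id"]
        rank = ranks.get(query_id, 0)
        ranks[query_id] = rank + 1
        yield AlignmentHit(
            query_id=query_id,
            subject_id=row["subject_id"],
            bitscore=bitscore,
            evalue=evalue,
            subject_taxa=taxa,
            raw_rank=rank,
        )


def group_by_query(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    """Group hits by query id, preserving first-appearance order of queries."""
    grouped: dict[str, list[AlignmentHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    return grouped


def filter_hits(
    hits: Sequence[AlignmentHit],
    policy: FilterPolicy = FilterPolicy(),
) -> list[AlignmentHit]:
    """Apply the retention policy to one query's hits.

    Thresholds first (``bitscore >= min_bitscore``), then sorts by
    descending bitscore with deterministic tie-breaks (ascending e-value,
    then file order), then truncates to ``max_hits``.  Idempotent.
    """
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"filter_hits expects hits of one query, got {sorted(queries)}")
    kept = [h for h in hits if h.bitscore >= policy.min_bitscore]
    kept.sort(key=lambda h: (-h.bitscore, h.evalue, h.raw_rank))
    return kept[: policy.max_hits]
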