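"""Protein search database construction.

Builds the combined FASTA database that MS/MS spectra are searched against:
merge several source databases, collapse exact-duplicate sequences, and
replace the (often huge, heterogeneous) description lines with fixed-width
hash digests, keeping a hash -> original map for traceability.  Scoped
databases — all proteins of given taxa, or proteins matching gene/protein
names with an optional clade restriction — are assembled from a pluggable
:class:`ProteinSource`; a local FASTA + metadata implementation is bundled
so nothing requires network access.

Deduplication is exact-identity: identical sequences collapse to the first
occurrence in file order.  The optional containment mode additionally drops
sequences that are substrings of an already-kept longer sequence (the way a
100%-identity CD-HIT run absorbs identical fragments); clustering below
100% identity is out of scope.
"""

from __future__ import annotations

import hashlib
import logging
import os
import re
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

from .consensus import normalize_label
from .taxonomy import TaxonomyTree, UnknownTaxonError

__all__ = [
    "ProteinRecord",
    "DedupReport",
    "HeaderMap",
    "ProteinSource",
    "LocalProteinSource",
    "RetrievalLog",
    "FastaParseError",
    "HashCollisionError",
    "read_fasta",
    "write_fasta",
    "merge_databases",
    "deduplicate",
    "hash_headers",
    "build_taxonomy_db",
    "build_functional_db",
]

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    """Malformed FASTA input; carries source name and line number."""

    def __init__(self, message: str, line_number: int, source: str = ""):
        where = f"{source}:" if source else "line "
        super().__init__(f"{where}{line_number}: {message}")
        self.line_number = line_number


class HashCollisionError(RuntimeError):
    """Two distinct headers produced the same digest."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: full description line (without ``>``), parsed accession,
    normalized sequence (upper case, trailing ``*`` stripped)."""

    header: str
    sequence: str
    accession: str = ""

    def __post_init__(self):
        if not self.header:
            raise ValueError("empty FASTA header")
        if not self.sequence:
            raise ValueError(f"empty sequence for header {self.header!r}")
        if not self.accession:
            object.__setattr__(self, "accession", self.header.split()[0])


def _normalize_sequence(seq: str) -> str:
    seq = seq.upper()
    while seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(source, name: str = "") -> Iterator[ProteinRecord]:
    """Stream :class:`ProteinRecord` from FASTA text.

    ``source`` may be a path or an open text handle.  Sequences are
    normalized (upper-cased, trailing ``*`` stripped).  Sequence data before
    the first header is a :class:`FastaParseError` carrying the source name
    and line number.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from read_fasta(handle, name=name or os.fspath(source))
        return
    if not name:
        handle_name = getattr(source, "name", "")
        name = handle_name if isinstance(handle_name, str) else ""

    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def emit() -> ProteinRecord:
        seq = _normalize_sequence("".join(chunks))
        if not seq:
            raise FastaParseError(f"record {header!r} has an empty sequence",
                                  header_line, name)
        return ProteinRecord(header=header, sequence=seq)

    for line_number, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield emit()
            header = line[1:].strip()
            header_line = line_number
            chunks = []
            if not header:
                raise FastaParseError("empty header line", line_number, name)
        else:
            if header is None:
                raise FastaParseError(
                    "sequence data before first '>' header", line_number, name
                )
            chunks.append(line.strip())
    if header is not None:
        yield emit()


def write_fasta(records: Iterable[ProteinRecord], destination, wrap: int = 60) -> int:
    """Write records as FASTA, wrapping sequence lines at ``wrap`` columns.

    Returns the number of records written.
    """
    if isinstance(destination, (str, os.PathLike)):
        with open(destination, "w", encoding="utf-8") as handle:
            return write_fasta(records, handle, wrap=wrap)
    count = 0
    for record in records:
        destination.write(f">{record.header}\n")
        seq = record.sequence
        for start in range(0, len(seq), wrap):
            destination.write(seq[start:start + wrap] + "\n")
        count += 1
    return count


def merge_databases(sources: Sequence) -> Iterator[ProteinRecord]:
    """Concatenate FASTA sources into one normalized record stream.

    Sources are read in the given order; record order within each source is
    preserved and the total record count equals the sum over sources.
    """
    for source in sources:
        yield from read_fasta(source)


@dataclass
class DedupReport:
    """Bookkeeping for deduplication: every input record is either kept or
    removed, and each removed header is attributed to its surviving record."""

    kept: int = 0
    removed: int = 0
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def write(self, destination) -> None:
        """Two-column table: surviving accession <TAB> removed header."""
        if isinstance(destination, (str, os.PathLike)):
            with open(destination, "w", encoding="utf-8") as handle:
                return self.write(handle)
        destination.write("kept_accession\tremoved_header\n")
        for accession, removed in self.clusters.items():
            for header in removed:
                destination.write(f"{accession}\t{header}\n")


def deduplicate(
    records: Iterable[ProteinRecord],
    containment: bool = False,
) -> tuple[list[ProteinRecord], DedupReport]:
    """Remove duplicate sequences, keeping the first occurrence (file order).

    With ``containment=True`` a sequence that is a substring of an
    already-kept longer sequence is also removed.  The report accounts for
    every input record (``kept + removed == input count``).
    """
    kept: list[ProteinRecord] = []
    by_seq: dict[str, ProteinRecord] = {}
    report = DedupReport()
    for record in records:
        survivor = by_seq.get(record.sequence)
        if survivor is None and containment:
            for candidate in kept:
                if record.sequence in candidate.sequence:
                    survivor = candidate
                    break
        if survivor is not None:
            report.removed += 1
            report.clusters.setdefault(survivor.accession, []).append(record.header)
        else:
            by_seq[record.sequence] = record
            kept.append(record)
            report.kept += 1
    return kept, report


@dataclass
class HeaderMap:
    """Bijection hashed header -> original header."""

    entries: dict[str, str] = field(default_factory=dict)

    def original(self, hashed: str) -> str:
        return self.entries[hashed]

    def __len__(self) -> int:
        return len(self.entries)

    def write(self, destination) -> None:
        """Two-column table: hashed <TAB> original."""
        if isinstance(destination, (str, os.PathLike)):
            with open(destination, "w", encoding="utf-8") as handle:
                return self.write(handle)
        destination.write("hashed\toriginal\n")
        for hashed, original in self.entries.items():
            destination.write(f"{hashed}\t{original}\n")

    @classmethod
    def read(cls, source) -> "HeaderMap":
        if isinstance(source, (str, os.PathLike)):
            with open(source, "r", encoding="utf-8") as handle:
                return cls.read(handle)
        entries: dict[str, str] = {}
        for i, line in enumerate(source):
            if i == 0 and line.startswith("hashed\t"):
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            hashed, _, original = line.partition("\t")
            entries[hashed] = original
        return cls(entries=entries)


_HEX = re.compile(r"^[0-9a-f]+$")


def hash_headers(
    records: Iterable[ProteinRecord],
    algorithm: str = "md5",
    _digest: Callable[[bytes], str] | None = None,
) -> tuple[list[ProteinRecord], HeaderMap]:
    """Replace each header with the lowercase hex digest of its exact text.

    The digest input is the full original description line, UTF-8 encoded,
    with no trailing newline.  Sequences are untouched.  The returned
    :class:`HeaderMap` records the digest -> original bijection; a digest
    collision between distinct originals is a hard error.

    A header that already looks like a digest of the configured algorithm
    (lowercase hex of the right length) is assumed hashed: it passes through
    unchanged with a warning, so re-running the pipeline on its own output
    is a no-op.

    Raises ``ValueError`` for an unknown algorithm name.
    """
    algorithm = algorithm.lower()
    if _digest is None:
        try:
            probe = hashlib.new(algorithm)
        except ValueError:
            raise ValueError(f"unknown hash algorithm: {algorithm!r}") from None
        digest_len = probe.digest_size * 2

        def _digest(data: bytes) -> str:
            return hashlib.new(algorithm, data).hexdigest()
    else:
        digest_len = len(_digest(b""))

    out: list[ProteinRecord] = []
    header_map = HeaderMap()
    warned = False
    for record in records:
        if len(record.header) == digest_len and _HEX.match(record.header):
            if not warned:
                logger.warning(
                    "header %r already looks hashed (%s); leaving as-is",
                    record.header, algorithm,
                )
                warned = True
            header_map.entries.setdefault(record.header, record.header)
            out.append(record)
            continue
        hashed = _digest(record.header.encode("utf-8"))
        existing = header_map.entries.get(hashed)
        if existing is not None and existing != record.header:
            raise HashCollisionError(
                f"{algorithm} collision: {existing!r} and {record.header!r} "
                f"both hash to {hashed}"
            )
        header_map.entries[hashed] = record.header
        out.append(ProteinRecord(header=hashed, sequence=record.sequence,
                                 accession=hashed))
    return out, header_map


@dataclass
class RetrievalLog:
    """Per-query retrieval bookkeeping for scoped DB building."""

    counts: dict = field(default_factory=dict)    # query -> record count
    failures: dict = field(default_factory=dict)  # query -> error message

    def write(self, destination) -> None:
        if isinstance(destination, (str, os.PathLike)):
            with open(destination, "w", encoding="utf-8") as handle:
                return self.write(handle)
        destination.write("query\trecords\tstatus\n")
        for query, count in self.counts.items():
            destination.write(f"{query}\t{count}\tok\n")
        for query, message in self.failures.items():
            destination.write(f"{query}\t0\tfailed: {message}\n")


class ProteinSource(ABC):
    """A queryable store of protein records (the retrieval back end).

    Implementations yield each matching record exactly once per query.  The
    bundled :class:`LocalProteinSource` serves records from local FASTA plus
    a metadata table; a remote (e.g. UniProt REST) implementation is a
    documented extension point and is deliberately not shipped.
    """

    @abstractmethod
    def by_taxon(self, taxon_id: int) -> Iterator[ProteinRecord]:
        """All records annotated with exactly this taxon id."""

    @abstractmethod
    def by_name(
        self,
        query: str,
        taxon_restriction: int | None = None,
        tree: TaxonomyTree | None = None,
    ) -> Iterator[ProteinRecord]:
        """Records whose annotation label matches ``query`` as a whole word
        (case-insensitive), optionally restricted to a taxonomic clade."""


class LocalProteinSource(ProteinSource):
    """Protein source backed by in-memory records with taxon and label metadata.

    Parameters
    ----------
    records
        The protein records served.
    taxa
        accession -> taxon id.
    labels
        accession -> annotation label (protein/gene name).
    """

    def __init__(
        self,
        records: Iterable[ProteinRecord],
        taxa: dict[str, int],
        labels: dict[str, str],
    ):
        self._records = list(records)
        self._taxa = dict(taxa)
        self._labels = {acc: normalize_label(lab) for acc, lab in labels.items()}

    @classmethod
    def from_files(cls, fasta_path, metadata_path) -> "LocalProteinSource":
        """Build from a FASTA file and a three-column metadata table
        ``accession<TAB>taxon_id<TAB>label``."""
        records = list(read_fasta(fasta_path))
        taxa: dict[str, int] = {}
        labels: dict[str, str] = {}
        with open(metadata_path, "r", encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"metadata row needs 3 columns: {line!r}")
                accession, taxon, label = fields[0], fields[1], fields[2]
                taxa[accession] = int(taxon)
                labels[accession] = label
        return cls(records, taxa, labels)

    def taxon_of(self, accession: str) -> int | None:
        return self._taxa.get(accession)

    def by_taxon(self, taxon_id: int) -> Iterator[ProteinRecord]:
        for record in self._records:
            if self._taxa.get(record.accession) == taxon_id:
                yield record

    def by_name(
        self,
        query: str,
        taxon_restriction: int | None = None,
        tree: TaxonomyTree | None = None,
    ) -> Iterator[ProteinRecord]:
        if taxon_restriction is not None and tree is None:
            raise ValueError("taxon_restriction requires a TaxonomyTree")
        pattern = re.compile(
            rf"(?<!\w){re.escape(normalize_label(query))}(?!\w)", re.IGNORECASE
        )
        for record in self._records:
            label = self._labels.get(record.accession)
            if label is None or not pattern.search(label):
                continue
            if taxon_restriction is not None:
                taxon = self._taxa.get(record.accession)
                if taxon is None:
                    continue
                try:
                    if not tree.is_ancestor(taxon_restriction, taxon):
                        continue
                except UnknownTaxonError:
                    continue
            yield record


def build_taxonomy_db(
    taxon_ids: Sequence[int],
    source: ProteinSource,
) -> tuple[list[ProteinRecord], RetrievalLog]:
    """Collect all records for the given taxa (duplicate ids collapsed).

    A failing retrieval for one taxon is logged and does not abort the
    others.  An empty taxon list is a contract violation.
    """
    if not taxon_ids:
        raise ValueError("taxon id list must be non-empty")
    seen: set[int] = set()
    unique = [t for t in taxon_ids if not (t in seen or seen.add(t))]
    records: list[ProteinRecord] = []
    log = RetrievalLog()
    for taxon in unique:
        try:
            found = list(source.by_taxon(taxon))
        except Exception as exc:  # noqa: BLE001 - per-taxon isolation is the contract
            logger.error("retrieval failed for taxon %s: %s", taxon, exc)
            log.failures[taxon] = str(exc)
            continue
        records.extend(found)
        log.counts[taxon] = len(found)
    return records, log


def build_functional_db(
    name_queries: Sequence[str],
    source: ProteinSource,
    taxon_restriction: int | None = None,
    tree: TaxonomyTree | None = None,
) -> tuple[list[ProteinRecord], RetrievalLog]:
    """Collect records whose annotation label matches any query name.

    Matching is case-insensitive whole-word on the normalized label; with
    ``taxon_restriction`` only records inside that clade (ancestor test on
    ``tree``) are kept.  Records matching several queries are emitted once,
    credited to the first matching query.
    """
    if not name_queries:
        raise ValueError("name query list must be non-empty")
    records: list[ProteinRecord] = []
    emitted: set[int] = set()
    log = RetrievalLog()
    for query in name_queries:
        try:
            found = list(source.by_name(query, taxon_restriction=taxon_restriction,
                                        tree=tree))
        except Exception as exc:  # noqa: BLE001
            logger.error("retrieval failed for query %r: %s", query, exc)
            log.failures[query] = str(exc)
            continue
        fresh = [r for r in found if id(r) not in emitted]
        emitted.update(id(r) for r in fresh)
        records.extend(fresh)
        log.counts[query] = len(found)
        if not found:
            logger.info("query %r matched no records", query)
    return records, log
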