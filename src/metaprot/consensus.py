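"""Protein-group consensus annotation: LCA taxonomy and most-frequent-name function.

Proteomics search engines report groups of proteins that share identified
peptides (the protein inference issue).  Annotating a group from the single
best alignment hit of one member is fragile; instead the retained alignment
hits of *all* members are pooled and the group is annotated by consensus:

* taxonomy — the lowest common ancestor (LCA) of every taxon supported by a
  retained hit, so evidence spanning several clades yields a conservative
  annotation at their common ancestor;
* function — the most frequent annotation label among the retained hits'
  subjects (one hit, one vote), with ties broken by summed bitscore and
  then lexicographically.

A hit whose subject maps to several taxa is first collapsed to the LCA of
its own taxa so a multi-mapped subject casts a single taxonomic vote.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignments import AlignmentHit, FilterPolicy, filter_hits, group_by_query
from .taxonomy import TaxonomyTree, UnknownTaxonError

__all__ = [
    "ProteinGroup",
    "AnnotationMap",
    "FunctionalConsensus",
    "TaxonomicConsensus",
    "ConsensusAnnotation",
    "UNASSIGNED",
    "UNKNOWN_FUNCTION",
    "taxonomic_consensus",
    "functional_consensus",
    "annotate_groups",
    "read_protein_groups",
    "read_annotation_map",
    "normalize_label",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
UNKNOWN_FUNCTION = "hypothetical/unknown"

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Trim and collapse internal whitespace (casing preserved)."""
    return _WS.sub(" ", label.strip())


@dataclass(frozen=True)
class ProteinGroup:
    """A protein group: identifier plus member protein accessions."""

    group_id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.group_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"group {self.group_id!r} has duplicate members")


class AnnotationMap:
    """Accession -> annotation label lookup (e.g. UniProt recommended names,
    COG identifiers).  Labels are whitespace-normalized on entry; empty
    labels are rejected."""

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        self._entries: dict[str, str] = {}
        items = entries.items() if isinstance(entries, Mapping) else entries
        for accession, label in items:
            norm = normalize_label(label)
            if not norm:
                raise ValueError(f"empty annotation label for accession {accession!r}")
            self._entries[accession] = norm

    def get(self, accession: str) -> str | None:
        return self._entries.get(accession)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries


@dataclass(frozen=True)
class TaxonomicConsensus:
    lca_taxon: int | None                    # None -> unassigned
    lineage: tuple[tuple[str, str], ...]     # (rank, name) root -> LCA
    hits_used: int
    hits_unresolvable: int


@dataclass(frozen=True)
class FunctionalConsensus:
    label: str
    support: int
    hits_used: int


@dataclass(frozen=True)
class ConsensusAnnotation:
    """One output row: a group's taxonomic and per-source functional consensus."""

    group_id: str
    taxonomy: TaxonomicConsensus
    functions: dict[str, FunctionalConsensus] = field(default_factory=dict)


def _pooled_hits(
    group: ProteinGroup,
    retained_hits: Mapping[str, Sequence[AlignmentHit]],
) -> list[AlignmentHit]:
    pooled: list[AlignmentHit] = []
    for accession in group.members:
        pooled.extend(retained_hits.get(accession, ()))
    return pooled


def taxonomic_consensus(
    group: ProteinGroup,
    retained_hits: Mapping[str, Sequence[AlignmentHit]],
    tree: TaxonomyTree,
) -> TaxonomicConsensus:
    """LCA consensus over the pooled retained hits of a group's members.

    Each hit contributes one taxon: the LCA of its own (possibly several)
    subject taxa, after merged-id redirection.  Hits carrying no resolvable
    taxon are counted as unresolvable and excluded.  With no taxonomic
    evidence at all the group is left unassigned.
    """
    votes: list[int] = []
    unresolvable = 0
    for hit in _pooled_hits(group, retained_hits):
        resolvable = []
        for tid in hit.subject_taxa:
            try:
                resolvable.append(tree.resolve(tid))
            except UnknownTaxonError:
                pass
        if resolvable:
            votes.append(tree.lca(resolvable))
        else:
            unresolvable += 1
    if not votes:
        return TaxonomicConsensus(None, (), 0, unresolvable)
    lca = tree.lca(votes)
    lineage = tuple((rank, name) for _, rank, name in tree.lineage(lca))
    return TaxonomicConsensus(lca, lineage, len(votes), unresolvable)


def functional_consensus(
    group: ProteinGroup,
    retained_hits: Mapping[str, Sequence[AlignmentHit]],
    annotation: AnnotationMap,
) -> FunctionalConsensus:
    """Most-frequent-label consensus over the pooled retained hits.

    Each hit votes with the normalized label of its subject accession; hits
    whose subject is absent from the map abstain.  Ties on vote count go to
    the label with the higher summed bitscore, then the lexicographically
    smaller label.  Comparison is case-insensitive; the reported label is
    the most frequent original casing among the winner's votes.
    """
    counts: dict[str, int] = {}
    scores: dict[str, float] = {}
    casings: dict[str, dict[str, int]] = {}
    used = 0
    for hit in _pooled_hits(group, retained_hits):
        label = annotation.get(hit.subject_id)
        if label is None:
            continue
        used += 1
        key = label.casefold()
        counts[key] = counts.get(key, 0) + 1
        scores[key] = scores.get(key, 0.0) + hit.bitscore
        spellings = casings.setdefault(key, {})
        spellings[label] = spellings.get(label, 0) + 1
    if not counts:
        return FunctionalConsensus(UNKNOWN_FUNCTION, 0, 0)
    winner_key = min(counts, key=lambda k: (-counts[k], -scores[k], k))
    spellings = casings[winner_key]
    reported = min(spellings, key=lambda s: (-spellings[s], s))
    return FunctionalConsensus(reported, counts[winner_key], used)


def _filtered_by_query(
    hits: Iterable[AlignmentHit],
    policy: FilterPolicy,
    known_queries: set[str],
    source_name: str,
) -> dict[str, list[AlignmentHit]]:
    grouped = group_by_query(hits)
    unmatched = [q for q in grouped if q not in known_queries]
    if unmatched:
        logger.info(
            "%s: %d alignment queries match no group member (ignored)",
            source_name, len(unmatched),
        )
    return {
        q: filter_hits(qhits, policy)
        for q, qhits in grouped.items()
        if q in known_queries
    }


def annotate_groups(
    groups: Sequence[ProteinGroup],
    taxonomy_alignments: Iterable[AlignmentHit],
    functional_sources: Sequence[tuple[str, Iterable[AlignmentHit], AnnotationMap]],
    tree: TaxonomyTree,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Annotate every group; returns one row per group, in input order.

    ``functional_sources`` is a sequence of ``(name, hits, annotation_map)``
    triples (e.g. a UniProt-derived and a COG-derived source); each yields
    its own ``<name>_label`` / ``<name>_support`` / ``<name>_hits_used``
    column triple.  Sources are reported separately, never merged into one
    vote.  Output is deterministic for identical inputs.
    """
    seen: set[str] = set()
    for group in groups:
        if group.group_id in seen:
            raise ValueError(f"duplicate group id: {group.group_id}")
        seen.add(group.group_id)
    known = {m for g in groups for m in g.members}

    tax_hits = _filtered_by_query(taxonomy_alignments, policy, known, "taxonomy")
    func_hits = [
        (name, _filtered_by_query(hits, policy, known, name), amap)
        for name, hits, amap in functional_sources
    ]

    rows: list[dict] = []
    for group in groups:
        tax = taxonomic_consensus(group, tax_hits, tree)
        row: dict = {
            "group_id": group.group_id,
            "lca_taxon_id": tax.lca_taxon if tax.lca_taxon is not None else UNASSIGNED,
            "lca_rank": tax.lineage[-1][0] if tax.lineage else UNASSIGNED,
            "lca_name": tax.lineage[-1][1] if tax.lineage else UNASSIGNED,
            "lca_lineage": ";".join(f"{rank}:{name}" for rank, name in tax.lineage),
            "tax_hits_used": tax.hits_used,
            "tax_hits_unresolvable": tax.hits_unresolvable,
        }
        for name, retained, amap in func_hits:
            func = functional_consensus(group, retained, amap)
            row[f"{name}_label"] = func.label
            row[f"{name}_support"] = func.support
            row[f"{name}_hits_used"] = func.hits_used
        rows.append(row)

    columns = ["group_id", "lca_taxon_id", "lca_rank", "lca_name", "lca_lineage",
               "tax_hits_used", "tax_hits_unresolvable"]
    for name, _, _ in func_hits:
        columns += [f"{name}_label", f"{name}_support", f"{name}_hits_used"]
    return pd.DataFrame(rows, columns=columns)


def write_annotations(table: pd.DataFrame, path) -> None:
    """Write the consensus table as a tab-delimited file with one header line."""
    table.to_csv(path, sep="\t", index=False)


def read_protein_groups(source) -> list[ProteinGroup]:
    """Read a two-column table ``group_id<TAB>comma-separated accessions``.

    Blank lines and ``#`` comments are skipped.  Duplicate group ids are an
    input error.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            return read_protein_groups(handle)
    groups: list[ProteinGroup] = []
    seen: set[str] = set()
    for i, line in enumerate(source):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if i == 0 and line.startswith("group_id\t"):
            continue  # optional header line
        group_id, _, members_cell = line.partition("\t")
        members = tuple(m.strip() for m in members_cell.split(",") if m.strip())
        if group_id in seen:
            raise ValueError(f"duplicate group id: {group_id}")
        seen.add(group_id)
        groups.append(ProteinGroup(group_id=group_id, members=members))
    return groups


def read_annotation_map(source) -> AnnotationMap:
    """Read a two-column table ``accession<TAB>label`` into an AnnotationMap."""
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            return read_annotation_map(handle)
    entries: list[tuple[str, str]] = []
    for line in source:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        accession, _, label = line.partition("\t")
        entries.append((accession, label))
    return AnnotationMap(entries)
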