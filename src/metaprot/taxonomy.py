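"""NCBI-style taxonomy handling: taxdump loading, lineages, lowest common ancestor.

The taxonomy is the backbone of conservative taxonomic binning: when the
alignment evidence for a protein group spans several taxa, the group is
annotated at the lowest common ancestor (LCA) of those taxa rather than at
any single best hit.  This module loads the standard NCBI taxdump dialect
(``nodes.dmp``, ``names.dmp``, ``merged.dmp``; fields separated by
``"\\t|\\t"``, rows terminated by ``"\\t|"``) into an in-memory tree and
answers lineage and LCA queries on it.

Depths are computed lazily via memoized parent walks; trees at the scale
this tool handles (desktop taxonomies, synthetic test trees) do not warrant
Euler-tour style preprocessing.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "TaxonomyStructureError",
    "UnknownTaxonError",
    "load_taxonomy",
]


class TaxonomyError(Exception):
    """Base class for taxonomy errors."""


class TaxonomyStructureError(TaxonomyError):
    """The loaded dump does not form a single rooted tree."""


class UnknownTaxonError(TaxonomyError):
    """A queried taxon id resolves to no loaded node (directly or via merged)."""

    def __init__(self, taxon_id: int):
        super().__init__(f"unknown taxon id: {taxon_id}")
        self.taxon_id = taxon_id


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy: id, parent link, rank and scientific name."""

    taxon_id: int
    parent_id: int
    rank: str
    name: str


def _iter_dmp_rows(source) -> Iterator[list[str]]:
    """Yield field lists from an NCBI taxdump-dialect stream.

    ``source`` may be a path or an open text handle / iterable of lines.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source, "r", encoding="utf-8") as handle:
            yield from _iter_dmp_rows(handle)
        return
    for line in source:
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.endswith("\t|"):
            line = line[: -len("\t|")]
        yield line.split("\t|\t")


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with merged-id redirection and LCA support.

    Merged-taxon redirection is transparent: every public lookup accepts an
    old id listed in ``merged`` and operates on its replacement.  Ids found
    in neither ``nodes`` nor ``merged`` raise :class:`UnknownTaxonError`;
    deciding what to do with such ids (skip, count, fail) is deliberately
    left to the caller.
    """

    nodes: dict[int, TaxonNode]
    merged: dict[int, int] = field(default_factory=dict)
    root_id: int = 0
    _depths: dict[int, int] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, taxon_id: int) -> bool:
        try:
            self.resolve(taxon_id)
        except UnknownTaxonError:
            return False
        return True

    def resolve(self, taxon_id: int) -> int:
        """Return the current id for ``taxon_id``, following the merged map."""
        if taxon_id in self.nodes:
            return taxon_id
        new_id = self.merged.get(taxon_id)
        if new_id is not None and new_id in self.nodes:
            return new_id
        raise UnknownTaxonError(taxon_id)

    def node(self, taxon_id: int) -> TaxonNode:
        return self.nodes[self.resolve(taxon_id)]

    def depth(self, taxon_id: int) -> int:
        """Number of edges between the node and the root (root has depth 0)."""
        tid = self.resolve(taxon_id)
        path = []
        while tid not in self._depths:
            if tid == self.root_id:
                self._depths[tid] = 0
                break
            path.append(tid)
            tid = self.nodes[tid].parent_id
        base = self._depths[tid]
        for offset, nid in enumerate(reversed(path), start=1):
            self._depths[nid] = base + offset
        return self._depths[self.resolve(taxon_id)]

    def root_path(self, taxon_id: int) -> list[int]:
        """Taxon ids from the root down to (and including) the queried taxon."""
        tid = self.resolve(taxon_id)
        path = [tid]
        while tid != self.root_id:
            tid = self.nodes[tid].parent_id
            path.append(tid)
        path.reverse()
        return path

    def lineage(self, taxon_id: int) -> list[tuple[int, str, str]]:
        """``(taxon_id, rank, name)`` triples from the root down to the taxon."""
        return [
            (tid, self.nodes[tid].rank, self.nodes[tid].name)
            for tid in self.root_path(taxon_id)
        ]

    def is_ancestor(self, ancestor_id: int, taxon_id: int) -> bool:
        """True if ``ancestor_id`` lies on the root path of ``taxon_id`` (or is it)."""
        anc = self.resolve(ancestor_id)
        tid = self.resolve(taxon_id)
        while True:
            if tid == anc:
                return True
            if tid == self.root_id:
                return False
            tid = self.nodes[tid].parent_id

    def _lca2(self, a: int, b: int) -> int:
        # Lift the deeper node to equal depth, then walk both up in lockstep.
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self.nodes[a].parent_id
            da -= 1
        while db > da:
            b = self.nodes[b].parent_id
            db -= 1
        while a != b:
            a = self.nodes[a].parent_id
            b = self.nodes[b].parent_id
        return a

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty collection of taxon ids.

        The strict ("naive") LCA: the deepest node that is an
        ancestor-or-self of every input taxon.  Input order is irrelevant
        and duplicates are harmless.
        """
        resolved = {self.resolve(t) for t in taxa}
        if not resolved:
            raise ValueError("lca() requires at least one taxon id")
        it = iter(sorted(resolved))  # sorted: determinism, order-invariance
        result = next(it)
        for tid in it:
            result = self._lca2(result, tid)
            if result == self.root_id:
                break
        return result


def load_taxonomy(
    nodes_source,
    names_source,
    merged_source=None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI taxdump-dialect streams.

    Parameters
    ----------
    nodes_source, names_source, merged_source
        Paths or open text streams in the taxdump dialect.  ``nodes``
        rows are ``taxon_id | parent_id | rank | ...``; ``names`` rows are
        ``taxon_id | name | unique name | name class`` (only rows of class
        ``"scientific name"`` are used; a taxon without one is named
        ``taxon_<id>``); ``merged`` rows are ``old_id | new_id``.

    Raises
    ------
    TaxonomyStructureError
        On duplicate taxon ids, dangling parents, cycles, a missing or
        non-unique root, or merged targets that do not resolve.
    """
    nodes: dict[int, TaxonNode] = {}
    parents: dict[int, int] = {}
    ranks: dict[int, str] = {}
    for row in _iter_dmp_rows(nodes_source):
        taxon_id = int(row[0])
        parent_id = int(row[1])
        if taxon_id in parents:
            raise TaxonomyStructureError(f"duplicate taxon id: {taxon_id}")
        parents[taxon_id] = parent_id
        ranks[taxon_id] = row[2].strip() if len(row) > 2 and row[2].strip() else "no rank"

    roots = [tid for tid, pid in parents.items() if tid == pid]
    if not roots:
        raise TaxonomyStructureError("no root (self-parent node) found")
    if len(roots) > 1:
        raise TaxonomyStructureError(f"multiple roots found: {sorted(roots)}")
    root_id = roots[0]

    for taxon_id, parent_id in parents.items():
        if parent_id not in parents:
            raise TaxonomyStructureError(
                f"taxon {taxon_id} has unknown parent {parent_id}"
            )

    # Cycle check: every node must reach the root through parent links.
    state: dict[int, int] = {}  # 1 = on current walk, 2 = verified
    for start in parents:
        tid = start
        walk = []
        while state.get(tid) != 2:
            if state.get(tid) == 1:
                raise TaxonomyStructureError(f"cycle detected at taxon {tid}")
            state[tid] = 1
            walk.append(tid)
            if tid == root_id:
                break
            tid = parents[tid]
        for nid in walk:
            state[nid] = 2

    names: dict[int, str] = {}
    for row in _iter_dmp_rows(names_source):
        taxon_id = int(row[0])
        name_txt = row[1].strip()
        name_class = row[3].strip() if len(row) > 3 else "scientific name"
        if name_class == "scientific name" and taxon_id in parents:
            names[taxon_id] = name_txt

    for taxon_id, parent_id in parents.items():
        nodes[taxon_id] = TaxonNode(
            taxon_id=taxon_id,
            parent_id=parent_id,
            rank=ranks[taxon_id],
            name=names.get(taxon_id, f"taxon_{taxon_id}"),
        )

    merged: dict[int, int] = {}
    if merged_source is not None:
        for row in _iter_dmp_rows(merged_source):
            old_id, new_id = int(row[0]), int(row[1])
            if new_id not in nodes:
                raise TaxonomyStructureError(
                    f"merged target {new_id} (for old id {old_id}) is not a loaded taxon"
                )
            merged[old_id] = new_id

    return TaxonomyTree(nodes=nodes, merged=merged, root_id=root_id)


def load_taxonomy_dir(path) -> TaxonomyTree:
    """Load ``nodes.dmp``/``names.dmp`` (and ``merged.dmp`` if present) from a directory."""
    base = os.fspath(path)
    nodes_p = os.path.join(base, "nodes.dmp")
    names_p = os.path.join(base, "names.dmp")
    merged_p = os.path.join(base, "merged.dmp")
    merged = merged_p if os.path.exists(merged_p) else None
    return load_taxonomy(nodes_p, names_p, merged)


def loads_taxonomy(nodes_text: str, names_text: str, merged_text: str | None = None) -> TaxonomyTree:
    """Load a taxonomy from in-memory taxdump-dialect strings (test convenience)."""
    merged = io.StringIO(merged_text) if merged_text else None
    return load_taxonomy(io.StringIO(nodes_text), io.StringIO(names_text), merged)
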