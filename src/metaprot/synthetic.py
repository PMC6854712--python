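"""Synthetic taxonomies and annotation scenarios with planted ground truth.

Everything the pipeline consumes — taxdump files, protein FASTA, protein
group tables, accession->label maps, tabular alignments — can be generated
here with a known planted truth, so the whole tool is testable end to end
without any downloads.

A scenario plants, for every protein group, a true taxon (a leaf of the
synthetic taxonomy) and a true function label.  Each group's members then
receive:

* on-target hits: subject taxon = the planted taxon, label = the planted
  label, bitscore ~ U[90, 200] (always above the retention threshold);
* off-target hits (a ``noise`` fraction of the group's hits): taxon from a
  disjoint clade and one fixed wrong label, bitscore ~ U[80, 150];
* sub-threshold decoy hits (bitscore ~ U[40, 79]) that the retention filter
  must discard.

With ``noise < 0.5`` the planted label holds a strict majority of the
retained votes by construction.  A group marked ``decoy_only`` receives
only sub-threshold hits and must come out unassigned/unknown.  All outputs
are cross-consistent (every alignment query exists in the FASTA and the
group table) and byte-identical for identical seeds.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field

from .taxonomy import TaxonomyTree, loads_taxonomy

__all__ = [
    "RANK_LADDER",
    "SyntheticTaxonomy",
    "GroupTruth",
    "ScenarioSpec",
    "Scenario",
    "generate_taxonomy",
    "plan_scenario",
    "generate_scenario",
    "generate_fasta_with_duplicates",
]

#: Ranks assigned top-down by depth; nodes deeper than the ladder get "no rank".
RANK_LADDER = ("superkingdom", "phylum", "class", "order", "family", "genus")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _dmp_row(*fields) -> str:
    return "\t|\t".join(str(f) for f in fields) + "\t|\n"


@dataclass
class SyntheticTaxonomy:
    """A generated taxonomy: taxdump-dialect texts plus a root-path index.

    ``root_paths`` maps every taxon id to its root-to-node id path and is
    emitted for oracle tests that must not go through the tree's own LCA.
    """

    nodes_text: str
    names_text: str
    merged_text: str
    root_paths: dict[int, tuple[int, ...]]
    leaf_ids: tuple[int, ...]

    def load(self) -> TaxonomyTree:
        return loads_taxonomy(self.nodes_text, self.names_text, self.merged_text)

    def write(self, directory) -> None:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        for fname, text in (
            ("nodes.dmp", self.nodes_text),
            ("names.dmp", self.names_text),
            ("merged.dmp", self.merged_text),
        ):
            with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
                fh.write(text)
        with open(os.path.join(directory, "root_paths.tsv"), "w", encoding="utf-8") as fh:
            fh.write("taxon_id\troot_path\n")
            for tid in sorted(self.root_paths):
                fh.write(f"{tid}\t{';'.join(map(str, self.root_paths[tid]))}\n")


def generate_taxonomy(n_internal: int, n_leaves: int, seed: int) -> SyntheticTaxonomy:
    """Generate a random rooted taxonomy with ``1 + n_internal + n_leaves`` nodes.

    The root is taxon 1; internal nodes attach to a random earlier internal
    node (preferentially the shallower ones, keeping the tree bushy), leaves
    attach to a random internal node and get rank "species".  Identical
    seeds give byte-identical dump texts.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = random.Random(seed)
    parent: dict[int, int] = {1: 1}
    internal = [1]
    next_id = 2
    for _ in range(n_internal):
        parent[next_id] = rng.choice(internal)
        internal.append(next_id)
        next_id += 1
    leaves = []
    for _ in range(n_leaves):
        parent[next_id] = rng.choice(internal)
        leaves.append(next_id)
        next_id += 1

    depths: dict[int, int] = {1: 0}

    def depth(tid: int) -> int:
        if tid not in depths:
            depths[tid] = depth(parent[tid]) + 1
        return depths[tid]

    def rank_of(tid: int) -> str:
        if tid == 1:
            return "no rank"
        if tid in parent and tid not in leaves:
            d = depth(tid) - 1
            return RANK_LADDER[d] if d < len(RANK_LADDER) else "no rank"
        return "species"

    nodes_rows = []
    names_rows = []
    root_paths: dict[int, tuple[int, ...]] = {}
    for tid in sorted(parent):
        nodes_rows.append(_dmp_row(tid, parent[tid], rank_of(tid)))
        name = "root" if tid == 1 else f"Taxon {tid}"
        names_rows.append(_dmp_row(tid, name, "", "scientific name"))
        path = [tid]
        while path[-1] != 1:
            path.append(parent[path[-1]])
        root_paths[tid] = tuple(reversed(path))

    return SyntheticTaxonomy(
        nodes_text="".join(nodes_rows),
        names_text="".join(names_rows),
        merged_text="",
        root_paths=root_paths,
        leaf_ids=tuple(leaves),
    )


@dataclass(frozen=True)
class GroupTruth:
    """Planted truth for one protein group."""

    group_id: str
    taxon_id: int
    label: str
    decoy_only: bool = False


@dataclass
class ScenarioSpec:
    """Study conditions for one synthetic scenario.

    ``noise`` is the fraction of each group's hits that are off-target
    (wrong clade, one fixed wrong label); it must stay below 0.5 so the
    planted label keeps a strict majority.
    """

    groups: list[GroupTruth]
    seed: int
    noise: float = 0.0
    members_per_group: int = 2
    hits_per_group: int = 10
    decoy_hits_per_group: int = 2
    noise_taxon: int = 0
    noise_label: str = "Wrong protein"

    def __post_init__(self):
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise fraction must be in [0, 0.5)")
        if self.hits_per_group < 1 or self.members_per_group < 1:
            raise ValueError("hits_per_group and members_per_group must be >= 1")


@dataclass
class Scenario:
    """Generated scenario files (as text) plus the planted-truth table."""

    proteins_fasta: str
    groups_tsv: str
    annotation_tsv: str
    taxonomy_aln_tsv: str
    functional_aln_tsv: str
    truth_tsv: str
    truth: dict[str, GroupTruth] = field(default_factory=dict)

    _FILES = {
        "proteins.fasta": "proteins_fasta",
        "groups.tsv": "groups_tsv",
        "annotations.tsv": "annotation_tsv",
        "taxonomy_aln.tsv": "taxonomy_aln_tsv",
        "functional_aln.tsv": "functional_aln_tsv",
        "truth.tsv": "truth_tsv",
    }

    def write(self, directory) -> None:
        directory = os.fspath(directory)
        os.makedirs(directory, exist_ok=True)
        for fname, attr in self._FILES.items():
            with open(os.path.join(directory, fname), "w", encoding="utf-8") as fh:
                fh.write(getattr(self, attr))


def plan_scenario(
    tree_fixture: SyntheticTaxonomy,
    n_groups: int,
    noise: float,
    seed: int,
    n_decoy_only: int = 0,
    **overrides,
) -> ScenarioSpec:
    """Plant truths for ``n_groups`` groups on a synthetic taxonomy.

    Planted taxa are distinct leaves; one further leaf is reserved as the
    off-target ("noise") clade.  The last ``n_decoy_only`` groups receive
    only sub-threshold hits.
    """
    leaves = list(tree_fixture.leaf_ids)
    if len(leaves) < n_groups + 1:
        raise ValueError(
            f"taxonomy has {len(leaves)} leaves; need {n_groups + 1} "
            f"({n_groups} planted + 1 noise)"
        )
    rng = random.Random(seed)
    chosen = rng.sample(leaves, n_groups + 1)
    noise_taxon = chosen[-1]
    groups = [
        GroupTruth(
            group_id=f"G{i:03d}",
            taxon_id=chosen[i],
            label=f"Planted protein {i}",
            decoy_only=i >= n_groups - n_decoy_only,
        )
        for i in range(n_groups)
    ]
    return ScenarioSpec(groups=groups, seed=seed, noise=noise,
                        noise_taxon=noise_taxon, **overrides)


def _aln_row(query: str, subject: str, evalue: float, bitscore: float,
             staxid: int | None) -> str:
    # 12-column outfmt-6 dialect; alignment coordinates are placeholders.
    base = (f"{query}\t{subject}\t95.0\t100\t5\t0\t1\t100\t1\t100\t"
            f"{evalue:.2e}\t{bitscore:.1f}")
    if staxid is not None:
        base += f"\t{staxid}"
    return base + "\n"


def generate_scenario(spec: ScenarioSpec, tree: TaxonomyTree) -> Scenario:
    """Materialize a scenario: FASTA, group table, annotation map, alignments.

    Raises ``ValueError`` if a planted taxon (or the noise taxon) is absent
    from the tree.
    """
    for truth in spec.groups:
        if truth.taxon_id not in tree:
            raise ValueError(f"planted taxon {truth.taxon_id} not in taxonomy")
    if spec.noise_taxon and spec.noise_taxon not in tree:
        raise ValueError(f"noise taxon {spec.noise_taxon} not in taxonomy")

    rng = random.Random(spec.seed)
    fasta: list[str] = []
    groups_rows = ["group_id\tmembers\n"]
    ann_rows: list[str] = []
    tax_rows: list[str] = []
    func_rows: list[str] = []
    truth_rows = ["group_id\ttaxon_id\tlabel\tdecoy_only\n"]
    truth_index: dict[str, GroupTruth] = {}

    n_off = int(spec.noise * spec.hits_per_group)
    n_on = spec.hits_per_group - n_off

    for truth in spec.groups:
        gid = truth.group_id
        truth_index[gid] = truth
        members = [f"{gid}_P{m + 1}" for m in range(spec.members_per_group)]
        groups_rows.append(f"{gid}\t{','.join(members)}\n")
        truth_rows.append(
            f"{gid}\t{truth.taxon_id}\t{truth.label}\t{int(truth.decoy_only)}\n"
        )
        for member in members:
            length = rng.randint(60, 180)
            seq = "".join(rng.choice(AMINO_ACIDS) for _ in range(length))
            fasta.append(f">{member} synthetic protein, group {gid}\n")
            for start in range(0, length, 60):
                fasta.append(seq[start:start + 60] + "\n")

        # Hit kinds per group: on-target / off-target / sub-threshold decoys.
        kinds = [] if truth.decoy_only else ["on"] * n_on + ["off"] * n_off
        kinds += ["decoy"] * spec.decoy_hits_per_group
        for k, kind in enumerate(kinds):
            member = members[k % len(members)]
            evalue = 10.0 ** -rng.uniform(20, 80)
            if kind == "on":
                taxon, label = truth.taxon_id, truth.label
                bitscore = rng.uniform(90, 200)
            elif kind == "off":
                taxon, label = spec.noise_taxon, spec.noise_label
                bitscore = rng.uniform(80, 150)
            else:
                taxon, label = spec.noise_taxon, spec.noise_label
                bitscore = rng.uniform(40, 79)
            tax_subject = f"NR_{gid}_{k}"
            func_subject = f"SP_{gid}_{k}"
            tax_rows.append(_aln_row(member, tax_subject, evalue, bitscore, taxon))
            func_rows.append(_aln_row(member, func_subject, evalue, bitscore, None))
            ann_rows.append(f"{func_subject}\t{label}\n")

    return Scenario(
        proteins_fasta="".join(fasta),
        groups_tsv="".join(groups_rows),
        annotation_tsv="".join(ann_rows),
        taxonomy_aln_tsv="".join(tax_rows),
        functional_aln_tsv="".join(func_rows),
        truth_tsv="".join(truth_rows),
        truth=truth_index,
    )


def generate_fasta_with_duplicates(
    n_unique: int, n_duplicates: int, seed: int
) -> tuple[str, int]:
    """FASTA text with ``n_unique`` distinct sequences plus ``n_duplicates``
    records repeating earlier sequences under fresh headers.

    Returns ``(fasta_text, planted_duplicate_count)``; deduplication at
    exact identity must remove exactly that many records.
    """
    if n_unique < 1:
        raise ValueError("need at least one unique record")
    rng = random.Random(seed)
    sequences = [
        "".join(rng.choice(AMINO_ACIDS) for _ in range(rng.randint(50, 120)))
        for _ in range(n_unique)
    ]
    out: list[str] = []
    for i, seq in enumerate(sequences):
        out.append(f">U{i:04d} unique synthetic protein {i}\n{seq}\n")
    for j in range(n_duplicates):
        seq = sequences[rng.randrange(n_unique)]
        out.append(f">D{j:04d} duplicate synthetic protein {j}\n{seq}\n")
    return "".join(out), n_duplicates
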