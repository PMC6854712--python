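# Methods

## Taxonomy model

The taxonomy is a single rooted tree in the NCBI taxdump dialect
(`nodes.dmp` / `names.dmp` / `merged.dmp`; fields separated by `"\t|\t"`,
rows terminated by `"\t|"`). The root is the unique self-parent node.
Loading validates structure eagerly — duplicate ids, dangling parents,
cycles, missing/multiple roots and merged targets that do not resolve are
all hard errors — so every later query can assume a well-formed tree. Only
`scientific name` rows are used; a taxon without one is named `taxon_<id>`.
Merged-id redirection is applied transparently at lookup time; ids present
in neither `nodes` nor `merged` raise a lookup error that the consensus
layer converts into an "unresolvable" count — the taxonomy layer never
silently drops evidence.

The LCA is the strict ("naive") variant: the deepest node that is an
ancestor-or-self of every input taxon, with no minimum-support and no
top-percent bitscore window. Hit-level quality control is done entirely by
the retention filter (below); adding MEGAN-style min-support parameters on
top would change the semantics from "consensus of retained evidence" to a
second, partially redundant filter. Pairwise LCA is computed by lifting the
deeper node to equal depth and walking both paths up in lockstep; depths
are memoized parent walks. At the tree sizes this tool faces (≤ a few
hundred thousand nodes; test trees ≤ 200) this is simpler than and as
reliable as Euler-tour/RMQ preprocessing.

## Hit retention

A hit survives if `bitscore ≥ min_bitscore` (default **80**); survivors are
sorted by descending bitscore — ties broken by ascending e-value, then by
file order (`raw_rank`) — and truncated to `max_hits` (default **20**) per
query. Thresholding precedes truncation: the cap is a cap on *retained*
hits, which is only meaningful after the threshold. The tie-break chain
exists purely for determinism; alignment tools emit ties, and a reproducible
tool cannot let dict/sort instability decide them. Filtering is per query
(alignment output is keyed by query); pooling across a group's members
happens downstream, so a group with many members may use more than
`max_hits` hits in total.

When the e-value column is absent from the configured column layout, hits
carry `evalue = inf`, which sorts them last among bitscore ties — absent
evidence never outranks present evidence.

## Consensus annotation

Evidence of all member proteins of a group is pooled before voting. The
alternative (per-member consensus, then a second vote across members) would
weight members equally regardless of how much evidence each has; pooling
uses every retained hit once and matches standard LCA-binning practice.

*Taxonomic*: a hit whose subject maps to several taxa (semicolon lists in
the `staxids` column) is first collapsed to the LCA of its own taxa, so one
alignment row casts exactly one vote and multi-mapped subjects cannot
dominate. Unresolvable taxa are excluded and counted per group
(`tax_hits_unresolvable`). A group with no resolvable taxonomic evidence is
`unassigned`, never silently placed at the root.

*Functional*: labels are normalized (trim, collapse internal whitespace)
and compared case-insensitively; the reported label is the most frequent
original spelling among the winner's votes. A hit whose subject is missing
from the accession→label map abstains (partial lookup tables are the norm;
treating them as errors would make real annotation tables unusable).
"Uncharacterized protein"-style labels vote like any other label — there is
no exclusion list, because silently discarding a label class would bias the
outcome invisibly. Ties on vote count go to the higher summed bitscore,
then the lexicographically smaller label. Functional sources (e.g. a
UniProt-derived and a COG-derived table) are reported in separate column
triples and never merged into one vote: the two vocabularies are not
commensurable.

## Database construction

Sources are merged in the given order; sequences are normalized to upper
case with trailing `*` (stop codon) stripped. Deduplication is
exact-identity via a sequence-keyed index, first occurrence surviving (file
order — a deterministic rule, since no biological criterion distinguishes
identical sequences). The optional containment mode also removes sequences
that are exact substrings of an already-kept longer sequence, approximating
how a 100%-identity CD-HIT-style clustering absorbs identical fragments;
clustering below 100% identity is deliberately out of scope. The dedup
report accounts for every input record (`kept + removed == input`).

Header hashing digests the full original description line (exact UTF-8
bytes, no trailing newline) — the header, not just the accession, is the
unit of identity — and records the `digest → original` bijection. A digest
collision between distinct headers is a hard error naming both. A header
that already looks like a digest of the configured algorithm (lowercase hex
of the right length) passes through unchanged with a warning, making the
merge → dedup → hash pipeline idempotent end to end.

Scoped databases are assembled from a `ProteinSource` interface. The
bundled implementation serves local FASTA plus an
`accession → taxon, label` metadata table; a remote (UniProt-style)
implementation is a documented extension point and is deliberately not
shipped, so the package never needs network access. `by_taxon` matches the
queried taxon id exactly (retrieval is per-ID; callers wanting a clade
expand it via the taxonomy). Name queries match case-insensitively on whole
words of the normalized label — a documented stand-in for repository-side
name search, whose exact matching rules are not standardized. The optional
taxonomic restriction is an ancestor test on the taxonomy tree.
Per-query retrieval failures are logged and skipped, never fatal.

## Synthetic data

The generator emulates the *shape* of the real inputs, not their biology:
random rooted taxonomies in the taxdump dialect (ranks assigned top-down
from a fixed ladder: superkingdom → … → genus, leaves as species), protein
groups with members, random amino-acid sequences, accession→label maps, and
outfmt-6 alignment tables that are cross-consistent with the FASTA and
group table.

Scenario conditions (defaults): 2 members and 10 hits per group; planted
taxa are distinct leaves; on-target hits carry the planted taxon and label
with bitscore ~ U[90, 200]; a `noise` fraction of hits is off-target (one
reserved disjoint-clade leaf, one fixed wrong label, bitscore ~ U[80, 150]);
2 extra decoy hits per group sit below the threshold (U[40, 79]). The
bitscore ranges deliberately straddle the default threshold of 80 so
filtering is exercised in every run, and `noise < 0.5` guarantees the
planted label a strict arithmetic majority. Groups can be marked
`decoy_only` (sub-threshold hits only) to probe the unassigned path. One
seeded random stream per scenario makes outputs byte-identical per seed.

What passing these scenarios shows: the filtering, pooling, LCA and voting
machinery is correct under controlled evidence. What it does not show:
robustness to real homology structure (hits to *relatives* of the true
taxon rather than to one disjoint clade), realistic bitscore/e-value joint
distributions, chimeric groups, or incomplete reference taxonomies beyond
the unresolvable-id path.

## Numerical and procedural choices

- All randomness flows through explicitly seeded `random.Random` streams.
- Bitscore comparison is plain float comparison; the threshold is inclusive
  (`≥ 80` keeps a hit at exactly 80, matching the stated default).
- Problem sizes in the test and acceptance runs — 50 random trees of ≤ 200
  nodes for the LCA oracle sweep, 25-group scenarios, 1000 randomized
  filter cases — were chosen as the smallest sizes that exercise every code
  path thoroughly; the whole suite runs in a few seconds.
- CLI outputs are written atomically (temp file + rename) with a JSON run
  manifest (inputs, resolved parameters, version). Parameter precedence is
  flag > config file > built-in default, auditable via the manifest.
- Workflow stages are independent subcommands composed in the shell; there
  is intentionally no embedded workflow engine.

## Known limitations

- No retrieval from live UniProt/NCBI; no execution of trimming, assembly,
  gene calling, alignment or sub-100% clustering tools — the package
  consumes their standard file formats instead.
- No peptide-to-protein inference or protein grouping; groups are taken as
  reported by upstream proteomics software.
- The 20-hit cap applies per query, not per group; a group's pooled
  evidence grows with its member count.
- Rank vocabularies are taken as-is; there is no normalization across
  taxonomy versions.
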