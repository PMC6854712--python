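# metaprot

Curated protein search databases and protein-group consensus annotation for
metaproteomics.

## The problem

Mass-spectrometry metaproteomics matches MS/MS spectra against a FASTA
database of candidate proteins, then has to say *which organism* and *which
function* each identification represents. Two steps make this hard in
microbial communities:

1. **Database construction.** Useful search databases combine several
   sources (metagenome-derived proteins, public-repository subsets scoped by
   taxon or by gene/protein name). The merged database must be deduplicated
   and its unwieldy description lines replaced by uniform identifiers.
2. **The protein inference issue.** Identified peptides frequently map to
   many homologous proteins, so proteomics software reports *protein groups*.
   Annotating a group from the single best alignment hit of one member is
   unreliable: the top hits often disagree taxonomically and functionally
   even at very low e-values.

`metaprot` addresses both. It builds the combined search database (merge →
exact-identity deduplication → header hashing, plus taxonomy- and
name-scoped database assembly from a pluggable local protein source), and it
annotates each protein group by **consensus over many retained alignment
hits** instead of the first hit only.

## The method

For each protein group, the tabular alignment hits (BLAST/Diamond
"outfmt 6" dialect) of *all* member proteins are pooled after per-query
filtering — by default only hits with **bitscore ≥ 80** are retained, at
most **20 per query** — and then:

- **Taxonomy:** each retained hit votes with one taxon (a hit mapping to
  several taxa is first collapsed to the LCA of its own taxa); the group is
  annotated at the **lowest common ancestor** of all votes, i.e. the deepest
  node of the NCBI-style taxonomy that is an ancestor-or-self of every
  supported taxon. Conflicting evidence therefore yields a conservative
  annotation at a higher rank rather than a wrong species call.
- **Function:** each retained hit votes with the annotation label
  (e.g. UniProt recommended name, or COG identifier) of its subject
  accession; the group gets the **most frequent label** (ties: higher summed
  bitscore, then lexicographic order). Several functional sources are
  reported side by side, never merged into one vote.

Database post-processing collapses exactly identical sequences (first
occurrence wins; an optional containment mode also absorbs exact
substrings) and replaces every header by its **MD5 digest** (other hashlib
algorithms selectable), keeping a `hashed → original` map for traceability.

## Worked example

Everything below runs offline: the `fixtures` subcommand generates a
synthetic taxonomy and a full scenario with planted ground truth.

```sh
metaprot fixtures --outdir demo --seed 3 --n-groups 4 --noise 0.0 --decoy-only 1
metaprot annotate \
    --groups demo/groups.tsv \
    --taxonomy-aln demo/taxonomy_aln.tsv \
    --functional "uniprot=demo/functional_aln.tsv:demo/annotations.tsv" \
    --taxdump demo/taxdump \
    --out demo/annotations_out.tsv
```

`demo/annotations_out.tsv` then contains:

```
group_id  lca_taxon_id  lca_rank    lca_name    lca_lineage                                         tax_hits_used  tax_hits_unresolvable  uniprot_label         uniprot_support  uniprot_hits_used
G000      19            species     Taxon 19    no rank:root;superkingdom:Taxon 7;species:Taxon 19  10             0                      Planted protein 0     10               10
G001      30            species     Taxon 30    no rank:root;superkingdom:Taxon 3;species:Taxon 30  10             0                      Planted protein 1     10               10
G002      29            species     Taxon 29    no rank:root;superkingdom:Taxon 2;species:Taxon 29  10             0                      Planted protein 2     10               10
G003      unassigned    unassigned  unassigned                                                      0              0                      hypothetical/unknown  0                0
```

Groups G000–G002 recover exactly the planted taxon and label recorded in
`demo/truth.tsv` (10 of 10 retained hits supporting each); G003 was given
only sub-threshold decoy hits (bitscore < 80), so after filtering no
evidence remains and it is reported `unassigned` / `hypothetical/unknown` —
the filter doing its job rather than a failure.

Database construction works the same way:

```sh
metaprot dedup proteins.fasta --out db.fasta --report dedup_report.tsv
# kept 8, removed 2
metaprot hash-headers db.fasta --out db_hashed.fasta --map headermap.tsv
```

or in one step with `metaprot build-db` (merge, dedup, hash, with optional
taxon-id- or name-scoped retrieval from a local protein source). Every
subcommand writes a JSON run manifest recording its inputs and resolved
parameters next to its primary output.

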