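"""Protein-group consensus: LCA taxonomy and most-frequent-name function."""

import io

import pytest

from metaprot.alignments import (
    OUTFMT6_COLUMNS,
    OUTFMT6_TAX_COLUMNS,
    AlignmentHit,
    FilterPolicy,
    filter_hits,
    read_alignments,
)
from metaprot.consensus import (
    UNASSIGNED,
    UNKNOWN_FUNCTION,
    AnnotationMap,
    ProteinGroup,
    annotate_groups,
    functional_consensus,
    normalize_label,
    read_annotation_map,
    read_protein_groups,
    taxonomic_consensus,
)
from metaprot.synthetic import generate_scenario, generate_taxonomy, plan_scenario


def hit(subject, bitscore=100.0, taxa=(), query="p", rank=0):
    return AlignmentHit(query_id=query, subject_id=subject, bitscore=bitscore,
                        evalue=1e-20, subject_taxa=tuple(taxa), raw_rank=rank)


def retained(**by_accession):
    return {acc: filter_hits(hits, FilterPolicy()) for acc, hits in by_accession.items()}


class TestTaxonomicConsensus:
    def test_pooled_members_give_group_lca(self, toy_tree):
        group = ProteinGroup("g", ("p1", "p2"))
        hits = retained(
            p1=[hit("a", taxa=[562], query="p1")],
            p2=[hit("b", taxa=[1236], query="p2")],
        )
        result = taxonomic_consensus(group, hits, toy_tree)
        assert result.lca_taxon == 1236
        assert result.hits_used == 2
        assert result.lineage[-1] == ("class", "Gammaproteobacteria")

    def test_no_taxon_evidence_means_unassigned(self, toy_tree):
        group = ProteinGroup("g", ("p1",))
        hits = retained(p1=[hit("a"), hit("b", rank=1)])
        result = taxonomic_consensus(group, hits, toy_tree)
        assert result.lca_taxon is None
        assert result.hits_used == 0
        assert result.hits_unresolvable == 2

    def test_singleton_hit_is_identity(self, toy_tree):
        group = ProteinGroup("g", ("p1",))
        result = taxonomic_consensus(
            group, retained(p1=[hit("a", taxa=[1423])]), toy_tree)
        assert result.lca_taxon == 1423

    def test_multi_taxon_hit_collapses_to_own_lca_first(self, toy_tree):
        # One row mapping to both E. coli and B. subtilis votes once, as
        # Bacteria; together with a Proteobacteria vote the group LCA is 2.
        group = ProteinGroup("g", ("p1",))
        hits = retained(p1=[hit("a", taxa=[562, 1423]),
                            hit("b", taxa=[1224], rank=1)])
        result = taxonomic_consensus(group, hits, toy_tree)
        assert result.lca_taxon == 2
        assert result.hits_used == 2

    def test_unresolvable_ids_counted_not_fatal(self, toy_tree):
        group = ProteinGroup("g", ("p1",))
        hits = retained(p1=[hit("a", taxa=[9999]), hit("b", taxa=[562], rank=1)])
        result = taxonomic_consensus(group, hits, toy_tree)
        assert result.lca_taxon == 562
        assert result.hits_unresolvable == 1
        assert result.hits_used == 1

    def test_ancestor_evidence_never_deepens_lca(self, toy_tree):
        group = ProteinGroup("g", ("p1",))
        base = [hit("a", taxa=[562])]
        with_anc = base + [hit("b", taxa=[1224], rank=1)]
        lca_base = taxonomic_consensus(group, retained(p1=base), toy_tree).lca_taxon
        lca_anc = taxonomic_consensus(group, retained(p1=with_anc), toy_tree).lca_taxon
        assert toy_tree.is_ancestor(lca_anc, lca_base)

    def test_disjoint_clade_moves_lca_strictly_rootward(self, toy_tree):
        group = ProteinGroup("g", ("p1",))
        base = [hit("a", taxa=[562])]
        with_far = base + [hit("b", taxa=[1423], rank=1)]
        lca_base = taxonomic_consensus(group, retained(p1=base), toy_tree).lca_taxon
        lca_far = taxonomic_consensus(group, retained(p1=with_far), toy_tree).lca_taxon
        assert lca_far != lca_base
        assert toy_tree.is_ancestor(lca_far, lca_base)


class TestFunctionalConsensus:
    def test_simple_majority(self):
        group = ProteinGroup("g", ("p1",))
        amap = AnnotationMap({"a": "DnaK", "b": "DnaK", "c": "GroEL"})
        hits = retained(p1=[hit("a"), hit("b", rank=1), hit("c", rank=2)])
        result = functional_consensus(group, hits, amap)
        assert (result.label, result.support, result.hits_used) == ("DnaK", 2, 3)

    def test_tie_broken_by_summed_bitscore(self):
        group = ProteinGroup("g", ("p1",))
        amap = AnnotationMap({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        hits = retained(p1=[
            hit("a1", bitscore=80), hit("a2", bitscore=90, rank=1),      # A: 170...
            hit("b1", bitscore=100, rank=2), hit("b2", bitscore=110, rank=3),  # B: 210
        ])
        result = functional_consensus(group, hits, amap)
        assert (result.label, result.support, result.hits_used) == ("B", 2, 4)

    def test_full_tie_broken_lexicographically(self):
        group = ProteinGroup("g", ("p1",))
        amap = AnnotationMap({"a": "Zeta", "b": "Alpha"})
        hits = retained(p1=[hit("a", bitscore=100), hit("b", bitscore=100, rank=1)])
        assert functional_consensus(group, hits, amap).label == "Alpha"

    def test_no_votes_is_unknown(self):
        group = ProteinGroup("g", ("p1",))
        result = functional_consensus(group, {}, AnnotationMap())
        assert (result.label, result.support, result.hits_used) == \
            (UNKNOWN_FUNCTION, 0, 0)

    def test_missing_mapping_abstains(self):
        group = ProteinGroup("g", ("p1",))
        amap = AnnotationMap({"a": "DnaK"})
        hits = retained(p1=[hit("a"), hit("unmapped", rank=1)])
        result = functional_consensus(group, hits, amap)
        assert (result.support, result.hits_used) == (1, 1)

    def test_casefold_voting_reports_majority_casing(self):
        group = ProteinGroup("g", ("p1",))
        amap = AnnotationMap({"a": "dnaK", "b": "dnaK", "c": "DNAK", "d": "GroEL"})
        hits = retained(p1=[hit("a"), hit("b", rank=1), hit("c", rank=2),
                            hit("d", rank=3)])
        result = functional_consensus(group, hits, amap)
        assert result.label == "dnaK"
        assert result.support == 3

    def test_support_and_abstentions_account_for_all_hits(self):
        group = ProteinGroup("g", ("p1", "p2"))
        amap = AnnotationMap({"a": "X", "b": "X", "c": "Y"})
        hits = retained(
            p1=[hit("a", query="p1"), hit("c", query="p1", rank=1)],
            p2=[hit("b", query="p2"), hit("nohit", query="p2", rank=1)],
        )
        result = functional_consensus(group, hits, amap)
        pooled = 4
        abstentions = pooled - result.hits_used
        losers = result.hits_used - result.support
        assert result.support + abstentions + losers == pooled

    def test_normalize_label_collapses_whitespace(self):
        assert normalize_label("  heat  shock\tprotein ") == "heat shock protein"


def scenario_tables(n_groups=5, noise=0.0, seed=11, n_decoy_only=0):
    taxonomy = generate_taxonomy(8, max(12, n_groups + 2), seed)
    tree = taxonomy.load()
    spec = plan_scenario(taxonomy, n_groups, noise, seed, n_decoy_only=n_decoy_only)
    scenario = generate_scenario(spec, tree)
    groups = read_protein_groups(io.StringIO(scenario.groups_tsv))
    args = (
        groups,
        read_alignments(io.StringIO(scenario.taxonomy_aln_tsv),
                        columns=OUTFMT6_TAX_COLUMNS),
        [("uniprot",
          read_alignments(io.StringIO(scenario.functional_aln_tsv),
                          columns=OUTFMT6_COLUMNS),
          read_annotation_map(io.StringIO(scenario.annotation_tsv)))],
        tree,
    )
    return scenario, args


class TestAnnotateGroups:
    def test_noise_free_scenario_recovers_all_planted_truth(self):
        scenario, args = scenario_tables(n_groups=5, noise=0.0)
        table = annotate_groups(*args)
        assert len(table) == 5
        for _, row_ in table.iterrows():
            truth = scenario.truth[row_["group_id"]]
            assert row_["lca_taxon_id"] == truth.taxon_id
            assert row_["uniprot_label"] == truth.label

    def test_rows_follow_input_group_order(self):
        _, args = scenario_tables(n_groups=4)
        table = annotate_groups(*args)
        assert list(table["group_id"]) == [g.group_id for g in args[0]]

    def test_empty_group_list_gives_empty_table(self, toy_tree):
        table = annotate_groups([], [], [], toy_tree)
        assert len(table) == 0

    def test_taxonomy_only_run_reports_unknown_function(self, toy_tree):
        groups = [ProteinGroup("g1", ("p1",))]
        hits = [hit("a", taxa=[562], query="p1")]
        table = annotate_groups(groups, hits,
                                [("uniprot", [], AnnotationMap())], toy_tree)
        assert table.loc[0, "uniprot_label"] == UNKNOWN_FUNCTION
        assert table.loc[0, "lca_taxon_id"] == 562

    def test_member_without_alignments_is_allowed(self, toy_tree):
        groups = [ProteinGroup("g1", ("p1", "p_silent"))]
        hits = [hit("a", taxa=[562], query="p1")]
        table = annotate_groups(groups, hits, [], toy_tree)
        assert table.loc[0, "lca_taxon_id"] == 562

    def test_unmatched_queries_ignored(self, toy_tree):
        groups = [ProteinGroup("g1", ("p1",))]
        hits = [hit("a", taxa=[562], query="p1"),
                hit("b", taxa=[1423], query="not_a_member")]
        table = annotate_groups(groups, hits, [], toy_tree)
        assert table.loc[0, "lca_taxon_id"] == 562

    def test_duplicate_group_id_is_input_error(self, toy_tree):
        groups = [ProteinGroup("g1", ("p1",)), ProteinGroup("g1", ("p2",))]
        with pytest.raises(ValueError, match="duplicate group id"):
            annotate_groups(groups, [], [], toy_tree)

    def test_unassigned_group_has_empty_lineage_cell(self, toy_tree):
        groups = [ProteinGroup("g1", ("p1",))]
        table = annotate_groups(groups, [], [], toy_tree)
        assert table.loc[0, "lca_taxon_id"] == UNASSIGNED
        assert table.loc[0, "lca_lineage"] == ""

    def test_output_is_byte_identical_across_runs(self, tmp_path):
        texts = []
        for _ in range(2):
            _, args = scenario_tables(n_groups=6, noise=0.2, seed=99)
            texts.append(annotate_groups(*args).to_csv(sep="\t", index=False))
        assert texts[0] == texts[1]


class TestReaders:
    def test_group_table_round_trip(self, stream):
        text = "group_id\tmembers\nG1\tp1,p2\nG2\tp3\n"
        groups = read_protein_groups(stream(text))
        assert [(g.group_id, g.members) for g in groups] == \
            [("G1", ("p1", "p2")), ("G2", ("p3",))]

    def test_duplicate_group_in_table_rejected(self, stream):
        with pytest.raises(ValueError, match="duplicate"):
            read_protein_groups(stream("G1\tp1\nG1\tp2\n"))

    def test_group_with_duplicate_members_rejected(self):
        with pytest.raises(ValueError, match="duplicate members"):
            ProteinGroup("g", ("p1", "p1"))

    def test_annotation_map_normalizes_and_rejects_empty(self, stream):
        amap = read_annotation_map(stream("acc1\t Heat  shock protein \n"))
        assert amap.get("acc1") == "Heat shock protein"
        with pytest.raises(ValueError, match="empty annotation label"):
            read_annotation_map(stream("acc2\t   \n"))
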