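"""Module orthology links, intragenic duplications and clade assignment."""

import pytest

from modevol.modmap import (
    ConfigurationError,
    assign_clades,
    detect_intragenic_duplications,
    map_orthologous_modules,
)
from modevol.trees import parse_newick


def _perfect_synteny_tree():
    return parse_newick(
        "((X|g1|m01,Y|g2|m01)100:1,(X|g1|m02,Y|g2|m02)100:1,(X|g1|m03,Y|g2|m03)100:1);"
    )


class TestOrthologLinks:
    def test_perfect_synteny_gives_complete_one_to_one_map(self):
        links = map_orthologous_modules(_perfect_synteny_tree())
        assert [(l.module_a, l.module_b) for l in links] == [
            ("X|g1|m01", "Y|g2|m01"),
            ("X|g1|m02", "Y|g2|m02"),
            ("X|g1|m03", "Y|g2|m03"),
        ]
        assert all(l.support >= 50 for l in links)

    def test_unattainable_threshold_gives_no_links(self):
        assert map_orthologous_modules(_perfect_synteny_tree(), threshold=101) == []

    def test_links_symmetric_in_gene_order(self):
        t1 = parse_newick("((X|g1|m01,Y|g2|m01)90:1,(Y|g2|m02,X|g1|m02)90:1,Z|g3|m01:1);")
        links = map_orthologous_modules(t1)
        pairs = {frozenset((l.module_a, l.module_b)) for l in links}
        assert frozenset(("X|g1|m01", "Y|g2|m01")) in pairs
        assert frozenset(("X|g1|m02", "Y|g2|m02")) in pairs

    def test_raising_threshold_never_adds_links(self):
        tree = parse_newick(
            "((X|g1|m01,Y|g2|m01)60:1,(X|g1|m02,Y|g2|m02)40:1,Z|g3|m01:1);"
        )
        low = {frozenset((l.module_a, l.module_b)) for l in map_orthologous_modules(tree, threshold=30)}
        mid = {frozenset((l.module_a, l.module_b)) for l in map_orthologous_modules(tree, threshold=50)}
        high = {frozenset((l.module_a, l.module_b)) for l in map_orthologous_modules(tree, threshold=70)}
        assert high <= mid <= low

    def test_emitted_links_meet_threshold(self):
        tree = parse_newick(
            "((X|g1|m01,Y|g2|m01)49:1,(X|g1|m02,Y|g2|m02)50:1,Z|g3|m01:1);"
        )
        links = map_orthologous_modules(tree, threshold=50)
        assert [(l.module_a, l.module_b) for l in links] == [("X|g1|m02", "Y|g2|m02")]

    def test_links_one_to_one_per_gene_pair_under_duplication(self):
        # gene Y duplicated its module: both copies are candidates; exactly
        # one link is emitted for the gene pair and module
        tree = parse_newick(
            "(((Y|g2|m01,Y|g2|m02)95,X|g1|m01)95:1,(X|g1|m02,Y|g2|m03)95:1,Z|g3|m01:1);"
        )
        links = map_orthologous_modules(tree, threshold=50)
        from_x1 = [l for l in links if "X|g1|m01" in (l.module_a, l.module_b)]
        assert len(from_x1) == 1


class TestIntragenic:
    def test_single_gene_clade_reported_with_member_indices(self):
        tree = parse_newick(
            "(((X|g1|m02,X|g1|m03)85,X|g1|m06)85:1,(X|g1|m01,Y|g2|m01)90:1,Y|g2|m02:1);"
        )
        groups = detect_intragenic_duplications(tree)
        assert len(groups) == 1
        assert groups[0]["module_indices"] == "2,3,6"
        assert groups[0]["gene"] == "X|g1"
        assert groups[0]["support"] == 85

    def test_fully_interleaved_tree_has_no_groups(self):
        assert detect_intragenic_duplications(_perfect_synteny_tree()) == []

    def test_groups_are_maximal(self):
        tree = parse_newick(
            "(((X|g1|m01,X|g1|m02)99,(X|g1|m03,X|g1|m04)99)99:1,"
            "(Y|g2|m01,Y|g2|m02)99:1,Z|g3|m01:1);"
        )
        groups = detect_intragenic_duplications(tree)
        genes = sorted(g["gene"] for g in groups)
        assert genes == ["X|g1", "Y|g2"]
        x = next(g for g in groups if g["gene"] == "X|g1")
        assert x["n_modules"] == 4  # the maximal clade, not its sub-cherries

    def test_low_support_groups_excluded(self):
        tree = parse_newick(
            "((X|g1|m01,X|g1|m02)30:1,(X|g1|m03,Y|g2|m01)90:1,Y|g2|m02:1);"
        )
        assert detect_intragenic_duplications(tree, threshold=50) == []


class TestCladeAssignment:
    def _tree(self):
        return parse_newick(
            "(((Tr_virens|g1|m01,REF1a)90,REF1b)90:1,"
            "((Toly_oph|g2|m01,REF2a)90,REF2b)90:1,"
            "(Toly_inf|g3|m01,REF3a)90:1);"
        )

    def _refs(self):
        return {"REF1a": "1", "REF1b": "1", "REF2a": "2", "REF2b": "2", "REF3a": "3"}

    def test_query_inside_pure_reference_clade_gets_its_label(self):
        ca = assign_clades(self._tree(), self._refs())
        assert ca.assignments["Tr_virens|g1|m01"] == "1"
        assert ca.assignments["Toly_oph|g2|m01"] == "2"
        assert ca.assignments["Toly_inf|g3|m01"] == "3"

    def test_tally_counts_per_genus_per_clade(self):
        ca = assign_clades(self._tree(), self._refs())
        tally = ca.tally.set_index("clade")
        assert tally.loc["1", "Tr"] == 1
        assert tally.loc["2", "Toly"] == 1
        assert tally.loc["3", "Toly"] == 1

    def test_query_with_only_mixed_references_above_is_unassigned(self):
        tree = parse_newick("((REF1,REF2)90,(q|g|m01,REF3)40:1);")
        ca = assign_clades(tree, {"REF1": "1", "REF2": "2", "REF3": "3"})
        assert ca.assignments["q|g|m01"] == "3"  # smallest pure clade wins
        tree2 = parse_newick("(q|g|m01,(REF1,REF2)90,REF3);")
        ca2 = assign_clades(tree2, {"REF1": "1", "REF2": "2", "REF3": "1"})
        assert ca2.assignments["q|g|m01"] == "unassigned"

    def test_missing_reference_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            assign_clades(self._tree(), {"REF1a": "1", "NOT_IN_TREE": "2"})
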