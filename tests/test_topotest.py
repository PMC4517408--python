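"""Species-tree regrafting and the HGT hypothesis comparison."""

import pytest

from modevol.topotest import (
    CladeError,
    TopologyHypothesis,
    compare_hypotheses,
    regraft,
)
from modevol.trees import canonical_newick, parse_newick


class TestRegraft:
    def test_regraft_single_leaf_to_new_sister(self, species4):
        alt = regraft(species4, {"A"}, {"C"})
        assert canonical_newick(alt) == "(((A,C),D),B);"

    def test_identity_move_preserves_topology(self, species4):
        alt = regraft(species4, {"A"}, {"B"})
        assert canonical_newick(alt) == canonical_newick(species4)

    def test_whole_clade_move(self):
        t = parse_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")
        alt = regraft(t, {"A", "B"}, {"D", "E"})
        assert canonical_newick(alt) == "(((A,B),(D,E)),C);"

    def test_root_clade_rejected(self, species4):
        with pytest.raises(CladeError):
            regraft(species4, {"A", "B", "C", "D"}, {"A"})

    def test_non_clade_set_rejected_with_taxa_named(self, species4):
        with pytest.raises(CladeError, match="A.*C|do not form"):
            regraft(species4, {"A", "C"}, {"B"})

    def test_overlapping_sets_rejected(self, species4):
        with pytest.raises(CladeError):
            regraft(species4, {"A"}, {"A", "B"})

    def test_affected_branch_lengths_set_to_one(self, species4):
        alt = regraft(species4, {"A"}, {"C"})
        moved = next(n for n in alt.postorder() if n.name == "A")
        assert moved.length == 1.0

    def test_original_tree_not_mutated(self, species4):
        before = canonical_newick(species4)
        regraft(species4, {"A"}, {"C"})
        assert canonical_newick(species4) == before


class TestCompareHypotheses:
    def _gene(self):
        return parse_newick("(a,b,(c,d));")

    def _lm(self):
        return {"a": "A", "b": "B", "c": "C", "d": "D"}

    def test_identical_hypotheses_have_zero_deltas(self, species4):
        hyps = [
            TopologyHypothesis("original", species4),
            TopologyHypothesis("same", species4.copy()),
        ]
        cmp = compare_hypotheses(self._gene(), hyps, self._lm())
        assert (cmp.table[["delta_dc", "delta_dup", "delta_loss"]] == 0).all().all()
        assert cmp.verdicts["same"] == "no change in deep-coalescence cost"

    def test_report_carries_three_count_columns_per_hypothesis(self, species4):
        hyps = [
            TopologyHypothesis("original", species4),
            TopologyHypothesis("alt", regraft(species4, {"A"}, {"C"})),
        ]
        cmp = compare_hypotheses(self._gene(), hyps, self._lm())
        for col in ("dc_cost", "duplications", "losses"):
            assert col in cmp.table.columns
        assert len(cmp.table) == 2

    def test_order_invariance(self, species4):
        alt = regraft(species4, {"A"}, {"C"})
        h1 = [TopologyHypothesis("original", species4), TopologyHypothesis("alt", alt)]
        h2 = [TopologyHypothesis("alt", alt), TopologyHypothesis("original", species4)]
        t1 = compare_hypotheses(self._gene(), h1, self._lm()).table
        t2 = compare_hypotheses(self._gene(), h2, self._lm()).table
        assert t1.to_dict(orient="records") == t2.to_dict(orient="records")

    def test_loss_only_improvement_flagged_as_insufficient_for_hgt(self):
        # gene tree concordant with neither topology, but the alternative
        # reduces losses without changing duplications
        species = parse_newick("(((A:1,B:1):1,C:1):1,D:1);")
        alt = regraft(species, {"C"}, {"D"})
        gene = parse_newick("(a,b,(c,d));")
        cmp = compare_hypotheses(
            gene,
            [TopologyHypothesis("original", species), TopologyHypothesis("alt", alt)],
            {"a": "A", "b": "B", "c": "C", "d": "D"},
        )
        row = cmp.table[cmp.table.hypothesis == "alt"].iloc[0]
        if row.delta_dc < 0 and row.delta_dup == 0:
            assert cmp.hgt_supported["alt"] is False
            assert "not sufficient" in cmp.verdicts["alt"]

    def test_taxon_set_mismatch_rejected(self, species4):
        other = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(CladeError):
            compare_hypotheses(
                self._gene(),
                [TopologyHypothesis("original", species4), TopologyHypothesis("x", other)],
                self._lm(),
            )

    def test_needs_at_least_two_hypotheses(self, species4):
        with pytest.raises(ValueError):
            compare_hypotheses(
                self._gene(), [TopologyHypothesis("original", species4)], self._lm()
            )

    def test_true_topology_beats_wrong_topology_on_simulated_families(self):
        # families simulated with duplications on the true species tree:
        # reconciling against a wrong topology should rarely cost less
        from modevol.simulate import (
            SimulationParams,
            SpeciesTreeSpec,
            simulate_module_history,
        )
        from modevol.reconcile import count_events

        true_sp = SpeciesTreeSpec(
            parse_newick("(((A:10,B:10):10,(C:10,D:10):10):10,(E:10,F:10):10);"),
            subs_scale=0.0,
        )
        wrong = regraft(true_sp.tree, {"A", "B"}, {"E", "F"})
        params = SimulationParams(
            n_init_modules=1, dup_rate=0.02, loss_rate=0.0, seed=23, n_families=50,
            seq_length=1,
        )
        hist = simulate_module_history(true_sp, params)
        wins = 0
        for g in hist.gene_trees:
            dc_true = count_events(g, true_sp.tree).dc_cost
            dc_wrong = count_events(g.copy(), wrong).dc_cost
            if dc_true <= dc_wrong:
                wins += 1
        assert wins >= int(0.95 * params.n_families)
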