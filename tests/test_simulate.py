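"""Module-family simulator: species trees, histories, sequences, export."""

import math

import numpy as np
import pytest

from modevol.simulate import (
    InvalidParameterError,
    SimulationParams,
    SpeciesTreeSpec,
    simulate_module_history,
    simulate_sequences,
    simulate_species_tree,
    write_dataset,
    _evolve,
)
from modevol.trees import Node, canonical_newick, parse_newick, to_newick


def test_species_tree_two_taxa_is_single_cherry():
    spec = simulate_species_tree(2, seed=1)
    assert len(spec.taxa) == 2
    assert len([n for n in spec.tree.postorder() if n.children]) == 1


def test_species_tree_seed_determinism():
    a = simulate_species_tree(5, seed=7)
    b = simulate_species_tree(5, seed=7)
    assert to_newick(a.tree) == to_newick(b.tree)


def test_species_tree_binary_node_count():
    # a rooted binary tree on n leaves has n-1 internal nodes, for any seed
    for seed in range(200):
        spec = simulate_species_tree(6, seed=seed)
        assert len([n for n in spec.tree.postorder() if n.children]) == 5
        assert all(
            n.length > 0 for n in spec.tree.postorder() if n.parent is not None
        )


def test_species_tree_rejects_single_taxon():
    with pytest.raises(InvalidParameterError):
        simulate_species_tree(1, seed=0)


def test_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        SimulationParams(n_init_modules=0)
    with pytest.raises(InvalidParameterError):
        SimulationParams(dup_rate=-1)
    with pytest.raises(InvalidParameterError):
        SpeciesTreeSpec(parse_newick("((A:1,B:1):1,C:0);"))  # zero-length branch


def _no_event_params(**kw):
    base = dict(
        n_init_modules=1, dup_rate=0.0, loss_rate=0.0, seed=5, n_families=50, seq_length=1
    )
    base.update(kw)
    return SimulationParams(**base)


def test_no_events_long_branches_gene_trees_concordant():
    # tau = 50 everywhere: lineage sorting is essentially impossible
    spec = SpeciesTreeSpec(parse_newick("((A:50,B:50):50,C:100);"), subs_scale=0.0)
    hist = simulate_module_history(spec, _no_event_params())
    for g in hist.gene_trees:
        relabeled = g.copy()
        for leaf in relabeled.leaves():
            leaf.name = leaf.name.split("|")[0]
        assert canonical_newick(relabeled) == canonical_newick(spec.tree)


def test_pure_birth_mean_module_count():
    # single effective branch of tau=10 at dup rate 0.1: E[tips] = e^(lambda tau)
    spec = SpeciesTreeSpec(parse_newick("(A:10,B:0.001);"), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=1, dup_rate=0.1, loss_rate=0.0, seed=3, n_families=2000, seq_length=1
    )
    hist = simulate_module_history(spec, params)
    counts = hist.architectures[hist.architectures.species == "A"]["n_modules"]
    mean = counts.sum() / params.n_families
    se = counts.std() / math.sqrt(params.n_families)
    assert abs(mean - math.e) < 3 * se


def test_tip_count_equals_initial_plus_ancestral_duplications():
    # with no losses, each species' module count is n_init + duplications on
    # its root-to-tip path (exact, from the event log)
    spec = SpeciesTreeSpec(parse_newick("((A:5,B:5):5,C:10);"), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=2, dup_rate=0.05, loss_rate=0.0, seed=11, n_families=40, seq_length=1
    )
    hist = simulate_module_history(spec, params)
    branch_names = {n.name for n in spec.tree.postorder()}
    paths = {"A": ["A"], "B": ["B"], "C": ["C"]}
    ab = next(n.name for n in spec.tree.postorder() if set(n.leaf_names()) == {"A", "B"})
    paths["A"].append(ab)
    paths["B"].append(ab)
    for fam in range(params.n_families):
        ev = hist.events[hist.events.family == fam]
        for sp in "ABC":
            dups = int(
                ((ev.event == "duplication") & ev.branch.isin(paths[sp])).sum()
            )
            row = hist.architectures[
                (hist.architectures.species == sp)
                & (hist.architectures.gene == f"F{fam + 1:03d}")
            ]
            assert int(row.n_modules.iloc[0]) == params.n_init_modules + dups


def test_event_log_replay_reproduces_architectures():
    """Replaying duplication/loss events from the root reproduces the ordered
    tip architectures exactly."""
    spec = SpeciesTreeSpec(parse_newick("((A:3,B:3):3,C:6);"), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=3, dup_rate=0.15, loss_rate=0.1, seed=13, n_families=60, seq_length=1
    )
    hist = simulate_module_history(spec, params)
    from modevol.trees import auto_label_internal

    auto_label_internal(spec.tree)
    for fam in range(params.n_families):
        gene = f"F{fam + 1:03d}"
        ev = hist.events[hist.events.family == fam]

        def replay(node, modules):
            if node.parent is not None:
                bev = ev[ev.branch == node.name].sort_values("time_on_branch")
                for row in bev.itertuples(index=False):
                    if row.event == "duplication":
                        i = modules.index(row.lineage)
                        modules.insert(i + 1, int(row.new_lineage))
                    else:
                        modules.remove(row.lineage)
            if node.is_leaf:
                assert hist.tip_lineages[(gene, node.name)] == modules
            for c in node.children:
                replay(c, list(modules))

        replay(spec.tree, list(range(1, params.n_init_modules + 1)))


def test_ortholog_pairs_symmetric_and_cross_species():
    spec = SpeciesTreeSpec(parse_newick("((A:5,B:5):5,C:10);"), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=2, dup_rate=0.05, loss_rate=0.02, seed=17, n_families=20, seq_length=1
    )
    hist = simulate_module_history(spec, params)
    for pair in hist.ortholog_pairs:
        a, b = sorted(pair)
        assert a.split("|")[0] != b.split("|")[0]
        assert a.split("|")[1] == b.split("|")[1]  # same family


def test_sequences_zero_rate_identical_to_root():
    spec = SpeciesTreeSpec(parse_newick("((A:5,B:5):5,C:10);"), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=1, dup_rate=0.0, loss_rate=0.0, seed=2, n_families=3, seq_length=80
    )
    hist = simulate_module_history(spec, params)
    seqs = simulate_sequences(hist, spec, params)
    for fam, records in seqs.items():
        assert len({s for _, s in records}) == 1


def test_p_distance_matches_twenty_state_jukes_cantor():
    # two sequences separated by exactly d substitutions/site in expectation
    d = 0.25
    tree = parse_newick(f"(x:{d / 2},y:{d / 2});")
    rng = np.random.default_rng(99)
    ps = []
    for _ in range(400):
        root = rng.integers(20, size=250)
        seqs = _evolve(root, tree, scale=1.0, rng=rng)
        p = float(np.mean(seqs["x"] != seqs["y"]))
        ps.append(p)
    expected = (19 / 20) * (1 - math.exp(-20 * d / 19))
    se = np.std(ps) / math.sqrt(len(ps))
    assert abs(np.mean(ps) - expected) < 3 * se


def test_dataset_export_is_byte_identical_under_seed(tmp_path):
    spec = simulate_species_tree(4, seed=21, subs_scale=0.02)
    params = SimulationParams(
        n_init_modules=2, dup_rate=0.05, loss_rate=0.02, seed=21, n_families=4, seq_length=60
    )
    outs = []
    for sub in ("a", "b"):
        hist = simulate_module_history(spec, params)
        seqs = simulate_sequences(hist, spec, params)
        out = tmp_path / sub
        write_dataset(out, spec, params, hist, seqs)
        outs.append(out)
    a, b = outs
    files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    assert files
    for f in files:
        assert (a / f).read_bytes() == (b / f).read_bytes()
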