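"""Seeded validation experiments for every stage of the pipeline.

Each function runs one self-contained experiment — simulating its own inputs,
running the package's main code path, and measuring agreement against either
an independent brute-force reference (:mod:`modevol.bruteforce`), a
closed-form expectation, or the simulator's ground truth. The experiment
conditions (tree shapes, rates, family counts) are fixed here and documented
in the package's methods note; the ``seed`` argument controls every source of
randomness.

All functions return flat dicts of numbers so the results can be dumped
straight into a report.
"""

from __future__ import annotations

import filecmp
import math
import tempfile
import time
from pathlib import Path

import numpy as np

from .bruteforce import oracle_counts, oracle_unrooted_min
from .builder import ModuleAlignment, bootstrap_supports, compute_distances, neighbor_joining
from .mining import SeedAlignment, build_profile, scan_protein, scan_proteins
from .modmap import detect_intragenic_duplications, map_orthologous_modules
from .pipeline import generate_fixture, run_pipeline
from .reconcile import count_events, reconcile_unrooted
from .simulate import (
    AMINO_ACIDS,
    SimulationParams,
    SpeciesTreeSpec,
    simulate_module_history,
    simulate_sequences,
)
from .trees import Node, canonical_newick, parse_newick, rf_distance

# Balanced six-taxon species trees used by the recovery experiments.
_BALANCED6 = "(((A:{t},B:{t}):{t},(C:{t},D:{t}):{t}):{t},(E:{t},F:{t}):{t});"


def _balanced6(tau: float) -> Node:
    return parse_newick(_BALANCED6.format(t=tau))


# ---------------------------------------------------------------------------
# Random reconciliation instances
# ---------------------------------------------------------------------------


def _rand_topology(rng, items: list[Node]) -> Node:
    nodes = list(items)
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        nodes.append(Node(children=[a, b]))
    root = nodes[0]
    for n in root.postorder():
        if n.parent is not None:
            n.length = 1.0
    return root


def _rand_species(rng, n_max: int = 6) -> Node:
    n = int(rng.integers(2, n_max + 1))
    labels = [chr(ord("A") + i) for i in range(n)]
    return _rand_topology(rng, [Node(name=l) for l in labels])


def _rand_gene(rng, species: Node, n_max: int = 8, n_min: int = 2):
    taxa = species.leaf_names()
    n = int(rng.integers(n_min, n_max + 1))
    picks = [taxa[int(rng.integers(len(taxa)))] for _ in range(n)]
    leaves = [Node(name=f"{sp}|g|x{i}") for i, sp in enumerate(picks)]
    leaf_map = {l.name: l.name.split("|")[0] for l in leaves}
    return _rand_topology(rng, leaves), leaf_map


def _unroot(gene: Node) -> Node:
    """Two-child root -> standard trifurcating unrooted representation."""
    a, b = gene.children
    inner = b if b.children else a
    outer = a if inner is b else b
    root = Node(children=[outer, *inner.children])
    return root


def oracle_agreement(n_instances: int = 500, seed: int = 0) -> dict:
    """Main LCA reconciliation vs brute-force enumeration on random instances."""
    rng = np.random.default_rng([seed % (2**31), 11])
    agree = 0
    for _ in range(n_instances):
        species = _rand_species(rng)
        gene, leaf_map = _rand_gene(rng, species)
        rec = count_events(gene, species, leaf_map)
        ora = oracle_counts(gene, species, leaf_map)
        if rec.summary() == ora:
            agree += 1
    return {"agreement_fraction": agree / n_instances, "n": n_instances}


def single_copy_identity(n_instances: int = 500, seed: int = 0) -> dict:
    """dc_cost = losses - 2*duplications on random single-copy instances.

    Single-copy means one gene copy per species (total coverage), the setting
    in which the identity is a theorem.
    """
    rng = np.random.default_rng([seed % (2**31), 12])
    holds = 0
    for _ in range(n_instances):
        species = _rand_species(rng)
        taxa = species.leaf_names()
        leaves = [Node(name=t) for t in taxa]
        gene = _rand_topology(rng, leaves)
        rec = count_events(gene, species, {t: t for t in taxa})
        if rec.dc_cost == rec.losses - 2 * rec.duplications:
            holds += 1
    return {"identity_fraction": holds / n_instances, "n": n_instances}


def unrooted_minimization(n_instances: int = 200, seed: int = 0) -> dict:
    """reconcile_unrooted vs exhaustive rooting enumeration with oracle costs."""
    rng = np.random.default_rng([seed % (2**31), 13])
    agree = 0
    for _ in range(n_instances):
        species = _rand_species(rng)
        gene, leaf_map = _rand_gene(rng, species, n_min=3)
        unrooted = _unroot(gene)
        rec = reconcile_unrooted(unrooted, species, leaf_map, criterion="dc")
        best_cost, optimal = oracle_unrooted_min(unrooted, species, leaf_map, "dc")
        if rec.dc_cost == best_cost and rec.optimal_rootings == optimal:
            agree += 1
    return {"agreement_fraction": agree / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# Coalescent calibration and event recovery
# ---------------------------------------------------------------------------


def discordance_calibration(
    taus=(0.5, 1.0, 2.0), n_families: int = 10000, seed: int = 0
) -> dict:
    """Three-taxon gene-tree discordance vs the closed form (2/3)exp(-tau)."""
    out: dict = {"n_families": n_families}
    for tau in taus:
        species = SpeciesTreeSpec(
            parse_newick(f"((A:1,B:1):{tau},C:{1 + tau});"), subs_scale=0.0
        )
        params = SimulationParams(
            n_init_modules=1,
            dup_rate=0.0,
            loss_rate=0.0,
            seed=(seed * 1000 + int(tau * 10)) % (2**31),
            n_families=n_families,
            seq_length=1,
        )
        history = simulate_module_history(species, params)
        disc = 0
        for g in history.gene_trees:
            cherry = next(
                n for n in g.postorder() if n.children and all(c.is_leaf for c in n.children)
            )
            if {c.name.split("|")[0] for c in cherry.children} != {"A", "B"}:
                disc += 1
        p = disc / n_families
        expected = (2.0 / 3.0) * math.exp(-tau)
        se = math.sqrt(expected * (1 - expected) / n_families)
        key = f"{tau:g}"
        out[f"observed_tau{key}"] = p
        out[f"expected_tau{key}"] = expected
        out[f"abs_z_tau{key}"] = abs(p - expected) / se
    return out


def duplication_recovery(n_families: int = 200, seed: int = 0) -> dict:
    """Exact recovery of simulated duplication counts in the no-ILS regime.

    Branches of 1000 coalescent units make lineage sorting vanishingly rare;
    a single ancestral module per family means every inferred duplication
    must correspond to a logged event. The duplication rate is set so the
    expected number of duplication-speciation boundary interactions over the
    whole experiment is ~0.03 (see the methods note).
    """
    species = SpeciesTreeSpec(_balanced6(1000.0), subs_scale=0.0)
    params = SimulationParams(
        n_init_modules=1,
        dup_rate=2.5e-5,
        loss_rate=0.0,
        seed=seed % (2**31),
        n_families=n_families,
        seq_length=1,
    )
    history = simulate_module_history(species, params)
    exact = 0
    total_true = 0
    for fam, gtree in enumerate(history.gene_trees):
        true = int(
            (
                (history.events["family"] == fam)
                & (history.events["event"] == "duplication")
            ).sum()
        )
        total_true += true
        rec = count_events(gtree, species.tree)
        if rec.duplications == true:
            exact += 1

    # null model: no events at all on a finite-depth tree -> inferred
    # duplications are pure ILS artifacts, absent on concordant families
    species2 = SpeciesTreeSpec(_balanced6(2.0), subs_scale=0.0)
    params2 = SimulationParams(
        n_init_modules=1,
        dup_rate=0.0,
        loss_rate=0.0,
        seed=(seed + 1) % (2**31),
        n_families=100,
        seq_length=1,
    )
    hist2 = simulate_module_history(species2, params2)
    concordant_ok = discordant_ok = True
    for g in hist2.gene_trees:
        relabeled = g.copy()
        for leaf in relabeled.leaves():
            leaf.name = leaf.name.split("|")[0]
        concordant = canonical_newick(relabeled) == canonical_newick(species2.tree)
        rec = count_events(g, species2.tree)
        if concordant and (rec.duplications != 0 or rec.dc_cost != 0):
            concordant_ok = False
        if not concordant and rec.dc_cost == 0:
            discordant_ok = False
    return {
        "families_exact": exact,
        "n_families": n_families,
        "exact_fraction": exact / n_families,
        "total_true_duplications": total_true,
        "concordant_null_zero": bool(concordant_ok),
        "discordant_positive_dc": bool(discordant_ok),
    }


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------


def _path_distances(tree: Node):
    leaves = [n for n in tree.postorder() if n.is_leaf]
    ids = [n.name for n in leaves]
    D = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(leaves):
        dist_up = {}
        n, d = a, 0.0
        while n is not None:
            dist_up[id(n)] = d
            d += n.length or 0.0
            n = n.parent
        for j, b in enumerate(leaves):
            if j <= i:
                continue
            n, d = b, 0.0
            while id(n) not in dist_up:
                d += n.length or 0.0
                n = n.parent
            D[i, j] = D[j, i] = d + dist_up[id(n)]
    return D, ids


def nj_consistency(n_trees: int = 100, seed: int = 0) -> dict:
    """NJ recovers the generating topology from additive distances (RF = 0)."""
    rng = np.random.default_rng([seed % (2**31), 14])
    ok = 0
    for _ in range(n_trees):
        n = int(rng.integers(5, 13))
        leaves = [Node(name=f"t{i}") for i in range(n)]
        true = _rand_topology(rng, leaves)
        for node in true.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.1, 1.0))
        D, ids = _path_distances(true)
        est = neighbor_joining(D, ids)
        if rf_distance(est, true) == 0:
            ok += 1
    return {"rf_zero_fraction": ok / n_trees, "n": n_trees}


# ---------------------------------------------------------------------------
# Domain mining
# ---------------------------------------------------------------------------


def _mutate(seq: str, frac: float, rng) -> str:
    s = list(seq)
    k = int(round(frac * len(s)))
    for i in rng.choice(len(s), size=k, replace=False):
        s[i] = AMINO_ACIDS[(AMINO_ACIDS.index(s[i]) + 1 + int(rng.integers(19))) % 20]
    return "".join(s)


def mining_recovery(
    seed: int = 0,
    n_proteins: int = 40,
    n_decoys: int = 20,
    profile_len: int = 120,
    max_divergence: float = 0.2,
) -> dict:
    """Planted-module recall/precision plus the short-hit length filter."""
    rng = np.random.default_rng([seed % (2**31), 15])
    consensus = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(20, size=profile_len))
    seed_aln = SeedAlignment([_mutate(consensus, 0.1, rng) for _ in range(8)])
    profile = build_profile(seed_aln)

    proteins = []
    truth: set[tuple[str, int]] = set()
    for k in range(n_proteins):
        n_mod = int(rng.integers(1, 4))
        linker = lambda: "".join(
            AMINO_ACIDS[int(i)] for i in rng.integers(20, size=int(rng.integers(40, 120)))
        )
        parts = [linker()]
        pos = len(parts[0])
        pid = f"P{k:03d}"
        for _ in range(n_mod):
            module = _mutate(consensus, float(rng.uniform(0.0, max_divergence)), rng)
            truth.add((pid, pos + 1))
            parts.append(module)
            pos += profile_len
            lk = linker()
            parts.append(lk)
            pos += len(lk)
        proteins.append((pid, "".join(parts)))
    for k in range(n_decoys):
        proteins.append(
            (
                f"D{k:03d}",
                "".join(AMINO_ACIDS[int(i)] for i in rng.integers(20, size=400)),
            )
        )

    hits = scan_proteins(proteins, profile, min_len=100)
    predicted = {(h.protein_id, h.start) for h in hits}
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0

    # a profile shorter than the minimum length can never yield a hit
    short_cons = consensus[:80]
    short_profile = build_profile(SeedAlignment([short_cons] * 4))
    planted = "".join(
        AMINO_ACIDS[int(i)] for i in rng.integers(20, size=150)
    ) + short_cons + "".join(AMINO_ACIDS[int(i)] for i in rng.integers(20, size=150))
    short_hits = scan_protein("SHORT", planted, short_profile, min_len=100)
    unfiltered = scan_protein("SHORT", planted, short_profile, min_len=1)
    return {
        "precision": precision,
        "recall": recall,
        "n_planted": len(truth),
        "n_hits": len(predicted),
        "short_hit_found_without_filter": len(unfiltered),
        "short_hit_after_filter": len(short_hits),
    }


# ---------------------------------------------------------------------------
# Module synteny / intragenic duplication recovery
# ---------------------------------------------------------------------------

_SYNTENY_SPECIES = lambda: SpeciesTreeSpec(_balanced6(20.0), subs_scale=0.004)


def synteny_recovery(n_families: int = 200, seed: int = 0, bootstrap: int = 100) -> dict:
    """Ortholog-link precision/recall against simulator ground truth.

    Long (500-column) module alignments on a low-ILS species tree, trees
    built with the package's NJ+bootstrap path, links mapped at the standard
    support threshold of 50.
    """
    species = _SYNTENY_SPECIES()
    params = SimulationParams(
        n_init_modules=3,
        dup_rate=5e-4,
        loss_rate=0.0,
        seed=seed % (2**31),
        n_families=n_families,
        seq_length=500,
    )
    history = simulate_module_history(species, params)
    seqs = simulate_sequences(history, species, params)
    tp = fp = fn = 0
    for fam in range(n_families):
        gene = f"F{fam + 1:03d}"
        recs = seqs.get(gene)
        if not recs or len(recs) < 4:
            continue
        aln = ModuleAlignment(recs)
        tree = bootstrap_supports(aln, replicates=bootstrap, seed=(seed + fam) % (2**31))
        links = map_orthologous_modules(tree, threshold=50)
        predicted = {frozenset((l.module_a, l.module_b)) for l in links}
        tag = f"|{gene}|"
        true = {p for p in history.ortholog_pairs if tag in next(iter(p))}
        tp += len(predicted & true)
        fp += len(predicted - true)
        fn += len(true - predicted)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "true_pairs": tp + fn,
        "predicted_pairs": tp + fp,
        "n_families": n_families,
    }


def intragenic_recovery(n_target: int = 200, seed: int = 0, bootstrap: int = 100) -> dict:
    """Detection of simulated within-branch (lineage-specific) duplications.

    Families are conditioned on carrying at least one duplication on a
    terminal species branch — the only duplications that leave a single-gene
    clade signature; detection succeeds when some reported intragenic group
    contains both the template module and its copy.
    """
    species = _SYNTENY_SPECIES()
    detected = examined = 0
    batch = 0
    while examined < n_target and batch < 6:
        params = SimulationParams(
            n_init_modules=3,
            dup_rate=3e-3,
            loss_rate=0.0,
            seed=(seed + 7919 * batch) % (2**31),
            n_families=120,
            seq_length=500,
        )
        history = simulate_module_history(species, params)
        seqs = simulate_sequences(history, species, params)
        taxa = set(species.taxa)
        for fam in range(params.n_families):
            if examined >= n_target:
                break
            gene = f"F{fam + 1:03d}"
            ev = history.events
            pend = ev[
                (ev["family"] == fam)
                & (ev["event"] == "duplication")
                & (ev["branch"].isin(taxa))
            ]
            if not len(pend):
                continue
            pairs = []
            for row in pend.itertuples(index=False):
                tips = history.tip_lineages.get((gene, row.branch), [])
                if row.lineage in tips and row.new_lineage in tips:
                    la = f"{row.branch}|{gene}|m{tips.index(row.lineage) + 1:02d}"
                    lb = f"{row.branch}|{gene}|m{tips.index(row.new_lineage) + 1:02d}"
                    pairs.append({la, lb})
            if not pairs:
                continue
            aln = ModuleAlignment(seqs[gene])
            tree = bootstrap_supports(
                aln, replicates=bootstrap, seed=(seed + 31 * fam + batch) % (2**31)
            )
            groups = detect_intragenic_duplications(tree, threshold=50)
            members = [set(g["modules"].split(",")) for g in groups]
            examined += 1
            if any(any(p <= m for m in members) for p in pairs):
                detected += 1
        batch += 1
    return {
        "detected": detected,
        "examined": examined,
        "detection_fraction": detected / examined if examined else 0.0,
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

_STABLE_SUFFIXES = (".tsv", ".nwk", ".fasta", ".afa", ".txt")


def pipeline_determinism(seed: int = 42) -> dict:
    """Fixture pipeline runs end to end; reruns are byte-identical."""
    t0 = time.time()
    with tempfile.TemporaryDirectory() as tmp:
        d1, d2 = Path(tmp) / "a", Path(tmp) / "b"
        cfg1 = generate_fixture(seed, d1)
        run_pipeline(cfg1)
        elapsed = time.time() - t0
        cfg2 = generate_fixture(seed, d2)
        run_pipeline(cfg2)
        files1 = sorted(
            p.relative_to(d1)
            for p in d1.rglob("*")
            if p.is_file() and p.suffix in _STABLE_SUFFIXES
        )
        files2 = sorted(
            p.relative_to(d2)
            for p in d2.rglob("*")
            if p.is_file() and p.suffix in _STABLE_SUFFIXES
        )
        identical = files1 == files2 and all(
            filecmp.cmp(d1 / f, d2 / f, shallow=False) for f in files1
        )
        expected = [
            "run/reconciliation.tsv",
            "run/extra_lineages.tsv",
            "run/node_events.tsv",
            "run/module_links.tsv",
            "run/intragenic_groups.tsv",
            "run/hypothesis_comparison.tsv",
            "run/coalescence_depth.tsv",
            "run/hits.tsv",
            "run/architectures.tsv",
        ]
        all_present = all((d1 / f).exists() for f in expected)
    return {
        "byte_identical": bool(identical),
        "all_tables_present": bool(all_present),
        "n_compared_files": len(files1),
        "runtime_seconds": elapsed,
    }
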