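"""Synthetic evolution of multi-modular gene families.

Generates the full ground-truthed stand-in for a comparative-genomic study of
NRPS module evolution: a species tree (Yule process, branch lengths in
coalescent units), per-family module histories evolving by module duplication
and module loss along the species tree, gene trees drawn from a multispecies
coalescent running inside the resulting locus tree, and amino-acid sequences
evolved along the gene trees under a 20-state Jukes-Cantor-like model.

Model layering
--------------
1. *Locus tree* (forward in time): each family starts with ``n_init_modules``
   module lineages at the species root. On every species branch each live
   module lineage independently experiences duplications (rate ``dup_rate``)
   and losses (rate ``loss_rate``) as Poisson processes; a duplication inserts
   the new copy immediately after its template in the gene's module order, a
   loss removes the lineage. At speciation nodes surviving lineages are copied
   into both daughter branches.
2. *Gene tree* (backward in time): one gene lineage per surviving tip module;
   within every locus-tree branch lineages coalesce at rate k(k-1)/2 per
   coalescent unit; lineages remaining at the family origin coalesce freely
   above the species root. At a duplication node the daughter locus's
   lineages are constrained to coalesce at the duplication instant, and the
   resulting single lineage joins a uniformly chosen resident lineage of the
   parent locus at that instant — every copy of a new locus descends from one
   resident gene at the moment of duplication.

All events are logged; the log, the true gene trees, the true cross-species
ortholog pairs (pairs whose locus-tree MRCA is a speciation node) and the tip
module architectures form the :class:`TrueHistory` ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .trees import Node, auto_label_internal, to_newick

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InvalidParameterError(ValueError):
    pass


@dataclass
class SpeciesTreeSpec:
    """A rooted binary species tree with branch lengths in coalescent units.

    ``subs_scale`` converts coalescent units into expected amino-acid
    substitutions per site for the sequence simulator.
    """

    tree: Node
    subs_scale: float = 0.01

    def __post_init__(self):
        self.validate()

    @property
    def taxa(self) -> list[str]:
        return self.tree.leaf_names()

    def validate(self) -> None:
        names = self.tree.leaf_names()
        if len(names) != len(set(names)):
            raise InvalidParameterError("species labels must be unique")
        for n in self.tree.postorder():
            if n.children and len(n.children) != 2:
                raise InvalidParameterError("species tree must be strictly binary")
            if n.parent is not None and (n.length is None or n.length <= 0):
                raise InvalidParameterError("all species-tree branch lengths must be > 0")
        if self.subs_scale < 0:
            raise InvalidParameterError("subs_scale must be >= 0")


@dataclass
class SimulationParams:
    """Knobs of the module-family simulator (rates per coalescent unit)."""

    n_init_modules: int = 3
    dup_rate: float = 0.05
    loss_rate: float = 0.02
    seed: int = 0
    n_families: int = 10
    seq_length: int = 200
    alphabet: str = AMINO_ACIDS
    #: coalescent units between successive ancestral duplications above the
    #: species root. The ancestral modules stand for long-established paralog
    #: lineages (ancient module diversity predating the sampled radiation),
    #: so their divergences are placed at regular deep intervals.
    ancestral_spacing: float = 10.0

    def __post_init__(self):
        if self.n_init_modules < 1:
            raise InvalidParameterError("n_init_modules must be >= 1")
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise InvalidParameterError("rates must be >= 0")
        if self.seq_length < 1:
            raise InvalidParameterError("seq_length must be >= 1")
        if self.n_families < 1:
            raise InvalidParameterError("n_families must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_init_modules": self.n_init_modules,
            "dup_rate": self.dup_rate,
            "loss_rate": self.loss_rate,
            "seed": self.seed,
            "n_families": self.n_families,
            "seq_length": self.seq_length,
            "alphabet": self.alphabet,
            "ancestral_spacing": self.ancestral_spacing,
        }


@dataclass
class TrueHistory:
    """Ground truth of one simulation run."""

    events: pd.DataFrame
    gene_trees: list  # one rooted Node per family (None if family went extinct)
    ortholog_pairs: set  # frozenset({leaf_a, leaf_b}) across all families
    architectures: pd.DataFrame  # species, gene, n_modules, modules
    tip_lineages: dict = field(default_factory=dict)  # (family, species) -> [lineage ids]


# ---------------------------------------------------------------------------
# Species-tree simulation (Yule)
# ---------------------------------------------------------------------------


def simulate_species_tree(
    n_taxa: int, seed: int, branch_scale: float = 1.0, subs_scale: float = 0.01
) -> SpeciesTreeSpec:
    """Yule (pure-birth) species tree with exponential waiting times.

    Speciation rate 1 per lineage; after the n-th lineage appears the tree is
    extended by one further exponential waiting time to the present, so tip
    branches have positive length. ``branch_scale`` multiplies every branch.
    """
    if n_taxa < 2:
        raise InvalidParameterError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = []  # (node, birth time)
    for _ in range(2):
        active.append((root.add_child(Node()), 0.0))
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node, birth = active.pop(i)
        node.length = (t - birth) * branch_scale
        active.append((node.add_child(Node()), t))
        active.append((node.add_child(Node()), t))
    t_end = t + rng.exponential(1.0 / n_taxa)
    for node, birth in active:
        node.length = (t_end - birth) * branch_scale
    for i, leaf in enumerate(root.leaves()):
        leaf.name = f"S{i + 1}"
    return SpeciesTreeSpec(tree=root, subs_scale=subs_scale)


# ---------------------------------------------------------------------------
# Module-history simulation
# ---------------------------------------------------------------------------


class _LocusNode:
    """Node of the per-family locus tree (events in module-lineage history).

    ``creator`` is the module-lineage id whose event created the node; on a
    duplication node ``lineage`` carries the id of the NEW (daughter) locus,
    so the daughter-side child can be identified unambiguously.
    """

    __slots__ = ("kind", "time", "branch", "children", "parent", "lineage", "species", "creator")

    def __init__(self, kind, time, branch=None, lineage=None, species=None, creator=None):
        self.kind = kind  # "root" | "dup" | "loss" | "spec" | "tip"
        self.time = time
        self.branch = branch
        self.children: list[_LocusNode] = []
        self.parent: Optional[_LocusNode] = None
        self.lineage = lineage
        self.species = species
        self.creator = creator

    def add(self, child: "_LocusNode") -> "_LocusNode":
        child.parent = self
        self.children.append(child)
        return child


class _Lineage:
    __slots__ = ("node", "lid")

    def __init__(self, node, lid):
        self.node = node  # locus node this lineage descends from
        self.lid = lid


def _node_times(root: Node) -> dict[Node, float]:
    times = {root: 0.0}
    for n in root.preorder():
        for c in n.children:
            times[c] = times[n] + c.length
    return times


def _simulate_family(
    species: SpeciesTreeSpec, params: SimulationParams, fam: int, rng: np.random.Generator
):
    """Forward duplication/loss pass for one family; returns locus structures."""
    stree = species.tree
    times = _node_times(stree)
    lam, mu = params.dup_rate, params.loss_rate
    total = lam + mu
    counter = [0]

    def new_lid():
        counter[0] += 1
        return counter[0]

    events = []
    # Each ancestral module's locus begins at the species-root speciation
    # (a "root" node at time 0). With several ancestral modules, the loci are
    # ancient paralogs: their stems are joined by duplication nodes above the
    # root at fixed deep spacing (random join order), modelling long-diverged
    # ancestral module lineages.
    root_lineages = []
    stems = []
    for _ in range(params.n_init_modules):
        lid = new_lid()
        r = _LocusNode("root", 0.0, lineage=lid, creator=lid)
        stems.append((r, lid))
        root_lineages.append(_Lineage(r, lid))
    t_anc = 0.0
    while len(stems) > 1:
        kk = len(stems)
        t_anc -= params.ancestral_spacing
        i = int(rng.integers(kk))
        j = int(rng.integers(kk - 1))
        if j >= i:
            j += 1
        (anode, alid) = stems[i]
        (bnode, blid) = stems[j]
        dup = _LocusNode("dup", t_anc, creator=alid, lineage=blid)
        dup.add(anode)
        dup.add(bnode)
        stems = [s for idx, s in enumerate(stems) if idx not in (i, j)]
        stems.append((dup, alid))
    roots = [stems[0][0]]

    tip_lineages: dict[str, list] = {}
    tip_nodes: dict[str, list] = {}

    stack = [(c, list(root_lineages)) for c in reversed(stree.children)]
    while stack:
        snode, incoming = stack.pop()
        # lineages entering the branch above snode keep their module order
        t0, t1 = times[snode.parent], times[snode]
        live = list(incoming)
        t = t0
        while live and total > 0:
            k = len(live)
            t += rng.exponential(1.0 / (k * total))
            if t >= t1:
                break
            i = int(rng.integers(k))
            lin = live[i]
            if rng.random() < (lam / total if total else 0.0):
                new_id = new_lid()
                ev = _LocusNode("dup", t, branch=snode.name, lineage=new_id, creator=lin.lid)
                lin.node.add(ev)
                new = _Lineage(ev, new_id)
                cont = _Lineage(ev, lin.lid)
                live[i] = cont
                live.insert(i + 1, new)
                events.append((fam, "duplication", snode.name, t - t0, lin.lid, new_id))
            else:
                ev = _LocusNode("loss", t, branch=snode.name, lineage=lin.lid, creator=lin.lid)
                lin.node.add(ev)
                live.pop(i)
                events.append((fam, "loss", snode.name, t - t0, lin.lid, None))
        if snode.is_leaf:
            tips = []
            for lin in live:
                tn = _LocusNode(
                    "tip", t1, branch=snode.name, lineage=lin.lid, species=snode.name,
                    creator=lin.lid,
                )
                lin.node.add(tn)
                tips.append(tn)
            tip_lineages[snode.name] = [lin.lid for lin in live]
            tip_nodes[snode.name] = tips
        else:
            # one speciation node per surviving lineage, shared by both daughters
            spns = []
            for lin in live:
                spn = _LocusNode(
                    "spec", t1, branch=snode.name, lineage=lin.lid, species=snode.name,
                    creator=lin.lid,
                )
                lin.node.add(spn)
                spns.append(spn)
            for c in reversed(snode.children):
                stack.append(
                    (c, [_Lineage(spn, lin.lid) for spn, lin in zip(spns, live)])
                )
    return roots, events, tip_lineages, tip_nodes


def _coalesce_pool(pool, t_hi, t_lo, rng, ne: float = 1.0):
    """Backward coalescence of (node, time) pairs from t_hi down to t_lo.

    ``t_lo`` may be ``-inf`` for free coalescence; ``ne`` rescales the
    coalescence rate (relative effective population size). Returns the
    surviving pool.
    """
    t = t_hi
    while len(pool) > 1:
        k = len(pool)
        wait = rng.exponential(2.0 * ne / (k * (k - 1)))
        if t - wait < t_lo:
            break
        t -= wait
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a = pool[max(i, j)]
        b = pool[min(i, j)]
        pool.remove(a)
        pool.remove(b)
        pool.append(_merge(a, b, t))
    return pool


def _merge(a, b, t):
    node = Node()
    an, at = a
    bn, bt = b
    an.length = at - t
    bn.length = bt - t
    node.add_child(an)
    node.add_child(bn)
    return (node, t)


def _gene_tree_for_family(roots, leaf_label, rng) -> Optional[Node]:
    """Multispecies coalescent within the locus forest of one family."""

    def process(lnode) -> list:
        if lnode.kind == "tip":
            leaf = Node(name=leaf_label[id(lnode)])
            return [(leaf, lnode.time)]
        if lnode.kind == "loss":
            return []
        pools = []
        for c in lnode.children:
            sub = process(c)
            sub = _coalesce_pool(sub, c.time, lnode.time, rng)
            pools.append(sub)
        if lnode.kind == "dup" and len(lnode.children) == 2:
            # the daughter-side child was created by the new locus's lineage
            if lnode.children[0].creator == lnode.lineage:
                daughter_pool, parent_pool = pools
            else:
                parent_pool, daughter_pool = pools
            # all copies of the new locus descend from one resident gene at
            # the duplication instant: force the daughter bottleneck, then
            # join a uniformly chosen resident lineage
            while len(daughter_pool) > 1:
                a = daughter_pool.pop(int(rng.integers(len(daughter_pool))))
                b = daughter_pool.pop(int(rng.integers(len(daughter_pool))))
                daughter_pool.append(_merge(a, b, lnode.time))
            if daughter_pool and parent_pool:
                d = daughter_pool.pop()
                j = int(rng.integers(len(parent_pool)))
                parent_pool[j] = _merge(parent_pool[j], d, lnode.time)
            return parent_pool + daughter_pool
        merged = []
        for p in pools:
            merged.extend(p)
        return merged

    pool = []
    for r in roots:
        pool.extend(process(r))
    if not pool:
        return None
    t_origin = min(r.time for r in roots)
    pool = _coalesce_pool(pool, t_origin, -math.inf, rng)
    root, _ = pool[0]
    root.length = None
    return root


def _locus_mrca_kind(a: _LocusNode, b: _LocusNode) -> Optional[str]:
    anc = set()
    x = a
    while x is not None:
        anc.add(id(x))
        x = x.parent
    x = b
    while x is not None:
        if id(x) in anc:
            return x.kind
        x = x.parent
    return None  # different ancestral loci


def simulate_module_history(species: SpeciesTreeSpec, params: SimulationParams) -> TrueHistory:
    """Simulate duplication/loss + coalescent histories for all families."""
    auto_label_internal(species.tree)
    all_events = []
    gene_trees = []
    ortho: set = set()
    arch_rows = []
    tip_lineages_all = {}

    for fam in range(params.n_families):
        rng = np.random.default_rng([params.seed % (2**31), fam])
        gene = f"F{fam + 1:03d}"
        roots, events, tip_lineages, tip_nodes = _simulate_family(species, params, fam, rng)
        all_events.extend(events)

        leaf_label = {}
        labels_by_tip = {}
        for sp in species.taxa:
            tips = tip_nodes.get(sp, [])
            for pos, tn in enumerate(tips, start=1):
                lbl = f"{sp}|{gene}|m{pos:02d}"
                leaf_label[id(tn)] = lbl
                labels_by_tip[id(tn)] = lbl
            if tips:
                arch_rows.append(
                    {
                        "species": sp,
                        "gene": gene,
                        "n_modules": len(tips),
                        "modules": ",".join(leaf_label[id(t)] for t in tips),
                    }
                )
            tip_lineages_all[(gene, sp)] = list(tip_lineages.get(sp, []))

        gtree = _gene_tree_for_family(roots, leaf_label, rng)
        gene_trees.append(gtree)

        # true ortholog pairs from locus-tree MRCA kinds
        flat = [(sp, tn) for sp in species.taxa for tn in tip_nodes.get(sp, [])]
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                (sa, ta), (sb, tb) = flat[i], flat[j]
                if sa == sb:
                    continue
                # the per-locus root node is the speciation at the species root
                if _locus_mrca_kind(ta, tb) in ("spec", "root"):
                    ortho.add(frozenset((labels_by_tip[id(ta)], labels_by_tip[id(tb)])))

    events_df = pd.DataFrame(
        all_events,
        columns=["family", "event", "branch", "time_on_branch", "lineage", "new_lineage"],
    )
    arch_df = pd.DataFrame(arch_rows, columns=["species", "gene", "n_modules", "modules"])
    return TrueHistory(
        events=events_df,
        gene_trees=gene_trees,
        ortholog_pairs=ortho,
        architectures=arch_df,
        tip_lineages=tip_lineages_all,
    )


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def _evolve(root_seq: np.ndarray, tree: Node, scale: float, rng, n_states: int = 20):
    """Poisson substitutions along each branch; uniform replacement residue."""
    seqs = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.parent is not None and node.length and scale > 0:
            seq = seq.copy()
            nsub = rng.poisson(len(seq) * node.length * scale)
            for _ in range(nsub):
                site = int(rng.integers(len(seq)))
                seq[site] = (seq[site] + 1 + int(rng.integers(n_states - 1))) % n_states
        if node.is_leaf:
            seqs[node.name] = seq
        else:
            for c in node.children:
                stack.append((c, seq))
    return seqs


def simulate_sequences(
    history: TrueHistory, species: SpeciesTreeSpec, params: SimulationParams
) -> dict[str, list[tuple[str, str]]]:
    """Amino-acid sequences for every tip module, one record list per family.

    Root sequence uniform over the alphabet; each gene-tree branch of length b
    (coalescent units) receives Poisson(seq_length * b * subs_scale)
    substitutions, each replacing the residue with a uniformly chosen
    different residue.
    """
    out = {}
    alpha = np.frombuffer(params.alphabet.encode(), dtype=np.uint8)
    for fam, gtree in enumerate(history.gene_trees):
        if gtree is None:
            continue
        gene = f"F{fam + 1:03d}"
        rng = np.random.default_rng([params.seed % (2**31), 10**6 + fam])
        root_seq = rng.integers(len(params.alphabet), size=params.seq_length)
        seqs = _evolve(root_seq, gtree, species.subs_scale, rng, len(params.alphabet))
        records = []
        for name in sorted(seqs):
            records.append((name, alpha[seqs[name]].tobytes().decode()))
        out[gene] = records
    return out


# ---------------------------------------------------------------------------
# Dataset export
# ---------------------------------------------------------------------------


def write_dataset(
    outdir,
    species: SpeciesTreeSpec,
    params: SimulationParams,
    history: TrueHistory,
    sequences: Optional[dict] = None,
) -> None:
    """Write the simulated dataset as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "families").mkdir(parents=True, exist_ok=True)
    with open(outdir / "species_tree.nwk", "w") as fh:
        fh.write(to_newick(species.tree) + "\n")
    with open(outdir / "true_gene_trees.nwk", "w") as fh:
        for g in history.gene_trees:
            fh.write((to_newick(g) if g is not None else "") + "\n")
    history.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
    history.architectures.to_csv(outdir / "architectures.tsv", sep="\t", index=False)
    pairs = sorted(tuple(sorted(p)) for p in history.ortholog_pairs)
    pd.DataFrame(pairs, columns=["module_a", "module_b"]).to_csv(
        outdir / "ortholog_pairs.tsv", sep="\t", index=False
    )
    with open(outdir / "params.json", "w") as fh:
        json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if sequences is not None:
        for gene in sorted(sequences):
            with open(outdir / "families" / f"{gene}.fasta", "w") as fh:
                for name, seq in sequences[gene]:
                    fh.write(f">{name}\n{seq}\n")
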