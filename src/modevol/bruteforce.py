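"""Independent brute-force reference implementations for cross-checking.

These functions recompute reconciliation quantities by direct enumeration
over leaf sets, deliberately avoiding the depth-arithmetic LCA machinery of
:mod:`modevol.reconcile`:

* the mapping is found by scanning all species nodes for the smallest clade
  containing a gene node's species set;
* deep-coalescence cost is counted per species branch as the number of
  maximal gene subtrees whose species all lie inside the branch's subtree
  (the lineage classes traversing the branch), minus one;
* losses walk explicit ancestor chains.

They are used as oracles in the test suite and the acceptance benchmarks and
must stay independent of the main code path.
"""

from __future__ import annotations

from .trees import Node, canonical_newick, enumerate_rootings


def oracle_mapping(gene: Node, species: Node, leaf_map: dict[str, str]) -> dict:
    """Gene node -> smallest species clade containing its species, by scan."""
    sp_sets = [(n, frozenset(n.leaf_names())) for n in species.postorder()]
    M = {}
    for v in gene.postorder():
        sps = frozenset(leaf_map[l] for l in v.leaf_names())
        best, best_size = None, None
        for s, ss in sp_sets:
            if sps <= ss and (best_size is None or len(ss) < best_size):
                best, best_size = s, len(ss)
        if best is None:
            raise ValueError(f"species set {sorted(sps)} not contained in the species tree")
        M[v] = best
    return M


def oracle_counts(gene: Node, species: Node, leaf_map: dict[str, str]) -> dict:
    """Duplications, losses and deep-coalescence cost by direct enumeration."""
    M = oracle_mapping(gene, species, leaf_map)

    dup_nodes = [
        v
        for v in gene.postorder()
        if v.children and any(M[v] is M[c] for c in v.children)
    ]
    duplications = len(dup_nodes)
    dup_set = set(id(v) for v in dup_nodes)

    # losses: explicit ancestor chain from M(child) up to M(parent)
    losses = 0
    for u in gene.postorder():
        for v in u.children:
            chain = []
            z = M[v]
            while z is not M[u]:
                chain.append(z)
                z = z.parent
            losses += len(chain) - 1 + (1 if id(u) in dup_set else 0)

    # deep coalescence: per species branch, count maximal gene subtrees whose
    # leaf species all lie within the branch's subtree
    dc = 0
    for s in species.postorder():
        if s.parent is None:
            continue
        S = set(s.leaf_names())
        classes = 0
        stack = [gene]
        while stack:
            n = stack.pop()
            sps = {leaf_map[l] for l in n.leaf_names()}
            if not (sps & S):
                continue
            if sps <= S:
                classes += 1
            else:
                stack.extend(n.children)
        dc += max(0, classes - 1)
    return {"duplications": duplications, "losses": losses, "dc_cost": dc}


def oracle_unrooted_min(
    gene: Node, species: Node, leaf_map: dict[str, str], criterion: str = "dc"
):
    """Exhaustive minimum over rootings, costed with :func:`oracle_counts`."""
    key = {"dc": "dc_cost", "dup": "duplications", "duploss": None}[criterion]
    best_cost = None
    optimal = []
    for rooted in enumerate_rootings(gene):
        c = oracle_counts(rooted, species, leaf_map)
        cost = c["duplications"] + c["losses"] if key is None else c[key]
        if best_cost is None or cost < best_cost:
            best_cost = cost
            optimal = [canonical_newick(rooted)]
        elif cost == best_cost:
            optimal.append(canonical_newick(rooted))
    return best_cost, sorted(set(optimal))
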