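"""Horizontal-gene-transfer topology test by re-reconciliation.

The test follows the comparative logic of reconciling the same module tree
against the original species tree and against an alternative obtained by a
prune-and-regraft move (e.g. moving one genus to be sister to another), then
decomposing the change in deep-coalescence cost into duplications versus
losses. A cost reduction achieved purely through fewer losses (no change in
duplications) is flagged as NOT sufficient evidence of HGT — discordance that
can be absorbed by losses alone is equally compatible with ancestral
polymorphism and lineage sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .reconcile import Reconciliation, coalescence_depth, reconcile_unrooted
from .trees import Node

CladeError = type("CladeError", (ValueError,), {})


@dataclass
class TopologyHypothesis:
    name: str
    species_tree: Node
    description: str = ""


@dataclass
class HypothesisComparison:
    table: pd.DataFrame
    reconciliations: dict[str, Reconciliation]
    verdicts: dict[str, str] = field(default_factory=dict)
    hgt_supported: dict[str, bool] = field(default_factory=dict)


def _find_clade(root: Node, taxa: set[str]) -> Node:
    taxa = set(taxa)
    all_taxa = set(root.leaf_names())
    missing = taxa - all_taxa
    if missing:
        raise CladeError(f"taxa not in tree: {sorted(missing)}")
    for n in root.postorder():
        if set(n.leaf_names()) == taxa:
            return n
    raise CladeError(f"taxa {sorted(taxa)} do not form a clade")


def regraft(species: Node, clade_taxa, new_sibling_taxa) -> Node:
    """Prune the clade of ``clade_taxa`` and reattach it as sister to the
    clade of ``new_sibling_taxa``.

    Affected branch lengths are set to 1 — the move is a topology-only
    hypothesis and parsimony reconciliation ignores lengths. Raises
    :class:`CladeError` when either taxon set does not induce a clade, when
    the sets overlap, or when the whole tree is asked to move.
    """
    clade_taxa, sib_taxa = set(clade_taxa), set(new_sibling_taxa)
    if clade_taxa & sib_taxa:
        raise CladeError(f"overlapping taxon sets: {sorted(clade_taxa & sib_taxa)}")
    tree = species.copy()
    clade = _find_clade(tree, clade_taxa)
    if clade.parent is None:
        raise CladeError("cannot regraft the root clade")
    # prune
    parent = clade.parent
    parent.children.remove(clade)
    clade.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        # suppress the degree-2 node
        only = parent.children[0]
        gp = parent.parent
        i = gp.children.index(parent)
        only.length = (only.length or 0.0) + (parent.length or 0.0)
        only.parent = gp
        gp.children[i] = only
    elif len(parent.children) == 1 and parent.parent is None:
        tree = parent.children[0]
        tree.parent = None
        tree.length = None
    sib = _find_clade(tree, sib_taxa)
    joint = Node(length=1.0)
    clade.length = 1.0
    if sib.parent is None:
        # new sibling is everything that remains: new root
        sib.length = 1.0
        joint.length = None
        joint.add_child(sib)
        joint.add_child(clade)
        return joint
    gp = sib.parent
    i = gp.children.index(sib)
    sib.length = 1.0
    joint.add_child(sib)
    joint.add_child(clade)
    joint.parent = gp
    gp.children[i] = joint
    return tree


def compare_hypotheses(
    gene: Node,
    hypotheses: list[TopologyHypothesis],
    leaf_map: Optional[dict[str, str]] = None,
    criterion: str = "dc",
    depth_pair: Optional[tuple[str, str]] = None,
) -> HypothesisComparison:
    """Reconcile the gene tree under every species-tree hypothesis.

    The baseline is the hypothesis named ``original`` (else the first).
    Reports dc / duplication / loss counts per hypothesis, deltas against the
    baseline, optionally the number of deeply-coalescing cross-species module
    pairs for ``depth_pair``, and a structured verdict per alternative.
    """
    if len(hypotheses) < 2:
        raise ValueError("need at least two hypotheses (including the original)")
    taxa0 = frozenset(hypotheses[0].species_tree.leaf_names())
    for h in hypotheses[1:]:
        if frozenset(h.species_tree.leaf_names()) != taxa0:
            raise CladeError(f"hypothesis {h.name!r} has a different taxon set")

    recs: dict[str, Reconciliation] = {}
    n_deep: dict[str, int] = {}
    for h in hypotheses:
        rec = reconcile_unrooted(gene.copy(), h.species_tree, leaf_map, criterion=criterion)
        recs[h.name] = rec
        if depth_pair is not None:
            sa, sb = depth_pair
            lm = leaf_map or {n: n.split("|")[0] for n in gene.leaf_names()}
            pairs = [
                (a, b)
                for a in gene.leaf_names()
                if lm[a] == sa
                for b in gene.leaf_names()
                if lm[b] == sb
            ]
            _, counts = coalescence_depth(
                pairs, rec.gene_tree, h.species_tree, leaf_map, sa, sb
            )
            n_deep[h.name] = counts["deeper"]

    base_name = next((h.name for h in hypotheses if h.name == "original"), hypotheses[0].name)
    base = recs[base_name]
    rows = []
    verdicts, supported = {}, {}
    for h in hypotheses:
        r = recs[h.name]
        row = {
            "hypothesis": h.name,
            "dc_cost": r.dc_cost,
            "duplications": r.duplications,
            "losses": r.losses,
            "delta_dc": r.dc_cost - base.dc_cost,
            "delta_dup": r.duplications - base.duplications,
            "delta_loss": r.losses - base.losses,
        }
        if depth_pair is not None:
            row["deep_pairs"] = n_deep[h.name]
        rows.append(row)
        if h.name == base_name:
            continue
        ddc, ddup = row["delta_dc"], row["delta_dup"]
        if ddc < 0 and ddup == 0:
            verdicts[h.name] = (
                "smaller deep-coalescence cost driven entirely by fewer losses "
                "(no change in duplications); not sufficient evidence of HGT"
            )
            supported[h.name] = False
        elif ddc < 0:
            verdicts[h.name] = (
                "smaller deep-coalescence cost with fewer duplications; "
                "consistent with, but not proof of, the alternative topology"
            )
            supported[h.name] = True
        elif ddc == 0:
            verdicts[h.name] = "no change in deep-coalescence cost"
            supported[h.name] = False
        else:
            verdicts[h.name] = "alternative topology increases the cost; original preferred"
            supported[h.name] = False

    table = pd.DataFrame(rows).sort_values("hypothesis", kind="stable").reset_index(drop=True)
    return HypothesisComparison(
        table=table, reconciliations=recs, verdicts=verdicts, hgt_supported=supported
    )
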