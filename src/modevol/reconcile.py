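"""Gene-tree / species-tree reconciliation by LCA mapping.

Implements parsimony reconciliation of a (possibly multi-copy) gene tree of
NRPS adenylation-domain modules against a rooted species tree:

* the LCA mapping M sending each gene node to the smallest species clade
  containing its descendant species;
* event labelling (duplication iff a node maps to the same species node as one
  of its children, speciation otherwise);
* loss counting per gene edge: ``dist(M(parent), M(child)) - 1 +
  [parent is a duplication]`` where ``dist`` is the number of species-tree
  edges between the two mapped nodes — no losses are charged above the mapping
  of the gene root;
* deep-coalescence cost: for every species branch, the number of gene
  lineages traversing it under the LCA embedding minus one (floored at zero),
  summed over branches.

Unrooted gene trees are handled by scoring every possible rooting and keeping
the one minimising the chosen criterion (deep-coalescence cost by default),
with deterministic tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .trees import (
    Node,
    auto_label_internal,
    canonical_newick,
    depth_map,
    enumerate_rootings,
    mrca,
)

logger = logging.getLogger(__name__)


class MappingError(ValueError):
    """A gene leaf cannot be mapped onto the species tree."""


class StructureError(ValueError):
    """A tree violates the binary/rooted structural requirements."""


def default_leaf_map(gene: Node) -> dict[str, str]:
    """Leaf label -> species: the field before the first ``|``."""
    return {name: name.split("|")[0] for name in gene.leaf_names()}


def read_leaf_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["leaf", "species"], dtype=str)
    return dict(zip(df["leaf"], df["species"]))


@dataclass
class Reconciliation:
    """Result of reconciling one rooted gene tree with a species tree."""

    gene_tree: Node
    species_tree: Node
    mapping: dict  # gene Node -> species Node
    node_events: dict  # gene internal Node -> "duplication" | "speciation"
    duplications: int
    losses: int
    dc_cost: int
    extra_lineages: dict[str, int] = field(default_factory=dict)
    criterion: Optional[str] = None
    optimal_rootings: Optional[list[str]] = None

    def summary(self) -> dict:
        return {
            "duplications": self.duplications,
            "losses": self.losses,
            "dc_cost": self.dc_cost,
        }


def _check_binary(root: Node, what: str) -> None:
    for n in root.postorder():
        if n.children and len(n.children) != 2:
            raise StructureError(
                f"{what} has a node with {len(n.children)} children; "
                "multifurcations must be resolved before reconciliation"
            )


def lca_mapping(gene: Node, species: Node, leaf_map: Optional[dict[str, str]] = None) -> dict:
    """LCA map M: gene node -> species node.

    Leaves map through ``leaf_map`` (default: label prefix before ``|``);
    internal nodes map to the species-tree LCA of their children's images.
    """
    _check_binary(gene, "gene tree")
    _check_binary(species, "species tree")
    if leaf_map is None:
        leaf_map = default_leaf_map(gene)
    sp_by_name = {n.name: n for n in species.postorder() if n.is_leaf}
    depths = depth_map(species)
    M: dict[Node, Node] = {}
    for v in gene.postorder():
        if v.is_leaf:
            sp = leaf_map.get(v.name)
            if sp is None:
                raise MappingError(f"gene leaf {v.name!r} has no species mapping")
            if sp not in sp_by_name:
                raise MappingError(
                    f"gene leaf {v.name!r} maps to {sp!r}, absent from the species tree"
                )
            M[v] = sp_by_name[sp]
        else:
            a, b = v.children
            M[v] = mrca(depths, M[a], M[b])
    return M


def count_events(
    gene: Node,
    species: Node,
    leaf_map: Optional[dict[str, str]] = None,
    mapping: Optional[dict] = None,
) -> Reconciliation:
    """Label events and count duplications, losses and deep-coalescence cost."""
    auto_label_internal(species)
    if mapping is None:
        mapping = lca_mapping(gene, species, leaf_map)
    depths = depth_map(species)

    events: dict[Node, str] = {}
    for v in gene.postorder():
        if v.is_leaf:
            continue
        if any(mapping[v] is mapping[c] for c in v.children):
            events[v] = "duplication"
        else:
            events[v] = "speciation"
    duplications = sum(1 for e in events.values() if e == "duplication")

    losses = 0
    for u in gene.postorder():
        for v in u.children:
            dist = depths[mapping[v]] - depths[mapping[u]]
            losses += dist - 1 + (1 if events[u] == "duplication" else 0)

    # lineages-per-branch census under the LCA embedding
    lineages: dict[Node, int] = {n: 0 for n in species.postorder() if n.parent is not None}
    for u in gene.postorder():
        for v in u.children:
            z = mapping[v]
            while z is not mapping[u]:
                lineages[z] += 1
                z = z.parent
    extra = {n.name: max(0, k - 1) for n, k in lineages.items()}
    dc_cost = sum(extra.values())

    return Reconciliation(
        gene_tree=gene,
        species_tree=species,
        mapping=mapping,
        node_events=events,
        duplications=duplications,
        losses=losses,
        dc_cost=dc_cost,
        extra_lineages=extra,
    )


_CRITERIA = ("dc", "dup", "duploss")


def _cost(rec: Reconciliation, criterion: str) -> int:
    if criterion == "dc":
        return rec.dc_cost
    if criterion == "dup":
        return rec.duplications
    if criterion == "duploss":
        return rec.duplications + rec.losses
    raise ValueError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")


def reconcile_unrooted(
    gene: Node,
    species: Node,
    leaf_map: Optional[dict[str, str]] = None,
    criterion: str = "dc",
) -> Reconciliation:
    """Reconcile an unrooted gene tree, minimising over all 2n-3 rootings.

    Ties on the criterion are broken by fewest duplications, then by the
    lexicographically smallest canonical Newick of the rooted tree, so reruns
    are bit-stable. A gene tree that is already rooted (two-child root) is
    reconciled as-is; the rooting enumeration is skipped with a notice.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; expected one of {_CRITERIA}")
    if len(gene.children) == 2:
        logger.info("gene tree is rooted; rooting enumeration skipped")
        rec = count_events(gene, species, leaf_map)
        rec.criterion = criterion
        rec.optimal_rootings = [canonical_newick(gene)]
        return rec
    if len(gene.children) != 3 or any(
        n.children and len(n.children) != 2 for n in gene.postorder() if n is not gene
    ):
        raise StructureError(
            "unrooted gene tree must be binary (three children at the root "
            "representation, two elsewhere)"
        )

    best = None
    best_key = None
    optimal: list[str] = []
    best_cost = None
    for rooted in enumerate_rootings(gene):
        rec = count_events(rooted, species, leaf_map)
        cost = _cost(rec, criterion)
        cnwk = canonical_newick(rooted)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            optimal = [cnwk]
        elif cost == best_cost:
            optimal.append(cnwk)
        key = (cost, rec.duplications, cnwk)
        if best_key is None or key < best_key:
            best_key = key
            best = rec
    best.criterion = criterion
    best.optimal_rootings = sorted(set(optimal))
    return best


def coalescence_depth(
    pairs,
    gene: Node,
    species: Node,
    leaf_map: Optional[dict[str, str]] = None,
    species_a: Optional[str] = None,
    species_b: Optional[str] = None,
):
    """Classify cross-species module pairs by coalescence depth.

    For each pair of gene leaves (one from each of two species), the LCA-mapped
    species node of their gene-tree MRCA is compared with the species-tree MRCA
    of the two species: equal -> ``at_mrca`` (the pair coalesces at the species
    split), strictly deeper -> ``deeper`` (deep coalescence).

    Returns ``(table, counts)`` with one row per pair.
    """
    auto_label_internal(species)
    if leaf_map is None:
        leaf_map = default_leaf_map(gene)
    mapping = lca_mapping(gene, species, leaf_map)
    gdepths = depth_map(gene)
    sdepths = depth_map(species)
    by_name = {n.name: n for n in gene.postorder() if n.is_leaf}
    sp_by_name = {n.name: n for n in species.postorder() if n.is_leaf}

    rows = []
    for a, b in pairs:
        if a not in by_name or b not in by_name:
            raise MappingError(f"pair ({a!r}, {b!r}) has leaves absent from the gene tree")
        sa, sb = leaf_map[a], leaf_map[b]
        if species_a is not None and {sa, sb} != {species_a, species_b}:
            raise MappingError(
                f"pair ({a!r}, {b!r}) is from species ({sa}, {sb}), "
                f"expected ({species_a}, {species_b})"
            )
        if sa == sb:
            raise MappingError(f"pair ({a!r}, {b!r}) is not cross-species")
        gm = mrca(gdepths, by_name[a], by_name[b])
        mapped = mapping[gm]
        smrca = mrca(sdepths, sp_by_name[sa], sp_by_name[sb])
        cls = "at_mrca" if mapped is smrca else "deeper"
        rows.append(
            {
                "leaf_a": a,
                "leaf_b": b,
                "mapped_species_node": mapped.name,
                "species_mrca": smrca.name,
                "classification": cls,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["leaf_a", "leaf_b", "mapped_species_node", "species_mrca", "classification"],
    )
    counts = {
        "at_mrca": int((table["classification"] == "at_mrca").sum()) if len(table) else 0,
        "deeper": int((table["classification"] == "deeper").sum()) if len(table) else 0,
    }
    return table, counts
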