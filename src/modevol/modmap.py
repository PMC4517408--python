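"""Module orthology/synteny maps from support-annotated trees.

Operationalises the figure-style module synteny map: two modules of two
different genes are linked as orthologs when the smallest clade containing
both has bootstrap support at or above a threshold (50 by default, missing
support counted as 0) and contains exactly one module from each of the two
genes; candidate links are resolved one-to-one per gene pair with
deterministic greedy tie-breaking. Clades of well-supported modules drawn
entirely from a single gene reveal intragenic module duplications, and query
modules are assigned to reference clades (the peptaibol clade-1/2/3 style
labels) by smallest pure containing clade.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .trees import Node, depth_map, midpoint_root, mrca

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class ModuleLink:
    module_a: str
    module_b: str
    support: int
    link_class: str  # "ortholog"
    mrca_size: int
    mrca_species_node: Optional[str] = None


def gene_of(module_id: str) -> str:
    """``SPECIES|GENE|mNN`` -> ``SPECIES|GENE``; single-field ids unchanged."""
    parts = module_id.split("|")
    return "|".join(parts[:2]) if len(parts) >= 2 else module_id


def module_index(module_id: str) -> int:
    m = re.search(r"\|m(\d+)$", module_id)
    return int(m.group(1)) if m else 0


def _node_support(n: Node) -> int:
    return n.support if n.support is not None else 0


def _gene_counts(root: Node):
    """Per node: leaf list and per-gene leaf counters (postorder)."""
    leaves_of: dict[Node, list[str]] = {}
    counts: dict[Node, dict[str, int]] = {}
    for n in root.postorder():
        if n.is_leaf:
            leaves_of[n] = [n.name]
            counts[n] = {gene_of(n.name): 1}
        else:
            lv: list[str] = []
            ct: dict[str, int] = {}
            for c in n.children:
                lv.extend(leaves_of[c])
                for g, k in counts[c].items():
                    ct[g] = ct.get(g, 0) + k
            leaves_of[n] = lv
            counts[n] = ct
    return leaves_of, counts


def map_orthologous_modules(
    tree: Node,
    arch: Optional[pd.DataFrame] = None,
    threshold: int = 50,
    species_tree: Optional[Node] = None,
    leaf_map: Optional[dict[str, str]] = None,
) -> list[ModuleLink]:
    """One-to-one orthologous module links across genes.

    For each cross-gene module pair the MRCA clade must have support >=
    ``threshold`` and contain exactly one module from at least one of the two
    genes: a clade with several copies on one side but a single module on the
    other marks a lineage-specific duplication whose copies are each
    orthologous to the single partner, while a clade with multiple copies on
    both sides spans paralogous sub-families and yields no link. Candidates
    are resolved greedily per gene pair by higher support, then smaller MRCA
    clade, then more N-terminal module positions, keeping links one-to-one.
    An unrooted tree is midpoint-rooted first so that clades are well
    defined.
    """
    tree = midpoint_root(tree)
    tree_leaves = set(tree.leaf_names())
    modules = sorted(tree_leaves)
    if arch is not None:
        declared = [m for row in arch.itertuples(index=False) for m in row.modules.split(",")]
        missing = [m for m in declared if m not in tree_leaves]
        if missing:
            logger.warning("modules absent from tree, excluded: %s", ",".join(missing))
        modules = sorted(m for m in declared if m in tree_leaves)

    depths = depth_map(tree)
    leaves_of, counts = _gene_counts(tree)
    leaf_nodes = {n.name: n for n in tree.postorder() if n.is_leaf}

    sp_depths = sp_leaves = None
    if species_tree is not None:
        sp_depths = depth_map(species_tree)
        sp_leaves = {n.name: n for n in species_tree.postorder() if n.is_leaf}
        if leaf_map is None:
            leaf_map = {m: m.split("|")[0] for m in modules}

    candidates = []
    by_gene: dict[str, list[str]] = {}
    for m in modules:
        by_gene.setdefault(gene_of(m), []).append(m)
    genes = sorted(by_gene)
    for gi in range(len(genes)):
        for gj in range(gi + 1, len(genes)):
            g1, g2 = genes[gi], genes[gj]
            for a in by_gene[g1]:
                for b in by_gene[g2]:
                    anc = mrca(depths, leaf_nodes[a], leaf_nodes[b])
                    if anc is tree:
                        continue  # root of an unrooted tree is not a clade
                    if _node_support(anc) < threshold:
                        continue
                    ct = counts[anc]
                    if min(ct.get(g1, 0), ct.get(g2, 0)) == 1:
                        candidates.append((a, b, anc))

    # greedy one-to-one resolution, deterministic ordering
    candidates.sort(
        key=lambda t: (
            -_node_support(t[2]),
            len(leaves_of[t[2]]),
            module_index(t[0]),
            module_index(t[1]),
            t[0],
            t[1],
        )
    )
    used: set[tuple[str, str]] = set()
    links = []
    for a, b, anc in candidates:
        ga, gb = gene_of(a), gene_of(b)
        if (a, gb) in used or (b, ga) in used:
            continue
        used.add((a, gb))
        used.add((b, ga))
        mrca_sp = None
        if species_tree is not None:
            sps = {leaf_map[x] for x in leaves_of[anc] if x in leaf_map}
            nodes = [sp_leaves[s] for s in sorted(sps) if s in sp_leaves]
            if nodes:
                z = nodes[0]
                for other in nodes[1:]:
                    z = mrca(sp_depths, z, other)
                mrca_sp = z.name
        links.append(
            ModuleLink(
                module_a=a,
                module_b=b,
                support=_node_support(anc),
                link_class="ortholog",
                mrca_size=len(leaves_of[anc]),
                mrca_species_node=mrca_sp,
            )
        )
    links.sort(key=lambda l: (l.module_a, l.module_b))
    return links


def links_table(links: list[ModuleLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module_a": l.module_a,
                "module_b": l.module_b,
                "support": l.support,
                "class": l.link_class,
                "mrca_size": l.mrca_size,
                "mrca_species_node": l.mrca_species_node,
            }
            for l in links
        ],
        columns=["module_a", "module_b", "support", "class", "mrca_size", "mrca_species_node"],
    )


def detect_intragenic_duplications(tree: Node, threshold: int = 50) -> list[dict]:
    """Maximal supported clades whose modules all come from one gene.

    Each reported group (gene, member modules, support) is evidence of
    intragenic module duplication — lineage-specific copies that cluster
    together inside a single gene, like the shared ancestry of modules 2, 3
    and 6 within a single NRPS. Unrooted trees are midpoint-rooted first.
    """
    tree = midpoint_root(tree)
    leaves_of, counts = _gene_counts(tree)
    groups = []

    def visit(n: Node):
        if n.is_leaf:
            return
        if (
            n is not tree
            and _node_support(n) >= threshold
            and len(counts[n]) == 1
            and len(leaves_of[n]) >= 2
        ):
            gene = next(iter(counts[n]))
            members = sorted(leaves_of[n], key=module_index)
            groups.append(
                {
                    "gene": gene,
                    "n_modules": len(members),
                    "modules": ",".join(members),
                    "module_indices": ",".join(str(module_index(m)) for m in members),
                    "support": _node_support(n),
                }
            )
            return  # maximal: do not descend
        for c in n.children:
            visit(c)

    visit(tree)
    groups.sort(key=lambda g: (g["gene"], g["modules"]))
    return groups


@dataclass
class CladeAssignment:
    assignments: dict[str, str]  # module id -> clade label or "unassigned"
    tally: pd.DataFrame  # per-genus counts per clade


def assign_clades(
    tree: Node,
    references: dict[str, str],
    genus_regex: str = r"^([^_|]+)",
) -> CladeAssignment:
    """Assign query modules to the clade of their smallest pure reference clade.

    ``references`` maps reference leaf ids to clade labels. A query gets the
    label of the nearest strict ancestor (below the root) whose reference
    members all share one label; mixed or absent references leave it
    ``unassigned``. The tally counts assigned modules per genus (extracted
    from the species field by ``genus_regex``) per clade. Unrooted trees are
    midpoint-rooted first.
    """
    tree = midpoint_root(tree)
    present = {r: lab for r, lab in references.items() if r in set(tree.leaf_names())}
    labels = set(references.values())
    missing = labels - set(present.values())
    if not present or missing:
        raise ConfigurationError(
            f"missing reference modules in tree for clade label(s): {sorted(missing) or 'all'}"
        )

    ref_labels: dict[Node, set] = {}
    for n in tree.postorder():
        if n.is_leaf:
            ref_labels[n] = {present[n.name]} if n.name in present else set()
        else:
            s = set()
            for c in n.children:
                s |= ref_labels[c]
            ref_labels[n] = s

    assignments = {}
    for leaf in tree.leaves():
        if leaf.name in present:
            continue
        label = "unassigned"
        n = leaf.parent
        while n is not None and n is not tree:
            if ref_labels[n]:
                if len(ref_labels[n]) == 1:
                    label = next(iter(ref_labels[n]))
                break
            n = n.parent
        assignments[leaf.name] = label

    rows = []
    pat = re.compile(genus_regex)
    for module, label in sorted(assignments.items()):
        species = module.split("|")[0]
        m = pat.search(species)
        genus = m.group(1) if m else species
        rows.append({"module": module, "clade": label, "genus": genus})
    df = pd.DataFrame(rows, columns=["module", "clade", "genus"])
    if len(df):
        tally = (
            df[df["clade"] != "unassigned"]
            .groupby(["clade", "genus"])
            .size()
            .unstack(fill_value=0)
            .reset_index()
        )
    else:
        tally = pd.DataFrame(columns=["clade"])
    return CladeAssignment(assignments=assignments, tally=tally)


def render_synteny(links: list[ModuleLink], arch: pd.DataFrame) -> str:
    """Plain-text synteny map: genes as rows, modules as columns, shared link
    ids marking orthologous modules."""
    link_id = {}
    for k, l in enumerate(sorted(links, key=lambda l: (l.module_a, l.module_b)), start=1):
        link_id.setdefault(l.module_a, []).append(k)
        link_id.setdefault(l.module_b, []).append(k)
    lines = []
    for row in arch.sort_values("gene").itertuples(index=False):
        cells = []
        for m in row.modules.split(","):
            ids = link_id.get(m)
            cells.append("m%02d[%s]" % (module_index(m), ",".join(map(str, ids)) if ids else "-"))
        lines.append(f"{row.gene}\t" + " ".join(cells))
    return "\n".join(lines) + ("\n" if lines else "")
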