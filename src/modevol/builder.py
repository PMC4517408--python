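"""Distance trees with bootstrap supports for module alignments.

Self-contained path to a support-annotated module tree: Poisson-corrected
pairwise distances, neighbor joining (delegated to scikit-bio's classic NJ),
and nonparametric bootstrap over alignment columns with supports written as
integer percentages on internal edges. Externally inferred ML trees can be
imported through :func:`modevol.trees.read_newick` instead — downstream
reconciliation is agnostic to how the tree was built.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .trees import Node, bipartitions, parse_newick


class AlignmentError(ValueError):
    pass


class UndefinedDistanceError(ValueError):
    pass


class ModuleAlignment:
    """Module id -> aligned amino-acid string, all of equal length."""

    def __init__(self, records):
        if isinstance(records, dict):
            records = list(records.items())
        self.ids = [r[0] for r in records]
        self.seqs = [r[1].upper() for r in records]
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate module ids in alignment")
        if not self.seqs:
            raise AlignmentError("empty alignment")
        L = len(self.seqs[0])
        if any(len(s) != L for s in self.seqs):
            raise AlignmentError("alignment rows have unequal lengths")
        self.length = L
        # integer matrix; gaps encoded as -1 for pairwise deletion
        mat = np.frombuffer("".join(self.seqs).encode(), dtype=np.uint8).reshape(
            len(self.seqs), L
        )
        self.matrix = mat.astype(np.int16)
        self.matrix[np.isin(mat, np.frombuffer(b"-.", dtype=np.uint8))] = -1

    def __len__(self):
        return len(self.ids)

    @classmethod
    def from_fasta(cls, path) -> "ModuleAlignment":
        from Bio import SeqIO

        return cls([(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")])


def compute_distances(
    aln: ModuleAlignment, columns: Optional[np.ndarray] = None, max_p: Optional[float] = None
) -> np.ndarray:
    """Poisson-corrected distances d = -ln(1 - p) with pairwise gap deletion.

    ``p`` is the proportion of differing sites over columns where neither
    sequence has a gap. ``columns`` restricts/resamples the columns (used by
    the bootstrap). With ``max_p`` set, saturated proportions are clipped
    instead of raising — bootstrap replicates use this so a resample cannot
    abort the run.
    """
    if len(aln) < 2:
        raise AlignmentError("need at least 2 sequences for distances")
    M = aln.matrix if columns is None else aln.matrix[:, columns]
    n = len(aln)
    D = np.zeros((n, n))
    valid = M >= 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            ns = int(shared.sum())
            if ns == 0:
                raise UndefinedDistanceError(
                    f"no shared ungapped columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            p = float((M[i, shared] != M[j, shared]).sum()) / ns
            if p >= 1.0 or (max_p is not None and p > max_p):
                if max_p is None:
                    raise UndefinedDistanceError(
                        f"distance undefined (p={p:.3f}) between "
                        f"{aln.ids[i]!r} and {aln.ids[j]!r}"
                    )
                p = max_p
            D[i, j] = D[j, i] = -np.log(1.0 - p)
    return D


def neighbor_joining(D: np.ndarray, ids: list[str]) -> Node:
    """Neighbor joining on a symmetric distance matrix; unrooted tree.

    Negative branch-length estimates are clamped to zero. Deterministic for a
    given matrix.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa for neighbor joining")
    tree = nj(DistanceMatrix(D, ids))
    return parse_newick(str(tree))


def bootstrap_supports(
    aln: ModuleAlignment, replicates: int = 100, seed: int = 0, max_p: float = 0.95
) -> Node:
    """NJ point-estimate tree annotated with bootstrap support percentages.

    Columns are resampled with replacement ``replicates`` times; each internal
    edge of the point-estimate tree carries the integer percentage of
    replicates whose NJ tree contains the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    point = neighbor_joining(compute_distances(aln), aln.ids)
    target = {bp: 0 for bp in bipartitions(point)}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(aln.length, size=aln.length)
        D = compute_distances(aln, columns=cols, max_p=max_p)
        rep = neighbor_joining(D, aln.ids)
        for bp in bipartitions(rep):
            if bp in target:
                target[bp] += 1

    all_leaves = frozenset(point.leaf_names())
    for n in point.postorder():
        if n.is_leaf or n is point:
            continue
        side = frozenset(n.leaf_names())
        bp = frozenset((side, all_leaves - side))
        if bp in target:
            n.support = int(round(100.0 * target[bp] / replicates))
    return point
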