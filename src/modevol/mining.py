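"""Adenylation-domain module mining with an ungapped log-odds profile.

A position-specific scoring profile is built from a seed alignment of known
A-domains (match columns = columns with < 50 % gaps; base-2 log-odds against a
uniform amino-acid background with pseudocounts). Protein sequences are then
scanned with a sliding window of the profile length; windows above a score
threshold are resolved greedily into non-overlapping domain hits, short hits
are discarded (the paper-style "< 100 residues" filter) and the survivors are
numbered N->C as m01, m02, ... Because hits are fixed-length windows, the
extracted modules are implicitly aligned column-for-column.

Externally produced domain coordinates can be supplied as a TSV instead
(protein_id, start, end; 1-based inclusive) to bypass the scanner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .simulate import AMINO_ACIDS

logger = logging.getLogger(__name__)

GAP_CHARS = set("-.")


class AlignmentFormatError(ValueError):
    pass


class EmptyProfileError(ValueError):
    pass


class HitConsistencyError(ValueError):
    pass


@dataclass
class SeedAlignment:
    """An aligned set of seed domain sequences (rows of equal length)."""

    sequences: list[str]

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentFormatError("seed alignment is empty")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise AlignmentFormatError("seed alignment is ragged (unequal row lengths)")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @classmethod
    def from_fasta(cls, path) -> "SeedAlignment":
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(seqs)


@dataclass
class ProfileModel:
    """Ungapped log-odds profile over match columns.

    ``scores[i, a]`` is the base-2 log-odds of residue ``a`` (indexed along
    ``AMINO_ACIDS``) at match column ``i``; ``score_threshold`` is in bits.
    """

    scores: np.ndarray  # (L, 20)
    score_threshold: float
    match_columns: list[int]

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass
class DomainHit:
    protein_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    score: float
    module_index: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def build_profile(
    seed: SeedAlignment,
    pseudocount: float = 1.0,
    background: float = 0.05,
    threshold_frac: float = 0.5,
) -> ProfileModel:
    """Build the log-odds profile from a seed alignment.

    Match columns are those with < 50 % gaps. The column score of residue
    ``a`` is ``log2(((count_a + pseudocount) / (n_col + 20 * pseudocount)) /
    background)`` with ``n_col`` the number of residues observed in the
    column. The default score threshold is ``threshold_frac`` times the
    maximum achievable profile score.
    """
    n = len(seed.sequences)
    cols = []
    for j in range(seed.n_columns):
        col = [s[j] for s in seed.sequences]
        gaps = sum(1 for c in col if c in GAP_CHARS)
        if gaps / n < 0.5:
            cols.append(j)
    if not cols:
        raise EmptyProfileError("seed alignment has no match columns (all-gap?)")
    scores = np.zeros((len(cols), 20))
    for i, j in enumerate(cols):
        counts = np.zeros(20)
        n_col = 0
        for s in seed.sequences:
            c = s[j]
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
                n_col += 1
        probs = (counts + pseudocount) / (n_col + 20.0 * pseudocount)
        scores[i] = np.log2(probs / background)
    profile = ProfileModel(scores=scores, score_threshold=0.0, match_columns=cols)
    profile.score_threshold = threshold_frac * profile.max_score
    return profile


def _encode(seq: str):
    """Sequence -> residue indices; non-amino-acid characters -> -1."""
    idx = np.full(len(seq), -1, dtype=np.int64)
    unknown = False
    for i, c in enumerate(seq.upper()):
        k = _AA_INDEX.get(c)
        if k is None:
            unknown = True
        else:
            idx[i] = k
    return idx, unknown


def scan_protein(protein_id: str, seq: str, profile: ProfileModel, min_len: int = 100):
    """Scan one protein; returns accepted, numbered, non-overlapping hits."""
    L = profile.length
    if len(seq) < L:
        return []
    idx, unknown = _encode(seq)
    if unknown:
        warnings.warn(
            f"protein {protein_id}: non-amino-acid characters scored as background",
            stacklevel=2,
        )
    # append a zero score row for unknown residues (log-odds of background = 0)
    scores = np.vstack([profile.scores.T, np.zeros(L)]).T  # (L, 21)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    wscores = scores[np.arange(L), windows].sum(axis=1)
    order = sorted(
        (i for i in range(len(wscores)) if wscores[i] >= profile.score_threshold),
        key=lambda i: (-wscores[i], i),
    )
    taken = np.zeros(len(seq), dtype=bool)
    hits = []
    for i in order:
        if taken[i : i + L].any():
            continue
        taken[i : i + L] = True
        hits.append(DomainHit(protein_id, i + 1, i + L, float(wscores[i])))
    hits = [h for h in hits if h.length >= min_len]
    hits.sort(key=lambda h: h.start)
    for k, h in enumerate(hits, start=1):
        h.module_index = k
    return hits


def scan_proteins(proteins, profile: ProfileModel, min_len: int = 100) -> list[DomainHit]:
    """Scan a protein FASTA (path) or iterable of (id, sequence) pairs."""
    hits = []
    for pid, seq in _iter_proteins(proteins):
        hits.extend(scan_protein(pid, seq, profile, min_len=min_len))
    return hits


def _iter_proteins(proteins):
    if isinstance(proteins, (str, Path)):
        for rec in SeqIO.parse(str(proteins), "fasta"):
            yield rec.id, str(rec.seq)
    else:
        yield from proteins


def _split_protein_id(pid: str) -> tuple[str, str]:
    """Derive (species, gene) from a protein id.

    ``SPECIES|GENE...`` ids split at the pipe; otherwise the species is the
    prefix before the first underscore (the TOPH_xxxx convention).
    """
    if "|" in pid:
        parts = pid.split("|")
        return parts[0], parts[1]
    if "_" in pid:
        return pid.split("_")[0], pid
    return pid, pid


def extract_modules(proteins, hits: list[DomainHit]):
    """Slice accepted hits out of the proteins.

    Returns ``(records, architectures)``: module FASTA records with headers
    ``SPECIES|GENE|m<NN>`` (fixed-length, hence implicitly aligned) and an
    architecture table with one row per gene carrying the ordered module ids.
    """
    seqs = {pid: seq for pid, seq in _iter_proteins(proteins)}
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.protein_id not in seqs:
            raise HitConsistencyError(f"hit references unknown protein {h.protein_id!r}")
        seq = seqs[h.protein_id]
        if not (1 <= h.start <= h.end <= len(seq)):
            raise HitConsistencyError(
                f"hit {h.protein_id}:{h.start}-{h.end} outside protein (len {len(seq)})"
            )
        by_protein.setdefault(h.protein_id, []).append(h)

    records = []
    arch_rows = []
    for pid in sorted(by_protein):
        phits = sorted(by_protein[pid], key=lambda h: h.start)
        species, gene = _split_protein_id(pid)
        ids = []
        for k, h in enumerate(phits, start=1):
            mid = f"{species}|{gene}|m{k:02d}"
            ids.append(mid)
            records.append((mid, seqs[pid][h.start - 1 : h.end]))
        arch_rows.append(
            {
                "gene": f"{species}|{gene}",
                "species": species,
                "n_modules": len(ids),
                "modules": ",".join(ids),
            }
        )
    arch = pd.DataFrame(arch_rows, columns=["gene", "species", "n_modules", "modules"])
    return records, arch


def read_hits_tsv(path) -> list[DomainHit]:
    """Load precomputed domain coordinates (protein_id, start, end[, score])."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            DomainHit(
                str(row.protein_id),
                int(row.start),
                int(row.end),
                float(getattr(row, "score", 0.0)),
            )
        )
    return hits


def write_hits_tsv(hits: list[DomainHit], path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "start": h.start,
                "end": h.end,
                "score": round(h.score, 4),
                "module_index": h.module_index,
            }
            for h in hits
        ],
        columns=["protein_id", "start", "end", "score", "module_index"],
    ).to_csv(path, sep="\t", index=False)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
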