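"""Sequence- and structure-level evaluation of designed sequences.

Recovery is the fraction of positions where a designed sequence matches the
native; diversity of a set is one minus the mean pairwise fraction of
identical-or-similar positions ("similar" meaning a positive BLOSUM62
substitution score; a strict-identity mode is available).  Both are
reported as fractions in [0, 1].  Structural agreement uses RMSD, raw or
after optimal (Kabsch) superposition.  Composition statistics compare
20-bin amino-acid frequency vectors (Pearson r and the total-variation
complement 1 - 0.5*sum|p - q| as composition similarity), and
:func:`substitution_logodds` rebuilds a BLOSUM-style half-bit log-odds
matrix from aligned native/designed pairs.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

from .structure_io import AA_ALPHABET

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def recovery(designed: str, native: str) -> float:
    """Fraction of positions with identical residues."""
    if len(designed) != len(native):
        raise ValueError("sequences must have equal length")
    if not designed:
        raise ValueError("empty sequences")
    same = sum(a == b for a, b in zip(designed, native))
    return same / len(native)


def _pair_similarity(a: str, b: str, similarity_rule: str) -> float:
    """Fraction of positions identical or similar between two sequences."""
    if similarity_rule == "blosum62":
        close = sum(x == y or blosum62_score(x, y) > 0 for x, y in zip(a, b))
    elif similarity_rule == "identity":
        close = sum(x == y for x, y in zip(a, b))
    else:
        raise ValueError(f"unknown similarity rule {similarity_rule!r}")
    return close / len(a)


def diversity(seqset, similarity_rule: str = "blosum62") -> float:
    """Mean over unordered sequence pairs of 1 - (same or similar)/length."""
    seqs = seqset.sequences if hasattr(seqset, "sequences") else list(seqset)
    if len(seqs) < 2:
        raise ValueError("diversity needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must share one length")
    vals = [1.0 - _pair_similarity(seqs[i], seqs[j], similarity_rule)
            for i in range(len(seqs)) for j in range(i + 1, len(seqs))]
    return float(np.mean(vals))


def kabsch_rotation(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation R and translation t minimizing ||R P + t - Q||.

    P, Q are (N, 3) paired coordinates; returns (R, t) with det(R) = +1.
    """
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    Hm = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(Hm)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = Q.mean(axis=0) - R @ P.mean(axis=0)
    return R, t


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
         superpose: bool = False) -> float:
    """Root-mean-square deviation (Å) over paired atoms."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if len(A) < 1:
        raise ValueError("need at least one atom")
    if superpose:
        R, t = kabsch_rotation(A, B)
        A = A @ R.T + t
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def composition(seqs) -> np.ndarray:
    """20-bin residue frequency vector over one or many sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = np.zeros(20)
    for s in seqs:
        for a in s:
            if a in AA_ALPHABET:
                counts[AA_ALPHABET.index(a)] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues found")
    return counts / total


def composition_stats(designed, native: str):
    """(Pearson r, composition similarity) between designed-set and native
    amino-acid compositions."""
    seqs = designed.sequences if hasattr(designed, "sequences") else designed
    p = composition(seqs)
    q = composition(native)
    r = float(np.corrcoef(p, q)[0, 1])
    similarity = float(1.0 - 0.5 * np.abs(p - q).sum())
    return r, similarity


def substitution_logodds(pairs) -> np.ndarray:
    """Half-bit log-odds substitution matrix from aligned sequence pairs.

    Counts (native, designed) residue pairs symmetrically, then applies
    the BLOSUM construction: s(a,b) = round(2 * log2(p_ab / e_ab)) with
    e_ab = f_a^2 on the diagonal and 2 f_a f_b off it.  Empty cells get a
    pseudocount of 1 so the log is defined.
    """
    if not pairs:
        raise ValueError("no aligned pairs given")
    counts = np.zeros((20, 20))
    for native, designed in pairs:
        if len(native) != len(designed):
            raise ValueError("aligned pairs must have equal length")
        for a, b in zip(native, designed):
            if a in AA_ALPHABET and b in AA_ALPHABET:
                i, j = AA_ALPHABET.index(a), AA_ALPHABET.index(b)
                counts[i, j] += 1
                counts[j, i] += 1
    counts[counts == 0] = 1.0
    total = counts.sum()
    p = counts / total
    f = p.sum(axis=1)
    expected = 2.0 * np.outer(f, f)
    np.fill_diagonal(expected, f ** 2)
    return np.round(2.0 * np.log2(p / expected))
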