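"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most naive correct
algorithm available (explicit three-matrix DP, exhaustive scans,
per-base splicing masks) so that they share no code path with the
package implementation they check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = float("-inf")


def sw_affine_brute(query: str, reference: str, gap_open: float = 11.0,
                    gap_extend: float = 1.0, matrix_name: str = "BLOSUM62") -> float:
    """Textbook three-matrix affine-gap Smith-Waterman, score only.

    A gap of length g costs gap_open + g * gap_extend.
    """
    mat = substitution_matrices.load(matrix_name)
    m, n = len(query), len(reference)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + mat[query[i - 1], reference[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def orf_scan_brute(transcript: str, min_codons: int):
    """Exhaustive ORF scan: every ATG, first in-frame stop, longest wins,
    ties to the smallest start.  Returns (start, end) or None."""
    stops = {"TAA", "TAG", "TGA"}
    candidates = []
    for pos in range(len(transcript) - 2):
        if transcript[pos:pos + 3] != "ATG":
            continue
        for j in range(pos, len(transcript) - 2, 3):
            if transcript[j:j + 3] in stops:
                if (j + 3 - pos) // 3 - 1 >= min_codons:
                    candidates.append((-(j + 3 - pos), pos))
                break
    if not candidates:
        return None
    neg_len, start = min(candidates)
    return start, start - neg_len


def splice_by_mask(region: str, tss: int, tes: int, removed_intervals) -> str:
    """Assemble a transcript by marking removed bases in a keep-mask."""
    keep = [tss <= i < tes for i in range(len(region))]
    for s, e in removed_intervals:
        for i in range(s, e):
            keep[i] = False
    return "".join(b for b, k in zip(region, keep) if k)


def enumerate_isoforms_brute(region: str, tss: int, tes: int, introns,
                             state_sets):
    """Recursive enumeration of all state-vector transcripts.

    ``introns`` are (start, end) pairs; a state is one of "canonical",
    "retained", ("alt5", off) or ("alt3", off).  Returns {vector: sequence}.
    """
    out = {}

    def removed(iv, state):
        s, e = iv
        if state == "canonical":
            return (s, e)
        if state == "retained":
            return None
        kind, off = state
        return (s + off, e) if kind == "alt5" else (s, e + off)

    def recurse(i, chosen):
        if i == len(introns):
            cuts = [removed(iv, st) for iv, st in zip(introns, chosen)]
            out[tuple(chosen)] = splice_by_mask(
                region, tss, tes, [c for c in cuts if c is not None])
            return
        for st in state_sets[i]:
            recurse(i + 1, chosen + [st])

    recurse(0, [])
    return out


def pearson_brute(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
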