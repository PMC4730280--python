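"""SOD-family homology screening.

A proteome is screened against labelled reference SODs with exact local
(Smith-Waterman) alignment under BLOSUM62 and affine gaps, hits are kept at
a Karlin-Altschul e-value threshold, and every retained hit is confirmed by
a conserved-residue domain profile: the Cu/Zn metal ligands, the disulfide
cysteines and the glycosylation asparagine for Cu-ZnSODs, and the metal
ligands for Mn/FeSODs.

A gap of length ``g`` costs ``gap_open + g * gap_extend`` (BLAST-style
existence/extension).  The row recurrence exploits ``gap_open >= gap_extend``
so the horizontal gap state collapses to a running maximum, which lets each
DP row be computed with a handful of vectorised numpy operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .errors import ConfigurationError, InputError
from .models import SequenceRecord


@dataclass(frozen=True)
class ScreenConfig:
    """Alignment scoring and hit-filtering parameters.

    The Karlin-Altschul constants default to the standard gapped
    BLOSUM62/11,1 values; the e-value threshold defaults to 1e-2.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    evalue_threshold: float = 1e-2
    ka_lambda: float = 0.267
    ka_k: float = 0.041

    def __post_init__(self):
        if self.evalue_threshold <= 0:
            raise ConfigurationError("e-value threshold must be > 0")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ConfigurationError("gap penalties must be > 0")
        if self.gap_open < self.gap_extend:
            raise ConfigurationError("gap_open must be >= gap_extend")

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


@dataclass(frozen=True)
class DomainProfile:
    """Conserved residues required of one SOD family.

    ``required`` holds 1-based positions on ``reference`` with the expected
    residue letter.  ``reference`` is the family exemplar the query is
    aligned to so that profile positions can be carried across.
    """

    family: str  # CuZn | Mn | Fe | Ni
    required: tuple[tuple[int, str], ...]
    reference: SequenceRecord

    def __post_init__(self):
        positions = [p for p, _ in self.required]
        if positions != sorted(set(positions)):
            raise ConfigurationError("profile positions must strictly increase")
        for pos, res in self.required:
            if not (1 <= pos <= len(self.reference)):
                raise ConfigurationError(
                    f"profile position {pos} outside reference "
                    f"(length {len(self.reference)})")
            if len(res) != 1:
                raise ConfigurationError(f"residue {res!r} is not one letter")


# Figure-style Cu-Zn profile: Cu ligands H97/H99/H114/H171, Zn ligands
# H114/H122/H131/D134, disulfide C108/C147, glycosylation N137.
CUZN_REQUIRED = ((97, "H"), (99, "H"), (108, "C"), (114, "H"), (122, "H"),
                 (131, "H"), (134, "D"), (137, "N"), (147, "C"), (171, "H"))
# Mn-fold metal ligands at SOD2-style numbering (H26, H74, D159, H163).
MN_REQUIRED = ((26, "H"), (74, "H"), (159, "D"), (163, "H"))


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment: score plus matched-position map."""

    score: float
    pairs: tuple[tuple[int, int], ...]  # (query_pos, ref_pos), 0-based
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]

    def ref_to_query(self) -> dict[int, int]:
        return {r: q for q, r in self.pairs}


@dataclass(frozen=True)
class ScreenHit:
    query_id: str
    reference_id: str
    score: float
    evalue: float
    family: str
    verdict: Optional[str] = None  # complete | partial | absent
    matched: tuple[int, ...] = ()
    missing: tuple[int, ...] = ()


def _encode(seq: str, alphabet: str, what: str) -> np.ndarray:
    lut = np.full(128, -1, dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    arr = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(arr < 0)[0]})
        raise InputError(f"unknown residue letters {bad} in {what}")
    return arr


def local_align(query: str, reference: str,
                config: ScreenConfig = ScreenConfig()) -> AlignmentResult:
    """Exact Smith-Waterman local alignment with affine gaps.

    Returns the maximal score and the residue correspondences of one
    optimal alignment (ties resolved deterministically: the end cell with
    the smallest coordinates, then diagonal > vertical > horizontal moves
    with shortest gap runs).
    """
    if not query or not reference:
        raise InputError("local_align requires non-empty sequences")
    matrix = config.matrix()
    alphabet = matrix.alphabet
    q = _encode(query, alphabet, "query")
    r = _encode(reference, alphabet, "reference")
    sub = np.asarray(matrix)[np.ix_(q, r)].astype(np.float64)  # m x n
    m, n = len(q), len(r)
    open_ext = config.gap_open + config.gap_extend
    ext = config.gap_extend

    H = np.zeros((m + 1, n + 1))
    F = np.full(n + 1, -np.inf)  # vertical gap state (gap in reference)
    jk = np.arange(n)  # 0..n-1 == column j-1 for columns 1..n
    for i in range(1, m + 1):
        F = np.maximum(F - ext, H[i - 1] - open_ext)
        C = np.maximum(0.0, np.maximum(H[i - 1, :-1] + sub[i - 1], F[1:]))
        # horizontal gap state via running max: E[j] = max_{k<j} C[k]-open-(j-k)*ext
        T = np.maximum.accumulate(C - config.gap_open + ext * jk)
        H[i, 1:] = np.maximum(C, T - ext * jk)
    score = float(H.max())
    if score <= 0:
        return AlignmentResult(0.0, (), (0, 0), (0, 0))

    i, j = map(int, np.unravel_index(int(np.argmax(H)), H.shape))
    end_q, end_r = i, j
    pairs = []
    while H[i, j] > 0:
        h = H[i, j]
        if i > 0 and j > 0 and np.isclose(h, H[i - 1, j - 1] + sub[i - 1, j - 1]):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            continue
        moved = False
        # vertical gap run (consumes query rows)
        for l in range(1, i + 1):
            if np.isclose(h, H[i - l, j] - config.gap_open - l * ext):
                i -= l
                moved = True
                break
        if moved:
            continue
        for l in range(1, j + 1):
            if np.isclose(h, H[i, j - l] - config.gap_open - l * ext):
                j -= l
                moved = True
                break
        if not moved:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed to find a predecessor")
    pairs.reverse()
    return AlignmentResult(score, tuple(pairs), (i, end_q), (j, end_r))


def evalue(score: float, query_len: int, ref_len: int,
           config: ScreenConfig = ScreenConfig()) -> float:
    """Karlin-Altschul expected hit count E = K*m*n*exp(-lambda*S)."""
    if score < 0:
        raise InputError("score must be >= 0")
    return config.ka_k * query_len * ref_len * exp(-config.ka_lambda * score)


def domain_check(protein: str, profile: DomainProfile,
                 alignment_to_profile: AlignmentResult) -> tuple[str, dict]:
    """Check required profile residues through an alignment to the profile
    reference.

    Verdict is ``complete`` iff every required residue is present,
    ``partial`` if at least half are, else ``absent``.  The report lists
    each required position as matched or missing.
    """
    ref_to_query = alignment_to_profile.ref_to_query()
    matched, missing = [], []
    for pos, res in profile.required:
        qpos = ref_to_query.get(pos - 1)
        if qpos is not None and protein[qpos] == res:
            matched.append(pos)
        else:
            missing.append(pos)
    if not missing:
        verdict = "complete"
    elif len(matched) * 2 >= len(profile.required):
        verdict = "partial"
    else:
        verdict = "absent"
    report = {"matched": tuple(matched), "missing": tuple(missing)}
    return verdict, report


def screen_proteome(proteome: Iterable[SequenceRecord],
                    references: Sequence[tuple[SequenceRecord, str]],
                    config: ScreenConfig = ScreenConfig(),
                    profiles: Optional[dict[str, DomainProfile]] = None,
                    ) -> list[ScreenHit]:
    """Screen a proteome against family-labelled reference SODs.

    Each query keeps its best-scoring reference (ties broken by score then
    reference id); hits with e-value <= threshold are retained and, when a
    profile for the called family is supplied, domain-checked against the
    profile reference.  Results are sorted by query id, so the outcome does
    not depend on proteome order.
    """
    references = list(references)
    if not references:
        raise ConfigurationError("screen_proteome needs at least one reference")
    hits = []
    for rec in proteome:
        best = None
        for ref, family in sorted(references, key=lambda rf: rf[0].id):
            aln = local_align(rec.residues, ref.residues, config)
            key = (-aln.score, ref.id)
            if best is None or key < best[0]:
                best = (key, aln, ref, family)
        _, aln, ref, family = best
        e = evalue(aln.score, len(rec.residues), len(ref.residues), config)
        if e > config.evalue_threshold:
            continue
        verdict, report = None, {"matched": (), "missing": ()}
        profile = (profiles or {}).get(family)
        if profile is not None:
            prof_aln = (aln if profile.reference.residues == ref.residues
                        else local_align(rec.residues, profile.reference.residues,
                                         config))
            verdict, report = domain_check(rec.residues, profile, prof_aln)
        hits.append(ScreenHit(
            query_id=rec.id, reference_id=ref.id, score=aln.score, evalue=e,
            family=family, verdict=verdict,
            matched=report["matched"], missing=report["missing"]))
    hits.sort(key=lambda h: h.query_id)
    return hits
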