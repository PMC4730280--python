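"""Junction-aware paired-end read mapping against a gene region.

The mapper re-creates the verification procedure used for the SOD gene
models: reads are anchored by exact seed words, extended allowing a small
number of substitutions, and may split into up to three blocks across
candidate reference skips whose ends obey the GT-AG rule.  A pair is kept
only when its mates land within a configurable reference span (default
1-2000 bp).  Transcription start/termination sites are the extreme
covered coordinates, and a gene model is "verified" when every base of
the region is covered by at least one aligned block.

Genome mode is contiguous-only with zero mismatches; transcriptome mode
allows spliced alignments with at most two substitutions per mate.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import ConfigurationError, EvidenceError
from .models import ReadPair, SequenceRecord, reverse_complement


@dataclass(frozen=True)
class MapperConfig:
    """Pairing and tolerance parameters.

    ``mode`` is ``transcriptome`` (spliced, <= ``max_mismatches``
    substitutions per mate) or ``genome`` (contiguous, 0 mismatches).
    """

    mode: str = "transcriptome"
    span_min: int = 1
    span_max: int = 2000
    max_mismatches: int = 2
    seed_length: int = 20
    seed_step: int = 5
    min_anchor: int = 8
    max_skip: int = 2000

    def __post_init__(self):
        if self.mode not in ("transcriptome", "genome"):
            raise ConfigurationError(f"unknown mapper mode {self.mode!r}")
        if self.span_min < 1 or self.span_max < self.span_min:
            raise ConfigurationError("need 1 <= span_min <= span_max")
        if self.max_mismatches < 0:
            raise ConfigurationError("mismatch limit must be >= 0")

    @property
    def mismatch_limit(self) -> int:
        return 0 if self.mode == "genome" else self.max_mismatches


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned mate: ordered (ref_start, ref_end, read_start) blocks.

    Gaps between consecutive blocks are candidate reference skips
    (introns); accepted skips always carry GT at the donor and AG before
    the acceptor.
    """

    read_id: str
    mate: int
    reference_id: str
    strand: str
    blocks: tuple[tuple[int, int, int], ...]
    mismatches: int

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def skips(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1, _), (s2, e2, _) in zip(self.blocks, self.blocks[1:]):
            out.append((e1, s2))
        return out


class ReferenceIndex:
    """Exact k-mer index over one reference sequence."""

    def __init__(self, reference: SequenceRecord, k: int = 20):
        self.reference = reference
        self.k = k
        self.seq = reference.residues
        self.arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        self.kmers: dict[str, list[int]] = defaultdict(list)
        for i in range(len(self.seq) - k + 1):
            self.kmers[self.seq[i:i + k]].append(i)


def _mate_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _candidate_placements(seq: str, index: ReferenceIndex, step: int) -> dict[int, tuple[int, int]]:
    """placement -> (min seed offset, max seed offset) supporting it."""
    k, m = index.k, len(seq)
    offsets = list(range(0, m - k + 1, step))
    if offsets[-1] != m - k:
        offsets.append(m - k)
    placements: dict[int, tuple[int, int]] = {}
    for o in offsets:
        for pos in index.kmers.get(seq[o:o + k], ()):
            p = pos - o
            lo, hi = placements.get(p, (o, o))
            placements[p] = (min(lo, o), max(hi, o))
    return placements


_G, _T, _A = ord("G"), ord("T"), ord("A")


def _split_costs(ref: np.ndarray, mate: np.ndarray, p_left: int, p_right: int,
                 cfg: MapperConfig) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Per-split-point data for a junction between two placements.

    Returns (valid split positions, cumulative-cost helper pair) or None.
    """
    m = mate.size
    if p_left < 0 or p_right + m > ref.size:
        return None
    mm_l = np.concatenate(([0], np.cumsum(ref[p_left:p_left + m] != mate)))
    mm_r = np.concatenate(([0], np.cumsum(ref[p_right:p_right + m] != mate)))
    s = np.arange(cfg.min_anchor, m - cfg.min_anchor + 1)
    donor_ok = (ref[p_left + s] == _G) & (ref[p_left + s + 1] == _T)
    acc_ok = (ref[p_right + s - 2] == _A) & (ref[p_right + s - 1] == _G)
    valid = s[donor_ok & acc_ok]
    if valid.size == 0:
        return None
    return valid, (mm_l, mm_r)


def _map_mate(seq: str, index: ReferenceIndex, cfg: MapperConfig):
    """Best alignment of one mate string on the forward reference strand.

    Returns (mismatches, blocks) or None; an ambiguous best (two
    placements with equal cost and block count) also returns None so that
    multi-mapping reads never contribute junction evidence.
    """
    m = len(seq)
    ref = index.arr
    mate = _mate_array(seq)
    limit = cfg.mismatch_limit
    placements = _candidate_placements(seq, index, cfg.seed_step)
    candidates: list[tuple[int, int, tuple]] = []  # (mism, nblocks, blocks)

    for p in placements:
        if 0 <= p and p + m <= ref.size:
            mism = int(np.count_nonzero(ref[p:p + m] != mate))
            if mism <= limit:
                candidates.append((mism, 1, ((p, p + m, 0),)))

    if cfg.mode == "transcriptome":
        order = sorted(placements)
        for i, p1 in enumerate(order):
            for p2 in order[i + 1:]:
                skip = p2 - p1
                if skip < 4 or skip > cfg.max_skip:
                    continue
                # seeds must support the left placement earlier in the read
                if placements[p1][0] >= placements[p2][1]:
                    continue
                data = _split_costs(ref, mate, p1, p2, cfg)
                if data is None:
                    continue
                valid, (mm_l, mm_r) = data
                cost = mm_l[valid] + (mm_r[m] - mm_r[valid])
                best = int(np.argmin(cost))
                if cost[best] <= limit:
                    s = int(valid[best])
                    candidates.append((int(cost[best]), 2,
                                       ((p1, p1 + s, 0), (p2 + s, p2 + m, s))))
        # three-block chains across two skips
        for i, p1 in enumerate(order):
            for j, p2 in enumerate(order[i + 1:], i + 1):
                if not (4 <= p2 - p1 <= cfg.max_skip):
                    continue
                for p3 in order[j + 1:]:
                    if not (4 <= p3 - p2 <= cfg.max_skip):
                        continue
                    if not (placements[p1][0] < placements[p2][1]
                            and placements[p2][0] < placements[p3][1]):
                        continue
                    d12 = _split_costs(ref, mate, p1, p2, cfg)
                    d23 = _split_costs(ref, mate, p2, p3, cfg)
                    if d12 is None or d23 is None:
                        continue
                    v1, (mmA, mmB) = d12
                    v2, (_, mmC) = d23
                    best = None
                    for s2 in v2:
                        use = v1[v1 <= s2 - cfg.min_anchor]
                        if use.size == 0:
                            continue
                        c1 = mmA[use] - mmB[use]
                        k1 = int(np.argmin(c1))
                        total = (int(c1[k1]) + int(mmB[s2])
                                 + int(mmC[m] - mmC[s2]))
                        key = (total, int(use[k1]), int(s2))
                        if best is None or key < best:
                            best = key
                    if best is not None and best[0] <= limit:
                        total, s1, s2 = best
                        candidates.append((total, 3,
                                           ((p1, p1 + s1, 0),
                                            (p2 + s1, p2 + s2, s1),
                                            (p3 + s2, p3 + m, s2))))

    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    best = candidates[0]
    # ambiguity: a distinct placement achieving the same cost and shape
    for other in candidates[1:]:
        if other[2] == best[2]:
            continue
        if (other[0], other[1]) == (best[0], best[1]):
            return None
        break
    return best[0], best[2]


def map_read_pair(pair: ReadPair, index: ReferenceIndex,
                  cfg: MapperConfig = MapperConfig()
                  ) -> Optional[tuple[AlignmentRecord, AlignmentRecord]]:
    """Map both mates; returns None when the pair is unmapped.

    Orientations FR and RF are both tried; the pair is kept only if both
    mates map unambiguously and the reference span is within
    ``[span_min, span_max]``.
    """
    results = []
    for strand1, strand2 in (("+", "-"), ("-", "+")):
        seq1 = pair.mate1 if strand1 == "+" else reverse_complement(pair.mate1)
        seq2 = pair.mate2 if strand2 == "+" else reverse_complement(pair.mate2)
        a1 = _map_mate(seq1, index, cfg)
        a2 = _map_mate(seq2, index, cfg)
        if a1 is None or a2 is None:
            continue
        span = (max(a1[1][-1][1], a2[1][-1][1])
                - min(a1[1][0][0], a2[1][0][0]))
        if not (cfg.span_min <= span <= cfg.span_max):
            continue
        results.append((a1[0] + a2[0], strand1, a1, a2))
    if not results:
        return None
    results.sort(key=lambda r: r[0])
    if len(results) == 2 and results[0][0] == results[1][0]:
        return None  # orientation-ambiguous
    _, strand1, a1, a2 = results[0]
    rid = index.reference.id
    rec1 = AlignmentRecord(pair.id, 1, rid, strand1, a1[1], a1[0])
    rec2 = AlignmentRecord(pair.id, 2, rid, "-" if strand1 == "+" else "+",
                           a2[1], a2[0])
    return rec1, rec2


def map_reads(pairs: Iterable[ReadPair], reference: SequenceRecord,
              cfg: MapperConfig = MapperConfig()) -> list[AlignmentRecord]:
    """Map a collection of pairs; unmapped pairs are silently dropped."""
    index = ReferenceIndex(reference, k=cfg.seed_length)
    out: list[AlignmentRecord] = []
    for pair in pairs:
        mapped = map_read_pair(pair, index, cfg)
        if mapped is not None:
            out.extend(mapped)
    return out


def determine_bounds(alignments: Iterable[AlignmentRecord],
                     reference: SequenceRecord) -> tuple[int, int]:
    """Transcription start/termination sites: the extreme coordinates
    covered by any mapped mate (0-based half-open)."""
    alignments = list(alignments)
    if not alignments:
        raise EvidenceError("no mapped pairs; cannot determine gene bounds")
    return (min(a.start for a in alignments),
            max(a.end for a in alignments))


@dataclass(frozen=True)
class CoverageReport:
    depth: np.ndarray
    region: tuple[int, int]
    verified: bool
    min_depth: int
    gaps: tuple[tuple[int, int], ...]


def coverage_profile(alignments: Iterable[AlignmentRecord],
                     region: tuple[int, int]) -> CoverageReport:
    """Per-base aligned-block depth over ``region``; skips contribute
    nothing.  The region is "verified" iff its minimum depth is >= 1; the
    minimum depth is reported so stronger thresholds can be checked."""
    start, end = region
    if end <= start:
        raise ConfigurationError(f"empty region [{start},{end})")
    depth = np.zeros(end - start, dtype=np.int64)
    for aln in alignments:
        for (s, e, _) in aln.blocks:
            lo, hi = max(s, start), min(e, end)
            if lo < hi:
                depth[lo - start:hi - start] += 1
    min_depth = int(depth.min())
    gaps = []
    in_gap = None
    for i, d in enumerate(depth):
        if d == 0 and in_gap is None:
            in_gap = i
        elif d > 0 and in_gap is not None:
            gaps.append((start + in_gap, start + i))
            in_gap = None
    if in_gap is not None:
        gaps.append((start + in_gap, end))
    return CoverageReport(depth=depth, region=region,
                          verified=min_depth >= 1, min_depth=min_depth,
                          gaps=tuple(gaps))
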