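"""GT-AG junction calling and per-intron splicing-mode classification.

From junction-aware alignments, distinct reference skips with GT-AG ends
become junction evidence; against a canonical gene model each intron then
accumulates a state set: ``canonical``, ``retained`` (contiguous reads
crossing both exon-intron boundaries), ``alt5`` (shared acceptor, shifted
donor) and ``alt3`` (shared donor, shifted acceptor).  States accumulate -
an intron may be both retained and alternatively spliced, as observed for
the third intron of the Cu-Zn SOD gene.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import AmbiguityError, ConfigurationError, EvidenceError
from .mapping import AlignmentRecord
from .models import (CANONICAL, RETAINED, GeneModel, Intron, SequenceRecord,
                     SpliceState)

MIN_SUPPORT_DEFAULT = 2
RETENTION_ANCHOR = 8


@dataclass(frozen=True)
class JunctionEvidence:
    """A distinct (donor, acceptor) reference skip with read support."""

    donor: int
    acceptor: int
    support: int

    def __post_init__(self):
        if self.acceptor - self.donor < 4:
            raise ConfigurationError("junction shorter than 4 bases")
        if self.support < 1:
            raise ConfigurationError("junction must have support >= 1")


@dataclass(frozen=True)
class IntronEvents:
    """Observed states of one canonical intron."""

    index: int  # 0-based intron index in the gene model
    start: int
    end: int
    states: tuple[tuple[SpliceState, int], ...]  # (state, support)

    def state_set(self) -> set[SpliceState]:
        return {s for s, _ in self.states}

    def support(self, state: SpliceState) -> int:
        for s, n in self.states:
            if s == state:
                return n
        return 0


@dataclass(frozen=True)
class SpliceEventCatalog:
    gene_id: str
    introns: tuple[IntronEvents, ...]
    novel: tuple[JunctionEvidence, ...] = ()

    def state_sets(self) -> list[list[SpliceState]]:
        return [sorted(ev.state_set()) for ev in self.introns]


def call_introns(alignments: Iterable[AlignmentRecord],
                 reference: SequenceRecord,
                 min_support: int = MIN_SUPPORT_DEFAULT) -> list[JunctionEvidence]:
    """Collapse alignment skips into junction evidence.

    Every skip is re-checked against the GT-AG rule on the reference; one
    mate contributes at most once to a given junction; junctions below
    ``min_support`` unique reads are dropped.  Output is sorted by donor
    then acceptor.
    """
    seq = reference.residues
    support: dict[tuple[int, int], set] = defaultdict(set)
    for aln in alignments:
        for donor, acceptor in aln.skips():
            if seq[donor:donor + 2] != "GT" or seq[acceptor - 2:acceptor] != "AG":
                continue
            support[(donor, acceptor)].add((aln.read_id, aln.mate))
    out = [JunctionEvidence(d, a, len(reads))
           for (d, a), reads in support.items() if len(reads) >= min_support]
    out.sort(key=lambda j: (j.donor, j.acceptor))
    return out


def _retention_support(alignments: Iterable[AlignmentRecord], boundary: int,
                       anchor: int = RETENTION_ANCHOR) -> int:
    """Reads whose single contiguous block crosses ``boundary`` by at
    least ``anchor`` bases on each side."""
    readers = set()
    for aln in alignments:
        for (s, e, _) in aln.blocks:
            if s <= boundary - anchor and e >= boundary + anchor:
                readers.add((aln.read_id, aln.mate))
    return len(readers)


def classify_events(junctions: Iterable[JunctionEvidence],
                    retention_evidence: Iterable[AlignmentRecord],
                    canonical_model: GeneModel,
                    min_support: int = MIN_SUPPORT_DEFAULT) -> SpliceEventCatalog:
    """Assign junctions and retention evidence to canonical introns.

    For canonical intron [s, e): a junction equal to it supports the
    canonical state; one sharing the acceptor with a shifted donor is an
    alternative 5' site (signed offset = shift); one sharing the donor
    with a shifted acceptor an alternative 3' site; an intron is retained
    when at least ``min_support`` contiguous reads cross each of its two
    boundaries (support reported as the weaker boundary).  Junctions
    sharing neither end are reported as novel, not classified.
    """
    junctions = list(junctions)
    alignments = list(retention_evidence)
    introns = canonical_model.introns
    events = []
    claimed: set[tuple[int, int]] = set()
    for i, iv in enumerate(introns):
        states: list[tuple[SpliceState, int]] = []
        canon_support = 0
        for j in junctions:
            if (j.donor, j.acceptor) == (iv.start, iv.end):
                canon_support = j.support
                claimed.add((j.donor, j.acceptor))
            elif j.acceptor == iv.end and j.donor != iv.start:
                states.append((SpliceState("alt5", j.donor - iv.start), j.support))
                claimed.add((j.donor, j.acceptor))
            elif j.donor == iv.start and j.acceptor != iv.end:
                states.append((SpliceState("alt3", j.acceptor - iv.end), j.support))
                claimed.add((j.donor, j.acceptor))
        left = _retention_support(alignments, iv.start)
        right = _retention_support(alignments, iv.end)
        if left >= min_support and right >= min_support:
            states.append((RETAINED, min(left, right)))
        # canonical state is always present for a called intron
        states.insert(0, (CANONICAL, canon_support))
        states.sort(key=lambda sn: sn[0])
        events.append(IntronEvents(index=i, start=iv.start, end=iv.end,
                                   states=tuple(states)))
    novel = tuple(j for j in junctions
                  if (j.donor, j.acceptor) not in claimed)
    return SpliceEventCatalog(gene_id=canonical_model.gene_id,
                              introns=tuple(events), novel=novel)


def dominant_introns(junctions: Iterable[JunctionEvidence],
                     reference: SequenceRecord) -> list[Intron]:
    """Pick one canonical intron per junction cluster when no model is
    given: the junction with maximal support among junctions sharing
    either end, ties broken by smaller intron length then donor."""
    junctions = sorted(junctions, key=lambda j: (-j.support,
                                                 j.acceptor - j.donor,
                                                 j.donor))
    chosen: list[JunctionEvidence] = []
    for j in junctions:
        if any(c.donor == j.donor or c.acceptor == j.acceptor
               or not (j.acceptor <= c.donor or j.donor >= c.acceptor)
               for c in chosen):
            continue
        chosen.append(j)
    chosen.sort(key=lambda j: j.donor)
    return [Intron(j.donor, j.acceptor) for j in chosen]


def annotate_model(catalog_or_junctions, bounds: tuple[int, int],
                   reference: SequenceRecord,
                   gene_id: str = "gene") -> GeneModel:
    """Build a verified gene model: exons are the complement of the
    canonical introns within [TSS, TES)."""
    tss, tes = bounds
    if isinstance(catalog_or_junctions, SpliceEventCatalog):
        introns = [Intron(ev.start, ev.end)
                   for ev in catalog_or_junctions.introns]
        gene_id = catalog_or_junctions.gene_id
    else:
        introns = dominant_introns(catalog_or_junctions, reference)
    introns = [iv for iv in introns if tss < iv.start and iv.end < tes]
    introns.sort(key=lambda iv: iv.start)
    for a, b in zip(introns, introns[1:]):
        if b.start < a.end:
            raise AmbiguityError(
                f"canonical introns overlap: [{a.start},{a.end}) and "
                f"[{b.start},{b.end})")
    return GeneModel(gene_id=gene_id, reference=reference,
                     tss=tss, tes=tes, introns=introns)
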