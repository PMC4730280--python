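"""Combinatorial isoform enumeration, ORF discovery and domain screening.

Transcripts are the Cartesian product of the per-intron state sets; each
is scanned for its longest ATG-initiated open reading frame, translated,
and checked against a SOD residue profile.  This reproduces the analysis
in which the initiation codon of the functional Cu-Zn SOD ORF lies inside
a retainable intron, so only transcripts retaining that intron can encode
the domain-complete protein.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ConfigurationError, InputError
from .models import GeneModel, SpliceState, translate
from .screen import DomainProfile, ScreenConfig, domain_check, local_align

ORF_MIN_CODONS_DEFAULT = 50
ENUMERATION_CAP = 10 ** 6


@dataclass(frozen=True)
class ORFAnnotation:
    """Longest ORF of a transcript, with flanking UTRs.

    ``start``/``end`` are transcript coordinates of the ORF including its
    stop codon, so ``end - start == 3 * (len(protein) + 1)``.
    """

    start: int
    end: int
    utr5: str
    utr3: str
    protein: str

    def __post_init__(self):
        if (self.end - self.start) % 3:
            raise InputError("ORF length must be a multiple of 3")


@dataclass(frozen=True)
class IsoformReport:
    transcript_id: str
    states: tuple[SpliceState, ...]
    sequence: str
    orf: Optional[ORFAnnotation]
    verdict: Optional[str]  # present iff orf is present
    group: Optional[int]  # distinct-protein group id (None without ORF)


def enumerate_transcripts(gene_model: GeneModel,
                          state_sets: Sequence[Sequence[SpliceState]],
                          cap: int = ENUMERATION_CAP,
                          ) -> list[tuple[tuple[SpliceState, ...], str]]:
    """All state-vector transcripts in lexicographic state order.

    The result length is exactly the product of the per-intron state-set
    sizes; a product beyond ``cap`` raises instead of enumerating.
    """
    if len(state_sets) != len(gene_model.introns):
        raise InputError(
            f"{len(state_sets)} state sets for {len(gene_model.introns)} introns")
    total = 1
    for states in state_sets:
        if not states:
            raise InputError("every intron needs at least one state")
        total *= len(states)
    if total > cap:
        raise ConfigurationError(
            f"state-vector product {total} exceeds cap {cap}")
    out = []
    for vec in itertools.product(*[sorted(s) for s in state_sets]):
        out.append((vec, gene_model.transcript(vec)))
    return out


def find_orf(transcript: str,
             min_codons: int = ORF_MIN_CODONS_DEFAULT) -> Optional[ORFAnnotation]:
    """Longest ATG-initiated ORF ending at an in-frame stop.

    Ties go to the 5'-most start; ORFs encoding fewer than ``min_codons``
    residues are ignored; an ATG with no downstream in-frame stop does not
    qualify.  Returns None when nothing qualifies.
    """
    best: Optional[tuple[int, int]] = None  # (-length, start)
    pos = transcript.find("ATG")
    while pos != -1:
        end = None
        for j in range(pos, len(transcript) - 2, 3):
            codon = transcript[j:j + 3]
            if codon in ("TAA", "TAG", "TGA"):
                end = j + 3
                break
        if end is not None:
            length = end - pos
            if (length // 3) - 1 >= min_codons:
                key = (-length, pos)
                if best is None or key < best:
                    best = key
        pos = transcript.find("ATG", pos + 1)
    if best is None:
        return None
    length, start = -best[0], best[1]
    end = start + length
    protein = translate(transcript[start:end])[:-1]
    return ORFAnnotation(start=start, end=end, utr5=transcript[:start],
                         utr3=transcript[end:], protein=protein)


def screen_isoforms(transcripts: Iterable[tuple[tuple[SpliceState, ...], str]],
                    profile: DomainProfile,
                    min_codons: int = ORF_MIN_CODONS_DEFAULT,
                    config: ScreenConfig = ScreenConfig(),
                    gene_id: str = "gene") -> list[IsoformReport]:
    """Translate every transcript's ORF and run the domain check.

    Reports are grouped by identical protein string: the group id is
    shared by state vectors yielding the same protein, numbered by first
    appearance in lexicographic enumeration order.
    """
    reports = []
    groups: dict[str, int] = {}
    for i, (vec, seq) in enumerate(transcripts, 1):
        orf = find_orf(seq, min_codons=min_codons)
        verdict = None
        group = None
        if orf is not None:
            aln = local_align(orf.protein, profile.reference.residues, config)
            verdict, _ = domain_check(orf.protein, profile, aln)
            group = groups.setdefault(orf.protein, len(groups) + 1)
        reports.append(IsoformReport(
            transcript_id=f"{gene_id}.iso{i:03d}", states=tuple(vec),
            sequence=seq, orf=orf, verdict=verdict, group=group))
    return reports


def count_distinct_proteins(reports: Iterable[IsoformReport],
                            which: str = "domain-any",
                            ) -> tuple[int, list[tuple[str, IsoformReport]]]:
    """Distinct protein strings passing a filter.

    ``which`` is ``all-with-ORF`` (any translated isoform),
    ``domain-complete`` or ``domain-any`` (complete or partial).  The
    representative of each group is the report with the lexicographically
    smallest state vector.
    """
    if which not in ("all-with-ORF", "domain-complete", "domain-any"):
        raise InputError(f"unknown filter {which!r}")
    chosen: dict[str, IsoformReport] = {}
    for rep in reports:
        if rep.orf is None:
            continue
        if which == "domain-complete" and rep.verdict != "complete":
            continue
        if which == "domain-any" and rep.verdict not in ("complete", "partial"):
            continue
        prot = rep.orf.protein
        if prot not in chosen or rep.states < chosen[prot].states:
            chosen[prot] = rep
    out = sorted(((p, r) for p, r in chosen.items()),
                 key=lambda pr: pr[1].states)
    return len(out), out
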