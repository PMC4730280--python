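"""Synthetic-data generators: fixture genes, read pairs, Ct tables, proteomes.

The three built-in fixture genes reproduce the intron layouts of the
*V. volvacea* SOD genes: a Cu-Zn SOD gene with eight introns
(52/76/80/125/57/58/54/55 bp) whose fourth intron carries the initiation
codon of the functional open reading frame, and two Mn SOD genes with
three introns (154/57/56 bp) and seven introns (47/72/126/119/88/61/87 bp).
Each intron is flagged with the splicing modes observed for it (intron
retention, alternative 5'/3' splice sites), and those flags define the
state space that both the read simulator and the isoform enumerator use.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import log2
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .models import (CANONICAL, RETAINED, GeneModel, Intron, ReadPair,
                     SequenceRecord, SpliceState, SYNONYMOUS, translate)
from .screen import (CUZN_REQUIRED, MN_REQUIRED, DomainProfile, ScreenConfig,
                     domain_check, local_align)

_BASES = np.array(list("ACGT"))
_AA20 = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# Intron and exon design

@dataclass(frozen=True)
class IntronSpec:
    """Length and splicing modes of one fixture intron.

    Offsets follow the signed :class:`~sodsplice.models.SpliceState`
    convention (positive = boundary moved downstream), so an alternative
    site may fall on either side of the canonical boundary; magnitudes must
    be at least 3 and smaller than the intron length.
    """

    length: int
    retention_capable: bool = False
    alt5_offset: int = 0
    alt3_offset: int = 0
    contains_initiation_codon: bool = False

    def __post_init__(self):
        if self.length < 4:
            raise ConfigurationError("intron length must be >= 4 (GT...AG)")
        for off in (self.alt5_offset, self.alt3_offset):
            if off and not (3 <= abs(off) < self.length):
                raise ConfigurationError(
                    f"alternative-site offset {off} must have 3 <= |offset| "
                    f"< intron length {self.length}")
        if self.contains_initiation_codon and not self.retention_capable:
            raise ConfigurationError(
                "an initiation-codon intron must be retention-capable")

    @property
    def states(self) -> list[SpliceState]:
        out = [CANONICAL]
        if self.retention_capable:
            out.append(RETAINED)
        if self.alt5_offset:
            out.append(SpliceState("alt5", self.alt5_offset))
        if self.alt3_offset:
            out.append(SpliceState("alt3", self.alt3_offset))
        return out


# The printed intron layouts of the three SOD genes.
CUZN_SOD1_INTRONS = (
    IntronSpec(52, retention_capable=True),
    IntronSpec(76, alt3_offset=+6),
    IntronSpec(80, retention_capable=True, alt3_offset=+6),
    IntronSpec(125, retention_capable=True, contains_initiation_codon=True),
    IntronSpec(57),
    IntronSpec(58),
    IntronSpec(54, retention_capable=True),
    IntronSpec(55, retention_capable=True),
)
MN_SOD1_INTRONS = (
    IntronSpec(154, retention_capable=True, alt5_offset=-9),
    IntronSpec(57, retention_capable=True),
    IntronSpec(56),
)
MN_SOD2_INTRONS = (
    IntronSpec(47, retention_capable=True),
    IntronSpec(72),
    IntronSpec(126, retention_capable=True),
    IntronSpec(119, retention_capable=True),
    IntronSpec(88, retention_capable=True),
    IntronSpec(61),
    IntronSpec(87, retention_capable=True),
)


@dataclass(frozen=True)
class ExonDesign:
    """How the coding sequence and UTRs are laid out across exons.

    ``intron_sites`` are insertion points in canonical-transcript
    coordinates.  When ``start_intron`` is set, the initiation codon of the
    functional ORF lies inside that intron: the transcript region upstream
    of it (``utr5_len`` bases) is entirely non-coding, the first
    ``lead_codons`` codons of the protein sit at the 3' end of the intron
    (the last codon doubles as the acceptor AG, so that residue must be
    E/K/Q), and the remaining codons follow in the downstream exons.
    """

    gene_id: str
    protein: str
    intron_sites: tuple[int, ...]
    utr5_len: int = 60
    utr3_len: int = 60
    flank: int = 100
    start_intron: Optional[int] = None
    lead_codons: int = 12

    def __post_init__(self):
        if list(self.intron_sites) != sorted(set(self.intron_sites)):
            raise ConfigurationError("intron sites must strictly increase")
        if self.start_intron is not None:
            if not (0 <= self.start_intron < len(self.intron_sites)):
                raise ConfigurationError("start_intron out of range")
            if self.intron_sites[self.start_intron] != self.utr5_len:
                raise ConfigurationError(
                    "the initiation-codon intron must sit at the boundary "
                    "between the non-coding leader and the coding tail")
            if self.protein[self.lead_codons - 1] not in "EKQ":
                raise ConfigurationError(
                    "the residue whose codon ends the initiation-codon intron "
                    "must be E, K or Q (codon ending in AG)")


@dataclass(frozen=True)
class GeneFixture:
    """A constructed gene with its ground truth."""

    model: GeneModel
    specs: tuple[IntronSpec, ...]
    design: ExonDesign
    protein: str
    start_codon: int  # genomic position of the functional ATG

    @property
    def gene_id(self) -> str:
        return self.model.gene_id

    @property
    def state_sets(self) -> list[list[SpliceState]]:
        return [sp.states for sp in self.specs]

    def state_vectors(self) -> list[tuple[SpliceState, ...]]:
        return [tuple(v) for v in itertools.product(*self.state_sets)]


# ---------------------------------------------------------------------------
# Sequence-level helpers

def _filler(rng: np.random.Generator, n: int) -> list[str]:
    seq = list(rng.choice(_BASES, n))
    return seq


def _choose_codons(protein: str, rng: np.random.Generator,
                   context: str = "", forced: Optional[dict] = None,
                   start_is_atg: bool = False) -> str:
    """Encode a protein (optionally ending '*') avoiding any ATG other than
    an explicit start codon, including ATGs spanning codon boundaries."""
    forced = forced or {}
    option_lists: list[list[str]] = []
    for idx, aa in enumerate(protein):
        if idx == 0 and start_is_atg:
            if aa != "M":
                raise ConfigurationError("start codon requires Met first")
            option_lists.append(["ATG"])
            continue
        options = [c for c in SYNONYMOUS[aa] if c != "ATG"]
        want = forced.get(idx)
        if want is not None:
            options = [c for c in options
                       if c == want or (want.endswith("*") and c.startswith(want[:-1]))]
        if not options:
            raise ConfigurationError(
                f"residue {aa!r} at {idx} has no admissible codon")
        rng.shuffle(options)
        option_lists.append(options)

    # depth-first search: a codon is admissible if appending it creates no
    # ATG across the rolling 2-base tail; backtrack on dead ends
    out: list[str] = []
    tails: list[str] = [context[-2:]]
    cursors = [0] * len(option_lists)
    idx = 0
    while idx < len(option_lists):
        placed = False
        while cursors[idx] < len(option_lists[idx]):
            c = option_lists[idx][cursors[idx]]
            cursors[idx] += 1
            if idx == 0 and start_is_atg:
                ok = True  # the designated start codon itself
            else:
                ok = "ATG" not in tails[-1] + c
            if ok:
                out.append(c)
                tails.append((tails[-1] + c)[-2:])
                placed = True
                break
        if placed:
            idx += 1
        else:
            if not out:
                raise ConfigurationError(
                    "no codon assignment avoids spurious ATGs")
            cursors[idx] = 0
            out.pop()
            tails.pop()
            idx -= 1
    return "".join(out)


_FAMILY_BASE_SEED = {"CuZn": 7001, "Mn": 7002, "Fe": 7003, "Ni": 7004}
_FAMILY_REQUIRED = {"CuZn": CUZN_REQUIRED, "Mn": MN_REQUIRED}


def family_base_protein(family: str, length: int = 180) -> str:
    """The fixed family exemplar: a synthetic SOD-like protein carrying
    the family's conserved residues at their profile positions, with Met
    only at position 1.  Every family member is a diverged copy of this."""
    required = _FAMILY_REQUIRED.get(family)
    if required is None:
        raise ConfigurationError(f"no residue profile for family {family!r}")
    if length < max(p for p, _ in required):
        raise ConfigurationError(
            f"protein length {length} shorter than profile span")
    rng = np.random.default_rng(_FAMILY_BASE_SEED[family])
    aa_pool = np.array([a for a in _AA20 if a != "M"])
    res = list(rng.choice(aa_pool, length))
    res[0] = "M"
    for pos, r in required:
        res[pos - 1] = r
    return "".join(res)


def design_family_protein(family: str, seed: int, length: int = 180,
                          forced: Optional[dict] = None,
                          divergence: float = 0.25) -> str:
    """One family member: the family exemplar mutated at ``divergence``
    of its non-conserved positions (profile residues and the start Met are
    never touched), plus any explicitly forced residues."""
    base = family_base_protein(family, length)
    required = _FAMILY_REQUIRED[family]
    keep = {p - 1 for p, _ in required} | {0} | set(forced or {})
    rng = np.random.default_rng(seed)
    aa_pool = [a for a in _AA20 if a != "M"]
    res = list(base)
    for i in range(length):
        if i not in keep and rng.random() < divergence:
            res[i] = aa_pool[int(rng.integers(len(aa_pool)))]
    for pos, r in (forced or {}).items():
        res[pos] = r
    return "".join(res)


# ---------------------------------------------------------------------------
# Gene construction

def _scrub_atg(genome: list[str], mutable: list[bool], keep: set[int]) -> None:
    """Mutate filler bases so the genome's only ATG is the designated start."""
    changed = True
    while changed:
        changed = False
        text = "".join(genome)
        pos = text.find("ATG")
        while pos != -1:
            if pos not in keep:
                for k in (pos + 1, pos, pos + 2):
                    if mutable[k]:
                        genome[k] = "C"
                        changed = True
                        break
                else:
                    raise ConfigurationError(
                        f"stray ATG at {pos} overlaps immutable bases")
                break  # rescan from a fresh string
            pos = text.find("ATG", pos + 1)


def _fix_junction_spans(genome: list[str], mutable: list[bool],
                        junctions: list[tuple[int, int]]) -> None:
    """Remove ATGs created by juxtaposition at (any) splice junction."""
    for cut_start, cut_end in junctions:
        for _ in range(4):
            left = "".join(genome[max(0, cut_start - 2):cut_start])
            right = "".join(genome[cut_end:cut_end + 2])
            span = left + right
            hit = span.find("ATG")
            if hit == -1 or len(left) < 2:
                break
            idxs = [cut_start - 2, cut_start - 1, cut_end, cut_end + 1]
            for k in idxs[hit:hit + 3]:
                if mutable[k]:
                    genome[k] = "C"
                    break
            else:
                raise ConfigurationError(
                    f"junction ({cut_start},{cut_end}) spawns an immutable ATG")


def _junction_ambiguous(text: str, s: int, e: int, max_shift: int = 8) -> bool:
    """True if shifting the whole junction by d bases yields an
    indistinguishable GT...AG junction (the classic alignment ambiguity)."""
    for d in range(-max_shift, max_shift + 1):
        if d == 0:
            continue
        if d > 0:
            same = text[s:s + d] == text[e:e + d]
        else:
            same = text[s + d:s] == text[e + d:e]
        if same and text[s + d:s + d + 2] == "GT" and text[e + d - 2:e + d] == "AG":
            return True
    return False


def build_gene_fixture(intron_specs: Sequence[IntronSpec], exon_design: ExonDesign,
                       seed: int) -> GeneFixture:
    """Construct a gene region realizing the intron layout and exon design.

    Guarantees: every intron (and every alternative site) is GT...AG; the
    genome contains exactly one ATG - the functional initiation codon; no
    splice junction is shift-ambiguous; when the initiation codon lies in a
    retainable intron, only transcripts retaining that intron contain an
    ATG at all.  Construction retries with fresh filler if a random draw
    violates one of these, so the result is a pure function of (specs,
    design, seed).
    """
    last_err: Exception | None = None
    for attempt in range(40):
        try:
            return _build_once(tuple(intron_specs), exon_design,
                               np.random.default_rng([seed, attempt]))
        except ConfigurationError as exc:
            last_err = exc
    raise ConfigurationError(
        f"could not realize fixture after 40 attempts: {last_err}")


def _build_once(specs: tuple[IntronSpec, ...], design: ExonDesign,
                rng: np.random.Generator) -> GeneFixture:
    if len(specs) != len(design.intron_sites):
        raise ConfigurationError("one transcript site is needed per intron")
    protein = design.protein
    k = design.start_intron

    # --- canonical transcript (exonic sequence) with mutability mask
    if k is None:
        utr5 = _filler(rng, design.utr5_len)
        cds = list(_choose_codons(protein + "*", rng, context="".join(utr5[-2:]),
                                  start_is_atg=True))
        t_seq = utr5 + cds + _filler(rng, design.utr3_len)
        t_mut = ([True] * len(utr5) + [False] * len(cds)
                 + [True] * design.utr3_len)
        atg_t = design.utr5_len  # transcript coordinate of the start codon
        lead_cds = ""
    else:
        lead_aa = protein[:design.lead_codons]
        lead_cds = _choose_codons(lead_aa, rng, context="",
                                  forced={design.lead_codons - 1:
                                          {"E": "GAG", "K": "AAG", "Q": "CAG"}[lead_aa[-1]]},
                                  start_is_atg=True)
        tail_cds = list(_choose_codons(protein[design.lead_codons:] + "*", rng,
                                       context=lead_cds[-2:]))
        upstream = _filler(rng, design.utr5_len)
        t_seq = upstream + tail_cds + _filler(rng, design.utr3_len)
        t_mut = ([True] * len(upstream) + [False] * len(tail_cds)
                 + [True] * design.utr3_len)
        atg_t = None

    if design.intron_sites[-1] >= len(t_seq):
        raise ConfigurationError("intron site beyond transcript end")
    if design.intron_sites[0] < 1:
        raise ConfigurationError("first intron site leaves no leading exon")

    # --- intron sequences
    introns_seq: list[list[str]] = []
    introns_mut: list[list[bool]] = []
    for i, sp in enumerate(specs):
        if k is not None and i == k:
            lead_len = 3 * design.lead_codons
            fill = sp.length - 2 - lead_len
            if fill < 1:
                raise ConfigurationError(
                    f"intron {i + 1} too short for {design.lead_codons} lead codons")
            body = list("GT") + _filler(rng, fill) + list(lead_cds)
            mut = [False, False] + [True] * fill + [False] * lead_len
        else:
            body = list("GT") + _filler(rng, sp.length - 4) + list("AG")
            mut = [False, False] + [True] * (sp.length - 4) + [False, False]
        if sp.contains_initiation_codon and (k is None or i != k):
            raise ConfigurationError(
                "contains_initiation_codon set but design.start_intron differs")
        introns_seq.append(body)
        introns_mut.append(mut)

    # --- assemble the genomic region
    genome: list[str] = _filler(rng, design.flank)
    mutable: list[bool] = [True] * design.flank
    tss = design.flank
    intron_bounds: list[tuple[int, int]] = []
    prev_site = 0
    for i, site in enumerate(design.intron_sites):
        seg = t_seq[prev_site:site]
        genome += seg
        mutable += t_mut[prev_site:site]
        start = len(genome)
        genome += introns_seq[i]
        mutable += introns_mut[i]
        intron_bounds.append((start, len(genome)))
        prev_site = site
    genome += t_seq[prev_site:]
    mutable += t_mut[prev_site:]
    tes = len(genome)
    genome += _filler(rng, design.flank)
    mutable += [True] * design.flank

    # --- alternative-site motifs: write into filler or verify in coding
    junction_cuts: list[tuple[int, int]] = []
    for (s, e), sp in zip(intron_bounds, specs):
        junction_cuts.append((s, e))
        for kind, off in (("alt5", sp.alt5_offset), ("alt3", sp.alt3_offset)):
            if not off:
                continue
            if kind == "alt5":
                cut = (s + off, e)
                motif_at, motif = s + off, "GT"
            else:
                cut = (s, e + off)
                motif_at, motif = e + off - 2, "AG"
            junction_cuts.append(cut)
            for j, base in enumerate(motif):
                pos = motif_at + j
                if mutable[pos]:
                    genome[pos] = base
                    mutable[pos] = False
                elif genome[pos] != base:
                    raise ConfigurationError(
                        f"{kind} site of intron at {s} needs {motif} at {pos} "
                        f"inside coding sequence; adjust the forced codon")

    # --- single-ATG guarantee
    if k is None:
        # introns inserted upstream of the start shift its genomic position
        g_atg = tss + atg_t + sum(
            sp.length for sp, site in zip(specs, design.intron_sites)
            if site <= atg_t)
    else:
        s, e = intron_bounds[k]
        g_atg = e - 3 * design.lead_codons
    _scrub_atg(genome, mutable, keep={g_atg})
    _fix_junction_spans(genome, mutable, junction_cuts)
    _scrub_atg(genome, mutable, keep={g_atg})

    text = "".join(genome)
    for cut_s, cut_e in junction_cuts:
        if _junction_ambiguous(text, cut_s, cut_e):
            raise ConfigurationError(
                f"junction ({cut_s},{cut_e}) is shift-ambiguous; retrying")

    model = GeneModel(
        gene_id=design.gene_id,
        reference=SequenceRecord(f"{design.gene_id}_region", text),
        tss=tss, tes=tes,
        introns=[Intron(s, e) for s, e in intron_bounds])
    fixture = GeneFixture(model=model, specs=specs, design=design,
                          protein=protein, start_codon=g_atg)
    _validate_fixture(fixture)
    return fixture


def _validate_fixture(fx: GeneFixture) -> None:
    """Ground-truth checks: ATG placement per state vector, ORF integrity."""
    k = fx.design.start_intron
    model = fx.model
    for states in fx.state_vectors():
        t = model.transcript(states)
        if k is None:
            removed = sum(
                iv.end - iv.start if st.kind == "canonical"
                else (iv.interval(st)[1] - iv.interval(st)[0]
                      if st.kind != "retained" else 0)
                for iv, st in zip(model.introns, states)
                if iv.start < fx.start_codon)
            pos = fx.start_codon - model.tss - removed
            if t[pos:pos + 3] != "ATG" or "ATG" in t[:pos]:
                raise ConfigurationError("start-codon bookkeeping failed")
        elif states[k].kind == "retained":
            removed = sum(
                iv.interval(st)[1] - iv.interval(st)[0]
                for iv, st in zip(model.introns[:k], states[:k])
                if st.kind != "retained")
            pos = fx.start_codon - model.tss - removed
            if t[pos:pos + 3] != "ATG":
                raise ConfigurationError("retained-intron ATG misplaced")
            if "ATG" in t[:pos]:
                raise ConfigurationError("spurious ATG upstream of the start")
        elif "ATG" in t:
            raise ConfigurationError(
                "a transcript splicing out the initiation-codon intron "
                "still contains an ATG")
    # all-canonical ORF of a plain gene (or retained-k ORF) must translate
    if k is None:
        base = tuple(CANONICAL for _ in model.introns)
    else:
        base = tuple(RETAINED if i == k else CANONICAL
                     for i in range(len(model.introns)))
    t = model.transcript(base)
    start = t.find("ATG")
    cds = t[start:start + 3 * (len(fx.protein) + 1)]
    if translate(cds) != fx.protein + "*":
        raise ConfigurationError("reference ORF does not translate the design")


# ---------------------------------------------------------------------------
# Built-in fixtures

def cu_zn_sod1_fixture(seed: int = 101) -> GeneFixture:
    """Eight-intron Cu-Zn SOD gene; the functional ATG sits inside the
    retainable fourth intron, so only I4-retaining transcripts code."""
    protein = design_family_protein("CuZn", seed=seed, forced={11: "E"})
    design = ExonDesign(
        gene_id="Vv_CuZnsod1", protein=protein,
        intron_sites=(70, 130, 195, 250, 360, 465, 565, 660),
        utr5_len=250, utr3_len=60, start_intron=3, lead_codons=12)
    return build_gene_fixture(CUZN_SOD1_INTRONS, design, seed)


def mn_sod1_fixture(seed: int = 102) -> GeneFixture:
    """Three-intron Mn SOD gene; I1 is retainable with an alternative 5'
    site nine bases upstream (requiring a Val codon at the shifted donor)."""
    protein = design_family_protein("Mn", seed=seed, forced={27: "V"})
    design = ExonDesign(
        gene_id="Vv_Mnsod1", protein=protein,
        intron_sites=(150, 300, 450), utr5_len=60, utr3_len=60)
    return build_gene_fixture(MN_SOD1_INTRONS, design, seed)


def mn_sod2_fixture(seed: int = 103) -> GeneFixture:
    """Seven-intron Mn SOD gene with five retention-capable introns."""
    protein = design_family_protein("Mn", seed=seed)
    design = ExonDesign(
        gene_id="Vv_Mnsod2", protein=protein,
        intron_sites=(80, 160, 240, 320, 400, 480, 560),
        utr5_len=60, utr3_len=60)
    return build_gene_fixture(MN_SOD2_INTRONS, design, seed)


def all_fixtures() -> list[GeneFixture]:
    return [cu_zn_sod1_fixture(), mn_sod1_fixture(), mn_sod2_fixture()]


def default_profiles() -> dict[str, DomainProfile]:
    """Domain profiles anchored on the family exemplar proteins."""
    return {
        "CuZn": DomainProfile("CuZn", CUZN_REQUIRED,
                              SequenceRecord("CuZnSOD_ref",
                                             family_base_protein("CuZn"))),
        "Mn": DomainProfile("Mn", MN_REQUIRED,
                            SequenceRecord("MnSOD_ref",
                                           family_base_protein("Mn"))),
    }


# ---------------------------------------------------------------------------
# Read-pair simulation

@dataclass(frozen=True)
class SimulationConfig:
    """Paired-end library geometry and error model.

    Fragment sizes are Normal(300, 50) truncated to [2 x read length,
    1000]; errors are substitutions only; qualities are constant Q40.
    """

    read_length: int = 75
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    coverage: float = 30.0
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 20:
            raise ConfigurationError("read length must be >= 20")
        if not (0 <= self.error_rate < 0.5):
            raise ConfigurationError("error rate must be in [0, 0.5)")
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")


def canonical_mixture() -> dict:
    return {"canonical": 1.0}


def event_mixture(fixture: GeneFixture, canonical_share: float = 0.7) -> dict:
    """The default transcript mixture: ``canonical_share`` canonical and the
    remainder split equally among single-event variant isoforms."""
    variants = []
    n = len(fixture.specs)
    for i, states in enumerate(fixture.state_sets):
        for st in states[1:]:
            vec = tuple(st if j == i else CANONICAL for j in range(n))
            variants.append(vec)
    if not variants:
        return {tuple([CANONICAL] * n): 1.0}
    share = (1.0 - canonical_share) / len(variants)
    mixture = {tuple([CANONICAL] * n): canonical_share}
    for vec in variants:
        mixture[vec] = share
    return mixture


def _normalize_mixture(mixture: dict, n_introns: int) -> list[tuple[tuple, float]]:
    out = []
    for key, prop in mixture.items():
        if key == "canonical":
            key = tuple([CANONICAL] * n_introns)
        key = tuple(key)
        if len(key) != n_introns:
            raise InputError(
                f"mixture state vector length {len(key)} != intron count {n_introns}")
        out.append((key, float(prop)))
    total = sum(p for _, p in out)
    if abs(total - 1.0) > 1e-9:
        raise InputError(f"mixture proportions sum to {total}, not 1")
    out.sort(key=lambda kv: kv[0])
    return out


_COMPLEMENT_ARR = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT_ARR[b] for b in reversed(seq))


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    if hit.any():
        for i in np.nonzero(hit)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def simulate_read_pairs(gene_model: GeneModel, mixture: dict,
                        config: SimulationConfig) -> list[ReadPair]:
    """Simulate paired-end reads from an isoform mixture.

    Fragment counts per isoform are ``coverage * proportion * length /
    (2 * read length)``; mate 1 reads the fragment start forward, mate 2
    the fragment end reverse-complemented.  Provenance (isoform id,
    fragment start) is recorded on every pair.  Same seed, same output.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_length
    lo = 2 * rl
    pairs: list[ReadPair] = []
    qual = "I" * rl
    for vec, prop in _normalize_mixture(mixture, len(gene_model.introns)):
        iso = gene_model.transcript(vec)
        iso_id = ";".join(str(s) for s in vec)
        if len(iso) < lo:
            raise InputError(
                f"isoform {iso_id} shorter than two read lengths")
        hi = min(1000, len(iso))
        n_frag = int(round(config.coverage * prop * len(iso) / (2 * rl)))
        for f in range(n_frag):
            frag_len = None
            for _ in range(1000):
                cand = int(round(rng.normal(config.fragment_mean,
                                            config.fragment_sd)))
                if lo <= cand <= hi:
                    frag_len = cand
                    break
            if frag_len is None:
                raise InputError(
                    f"could not draw a fragment <= isoform {iso_id} "
                    f"in 1000 attempts")
            start = int(rng.integers(0, len(iso) - frag_len + 1))
            frag = iso[start:start + frag_len]
            mate1 = _mutate(frag[:rl], rng, config.error_rate)
            mate2 = _mutate(_revcomp(frag[-rl:]), rng, config.error_rate)
            pairs.append(ReadPair(
                id=f"{gene_model.gene_id}:{iso_id}:{f}",
                mate1=mate1, qual1=qual, mate2=mate2, qual2=qual,
                origin=(iso_id, start)))
    return pairs


def simulate_genome_read_pairs(region: SequenceRecord,
                               config: SimulationConfig) -> list[ReadPair]:
    """Paired-end reads from the unspliced genomic region (the genome
    sequencing pool used for per-base accuracy verification)."""
    model = GeneModel(gene_id=region.id, reference=region,
                      tss=0, tes=len(region), introns=[])
    return simulate_read_pairs(model, {(): 1.0}, config)


# ---------------------------------------------------------------------------
# qPCR Ct tables

@dataclass(frozen=True)
class CtDesign:
    """Generative design for a replicate Ct table.

    The generative model is the inverse of the Livak statistic: the target
    gene's Ct in a condition is ``baseline - log2(fold) + N(0, sd)`` and
    the reference gene's Ct is its own baseline plus the same noise model,
    so running the expression module on the table recovers ``fold``.
    """

    genes: tuple[str, ...]
    conditions: tuple[str, ...]
    calibrator: str
    fold_changes: tuple[tuple[str, str, float], ...]  # (gene, condition, fold)
    replicates: int = 4
    reference_gene: str = "gapdh"
    reference_ct: float = 16.0
    target_ct: float = 22.0
    ct_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 3:
            raise ConfigurationError("replicate count must be >= 3")
        if self.calibrator not in self.conditions:
            raise ConfigurationError("calibrator must be one of the conditions")
        for gene, cond, fold in self.fold_changes:
            if fold <= 0:
                raise ConfigurationError(f"fold change {fold} for {gene}/{cond} "
                                         "must be > 0")

    def fold(self, gene: str, condition: str) -> float:
        for g, c, f in self.fold_changes:
            if g == gene and c == condition:
                return f
        return 1.0


def generate_ct_table(design: CtDesign) -> pd.DataFrame:
    """Replicate-resolved Ct table with known true fold changes."""
    rng = np.random.default_rng(design.seed)
    rows = []
    for cond in design.conditions:
        for rep in range(1, design.replicates + 1):
            sample = f"{cond}_r{rep}"
            rows.append((sample, cond, design.reference_gene, rep,
                         design.reference_ct + rng.normal(0.0, design.ct_sd)))
            for gene in design.genes:
                ct = (design.target_ct - log2(design.fold(gene, cond))
                      + rng.normal(0.0, design.ct_sd))
                rows.append((sample, cond, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "condition", "gene",
                                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# Proteome generation

def generate_proteome(n_decoys: int, embedded_profiles: Iterable[DomainProfile],
                      seed: int, decoy_length: tuple[int, int] = (150, 250),
                      mutation_rate: float = 0.2,
                      reject_profiles: Optional[Iterable[DomainProfile]] = None,
                      ) -> list[SequenceRecord]:
    """A synthetic proteome: uniform-composition decoys plus sequences
    carrying complete family residue profiles.

    Decoys are rejection-sampled so that none of them carries even a
    partial profile (verdict must be ``absent`` against every profile in
    ``reject_profiles``, which defaults to the embedded ones, or to the
    built-in family profiles when nothing is embedded).  Embedded sequences
    are the profile references mutated at non-required positions.
    """
    if n_decoys < 0:
        raise ConfigurationError("n_decoys must be >= 0")
    rng = np.random.default_rng(seed)
    embedded_profiles = list(embedded_profiles)
    rejectors = (list(reject_profiles) if reject_profiles is not None
                 else embedded_profiles) or list(default_profiles().values())
    cfg = ScreenConfig()
    records: list[SequenceRecord] = []
    for i, prof in enumerate(embedded_profiles, 1):
        ref = prof.reference.residues
        keep = {p - 1 for p, _ in prof.required} | {0}
        res = list(ref)
        pool = [a for a in _AA20 if a != "M"]
        for j in range(len(res)):
            if j not in keep and rng.random() < mutation_rate:
                res[j] = pool[int(rng.integers(len(pool)))]
        records.append(SequenceRecord(f"sod_{prof.family}_{i}", "".join(res),
                                      f"embedded {prof.family} profile"))
    aa = np.array(list(_AA20))
    for i in range(1, n_decoys + 1):
        for _ in range(100):
            n = int(rng.integers(decoy_length[0], decoy_length[1] + 1))
            cand = "".join(rng.choice(aa, n))
            ok = True
            for prof in rejectors:
                aln = local_align(cand, prof.reference.residues, cfg)
                verdict, _ = domain_check(cand, prof, aln)
                if verdict != "absent":
                    ok = False
                    break
            if ok:
                records.append(SequenceRecord(f"decoy_{i:04d}", cand))
                break
        else:
            raise ConfigurationError(
                "could not draw a profile-free decoy in 100 attempts")
    return records
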