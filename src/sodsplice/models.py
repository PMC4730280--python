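"""Core domain types shared by every pipeline stage.

Coordinate convention: every in-memory coordinate is 0-based half-open on the
coding strand of the loaded gene region.  Conversion to 1-based inclusive
coordinates happens only at the GFF3 boundary (see :mod:`sodsplice.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import total_ordering
from typing import Optional, Sequence

from .errors import InputError

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ARNDCQEGHILKMFPSTWYVX*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Standard genetic code, DNA codons.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SYNONYMOUS = {}
for _codon, _aa in CODON_TABLE.items():
    SYNONYMOUS.setdefault(_aa, []).append(_codon)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a DNA coding sequence; stops translate to '*'."""
    if len(cds) % 3:
        raise InputError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.residues:
            raise InputError(f"record {self.id!r} has empty residues")

    def validate_nucleotide(self) -> "SequenceRecord":
        bad = set(self.residues) - NUCLEOTIDES
        if bad:
            raise InputError(
                f"record {self.id!r} has non-nucleotide letters {sorted(bad)}")
        return self

    def validate_protein(self) -> "SequenceRecord":
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise InputError(
                f"record {self.id!r} has non-amino-acid letters {sorted(bad)}")
        return self

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read; provenance is set only by the simulator."""

    id: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str
    origin: Optional[tuple] = None  # (isoform id, fragment start on isoform)

    def __post_init__(self):
        if len(self.mate1) != len(self.qual1) or len(self.mate2) != len(self.qual2):
            raise InputError(
                f"read {self.id!r}: sequence and quality lengths differ")


FEATURE_KINDS = {
    "gene", "mRNA", "exon", "intron", "CDS", "five_prime_UTR", "three_prime_UTR",
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One GFF3-style feature; internal coordinates 0-based half-open."""

    seqid: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    attributes: tuple = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise InputError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"bad interval [{self.start},{self.end}) for {self.kind}")
        if self.strand not in "+-":
            raise InputError(f"bad strand {self.strand!r}")


_STATE_ORDER = {"canonical": 0, "retained": 1, "alt5": 2, "alt3": 3}


@total_ordering
@dataclass(frozen=True)
class SpliceState:
    """One splicing decision for one intron.

    ``offset`` is a signed shift of the affected boundary coordinate
    (donor for ``alt5``, acceptor for ``alt3``): positive offsets move the
    boundary downstream on the coding strand, so ``alt3`` with ``+6``
    lengthens the intron by six bases while ``alt5`` with ``+6`` shortens it.
    """

    kind: str
    offset: int = 0

    def __post_init__(self):
        if self.kind not in _STATE_ORDER:
            raise InputError(f"unknown splice state {self.kind!r}")
        if self.kind in ("canonical", "retained") and self.offset != 0:
            raise InputError(f"{self.kind} state cannot carry an offset")
        if self.kind in ("alt5", "alt3") and self.offset == 0:
            raise InputError(f"{self.kind} state needs a non-zero offset")

    def _key(self):
        return (_STATE_ORDER[self.kind], self.offset)

    def __lt__(self, other):
        return self._key() < other._key()

    def __str__(self):
        if self.kind in ("canonical", "retained"):
            return self.kind
        return f"{self.kind}({self.offset:+d})"


CANONICAL = SpliceState("canonical")
RETAINED = SpliceState("retained")


@dataclass(frozen=True)
class Intron:
    """A canonical intron on the coding strand of its gene region."""

    start: int
    end: int

    def __post_init__(self):
        if self.end - self.start < 4:
            raise InputError(
                f"intron [{self.start},{self.end}) too short for GT...AG")

    def __len__(self):
        return self.end - self.start

    def interval(self, state: SpliceState) -> tuple[int, int]:
        """Removed reference interval under a splicing state."""
        if state.kind == "canonical":
            return (self.start, self.end)
        if state.kind == "alt5":
            return (self.start + state.offset, self.end)
        if state.kind == "alt3":
            return (self.start, self.end + state.offset)
        raise InputError("retained introns remove nothing")


@dataclass
class GeneModel:
    """A gene region with its transcribed bounds and canonical introns.

    ``reference`` holds the full extracted region (flanks included) on the
    coding strand; minus-strand genes are reverse-complemented at load time.
    Exons and introns alternate and tile ``[tss, tes)``.
    """

    gene_id: str
    reference: SequenceRecord
    tss: int
    tes: int
    introns: list[Intron] = field(default_factory=list)
    strand: str = "+"

    def __post_init__(self):
        self.validate()

    @property
    def exons(self) -> list[tuple[int, int]]:
        out, pos = [], self.tss
        for iv in self.introns:
            out.append((pos, iv.start))
            pos = iv.end
        out.append((pos, self.tes))
        return out

    def donor_acceptor(self, intron: Intron) -> tuple[str, str]:
        seq = self.reference.residues
        return seq[intron.start:intron.start + 2], seq[intron.end - 2:intron.end]

    def validate(self) -> "GeneModel":
        if not (0 <= self.tss < self.tes <= len(self.reference)):
            raise InputError(
                f"{self.gene_id}: bounds [{self.tss},{self.tes}) outside region")
        if self.strand not in "+-":
            raise InputError(f"{self.gene_id}: bad strand {self.strand!r}")
        pos = self.tss
        for iv in self.introns:
            if iv.start < pos + 1 or iv.end > self.tes - 1:
                raise InputError(
                    f"{self.gene_id}: intron [{iv.start},{iv.end}) does not "
                    f"leave flanking exon sequence inside [{self.tss},{self.tes})")
            pos = iv.end
            donor, acceptor = self.donor_acceptor(iv)
            if donor != "GT" or acceptor != "AG":
                raise InputError(
                    f"{self.gene_id}: intron [{iv.start},{iv.end}) is "
                    f"{donor}...{acceptor}, not GT...AG")
        return self

    def transcript(self, states: Optional[Sequence[SpliceState]] = None) -> str:
        """Mature transcript under one per-intron state vector.

        ``None`` means all-canonical.  States apply left to right; the
        removed interval of each spliced intron is taken out of the
        pre-mRNA ``[tss, tes)``.
        """
        if states is None:
            states = [CANONICAL] * len(self.introns)
        if len(states) != len(self.introns):
            raise InputError(
                f"{self.gene_id}: state vector length {len(states)} != "
                f"intron count {len(self.introns)}")
        seq = self.reference.residues
        parts, pos = [], self.tss
        for intron, state in zip(self.introns, states):
            if state.kind == "retained":
                continue
            cut_start, cut_end = intron.interval(state)
            parts.append(seq[pos:cut_start])
            pos = cut_end
        parts.append(seq[pos:self.tes])
        return "".join(parts)

    def transcript_length(self, states: Optional[Sequence[SpliceState]] = None) -> int:
        return len(self.transcript(states))
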