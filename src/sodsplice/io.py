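"""Readers and writers for FASTA, FASTQ (Phred+33), GFF3, Newick and CSV.

All parsing of the standard formats is delegated to Biopython / dendropy /
pandas; this module enforces the pipeline's stricter conventions on top
(unique ids, uppercase residues, 0-based half-open internal coordinates
converted to 1-based inclusive GFF3 on disk, explicit intron features).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Union

import dendropy
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, InputError
from .models import GeneModel, Intron, ReadPair, SequenceRecord

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read FASTA into ordered records; residues are uppercased.

    Raises :class:`FormatError` on an empty file or duplicate ids.
    """
    records, seen = [], set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython-side failure
        raise FormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(
            id=rec.id,
            residues=str(rec.seq).upper(),
            description=rec.description[len(rec.id):].strip(),
        ))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33 only)

def _read_fastq_mates(path: PathLike) -> list[tuple[str, str, str]]:
    """One FASTQ file -> list of (id, residues, quality string)."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            out.append((rec.id, str(rec.seq).upper(),
                        "".join(chr(q + 33) for q in quals)))
    except ValueError as exc:
        # Biopython's message names the offending record.
        raise FormatError(f"{path}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no FASTQ records found")
    return out


def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def read_fastq(path1: PathLike, path2: PathLike | None = None) -> list[ReadPair]:
    """Read paired FASTQ, either two-file or interleaved.

    Qualities are decoded as Phred+33.  Two-file mode requires equal record
    counts and matching ids (after stripping ``/1``/``/2`` suffixes).
    """
    if path2 is not None:
        mates1 = _read_fastq_mates(path1)
        mates2 = _read_fastq_mates(path2)
        if len(mates1) != len(mates2):
            raise FormatError(
                f"pairing error: {path1} has {len(mates1)} records but "
                f"{path2} has {len(mates2)}")
        pairs = []
        for (id1, s1, q1), (id2, s2, q2) in zip(mates1, mates2):
            base1, base2 = _strip_mate_suffix(id1), _strip_mate_suffix(id2)
            if base1 != base2:
                raise FormatError(
                    f"pairing error: mate ids {id1!r} and {id2!r} disagree")
            pairs.append(ReadPair(base1, s1, q1, s2, q2))
        return pairs
    mates = _read_fastq_mates(path1)
    if len(mates) % 2:
        raise FormatError(
            f"{path1}: interleaved file has an odd record count ({len(mates)})")
    pairs = []
    for i in range(0, len(mates), 2):
        (id1, s1, q1), (id2, s2, q2) = mates[i], mates[i + 1]
        base1, base2 = _strip_mate_suffix(id1), _strip_mate_suffix(id2)
        if base1 != base2:
            raise FormatError(
                f"pairing error: adjacent ids {id1!r} and {id2!r} disagree")
        pairs.append(ReadPair(base1, s1, q1, s2, q2))
    return pairs


def write_fastq(pairs: Iterable[ReadPair], path1: PathLike, path2: PathLike | None = None) -> None:
    """Write pairs as two-file (or interleaved, if ``path2`` is None) FASTQ."""
    if path2 is None:
        with open(path1, "w") as fh:
            for p in pairs:
                fh.write(f"@{p.id}/1\n{p.mate1}\n+\n{p.qual1}\n")
                fh.write(f"@{p.id}/2\n{p.mate2}\n+\n{p.qual2}\n")
        return
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}/1\n{p.mate1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.id}/2\n{p.mate2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# GFF3

def _gff_line(seqid, source, kind, start, end, strand, attrs):
    # internal 0-based half-open -> 1-based inclusive
    attr_text = ";".join(f"{k}={v}" for k, v in attrs)
    return f"{seqid}\t{source}\t{kind}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_text}"


def write_gff3(model: GeneModel) -> str:
    """Serialize a gene model as GFF3 text with explicit intron features.

    Minus-strand models are stored internally on the coding strand; on
    output their coordinates are mirrored back to the plus strand of the
    region so that features ascend by start as GFF3 requires.
    """
    L = len(model.reference)

    def conv(start, end):
        if model.strand == "+":
            return start, end
        return L - end, L - start

    seqid, gid = model.reference.id, model.gene_id
    lines = ["##gff-version 3",
             f"##sequence-region {seqid} 1 {L}"]
    rows = [("gene", *conv(model.tss, model.tes), [("ID", gid)])]
    rows.append(("mRNA", *conv(model.tss, model.tes),
                 [("ID", f"{gid}.t1"), ("Parent", gid)]))
    for i, (s, e) in enumerate(model.exons, 1):
        rows.append(("exon", *conv(s, e),
                     [("ID", f"{gid}.exon{i}"), ("Parent", f"{gid}.t1")]))
    for i, iv in enumerate(model.introns, 1):
        rows.append(("intron", *conv(iv.start, iv.end),
                     [("ID", f"{gid}.intron{i}"), ("Parent", f"{gid}.t1")]))
    rows.sort(key=lambda r: (r[1], r[2]))
    for kind, s, e, attrs in rows:
        lines.append(_gff_line(seqid, "sodsplice", kind, s, e, model.strand, attrs))
    return "\n".join(lines) + "\n"


def read_gff3(text: str, reference: SequenceRecord) -> GeneModel:
    """Parse GFF3 text (the dialect written by :func:`write_gff3`) back into
    a :class:`GeneModel` over ``reference``.

    Minus-strand features are mirrored onto the coding strand and the
    reference is reverse-complemented, so downstream logic always sees the
    coding strand.
    """
    from .models import reverse_complement

    gene = None
    introns = []
    strand = "+"
    gene_id = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"GFF3 line has {len(cols)} columns: {line!r}")
        kind, start, end, strand_col = cols[2], int(cols[3]) - 1, int(cols[4]), cols[6]
        attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
        if kind == "gene":
            gene = (start, end)
            strand = strand_col
            gene_id = attrs.get("ID", "gene")
        elif kind == "intron":
            introns.append((start, end))
    if gene is None:
        raise FormatError("GFF3 text contains no gene feature")
    ref = reference
    L = len(ref)
    if strand == "-":
        ref = SequenceRecord(ref.id, reverse_complement(ref.residues),
                             ref.description)
        gene = (L - gene[1], L - gene[0])
        introns = [(L - e, L - s) for s, e in introns]
    introns.sort()
    return GeneModel(
        gene_id=gene_id, reference=ref, tss=gene[0], tes=gene[1],
        introns=[Intron(s, e) for s, e in introns], strand=strand)


# ---------------------------------------------------------------------------
# Newick (via dendropy)

def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree; internal-node labels carry bootstrap supports."""
    text = tree.as_string(schema="newick", suppress_rooting=True,
                          suppress_internal_node_labels=False).strip()
    return text + ("\n" if not text.endswith("\n") else "")


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")


# ---------------------------------------------------------------------------
# CSV (comma, header row, UTF-8)

CT_COLUMNS = ["sample", "condition", "gene", "replicate", "ct"]


def read_ct_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: Ct table lacks columns {missing}")
    if not pd.api.types.is_numeric_dtype(df["ct"]):
        raise FormatError(f"{path}: ct column is not numeric")
    return df[CT_COLUMNS]


def write_ct_table(df: pd.DataFrame, path: PathLike) -> None:
    df[CT_COLUMNS].to_csv(path, index=False)


def read_alignment_fasta(path: PathLike) -> list[SequenceRecord]:
    """Aligned FASTA: equal-length rows, gaps as '-'."""
    records = read_fasta(path)
    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise FormatError(f"{path}: aligned rows have unequal lengths {sorted(lengths)}")
    return records
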