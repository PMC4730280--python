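# Methods

This note documents the models, numerical choices and limitations behind
`sodsplice`. Conventions first: all in-memory coordinates are 0-based
half-open on the coding strand (minus-strand genes are
reverse-complemented at load time); GFF3 output is 1-based inclusive;
FASTQ qualities are Phred+33 only.

## Synthetic world

The package ships three fixture genes whose intron layouts reproduce the
published *V. volvacea* SOD gene structures:

| gene | introns (bp) | stated modes |
|---|---|---|
| Cu-Zn SOD | 52, 76, 80, 125, 57, 58, 54, 55 | retention I1/I4/I7/I8; alt-3′ I2; retention + alt-3′ I3 |
| Mn SOD 1 | 154, 57, 56 | retention + alt-5′ I1; retention I2 |
| Mn SOD 2 | 47, 72, 126, 119, 88, 61, 87 | retention I1/I3/I4/I5/I7 |

Alternative-site offsets are signed boundary shifts (positive =
downstream): the alt-3′ sites are `+6`, the Mn SOD 1 alt-5′ site is
`−9` (a Val codon supplies the shifted GT donor inside the coding
sequence). Each gene carries a 180-residue protein with the family's
conserved residues at their profile positions — Cu/Zn ligands,
disulfide cysteines and the glycosylation asparagine for the Cu-Zn
family; the four metal ligands H26/H74/D159/H163 for the Mn fold. The
exact Mn ligand numbering is shown only graphically in the source
figure, so the package adopts the classical mitochondrial MnSOD
positions and keeps them configurable.

Family members are 25%-diverged copies of one fixed exemplar per family;
the exemplar doubles as the domain-profile reference so that residue
positions carry across a local alignment. Decoy proteome sequences are
uniform over the 20 amino acids and rejection-sampled until they carry
no partial profile.

**Fixture construction guarantees.** Every intron (and every declared
alternative site) is GT…AG; the genomic region contains exactly one ATG;
no splice junction is shift-ambiguous within ±8 bp (the classic aligner
ambiguity, checked explicitly and re-drawn on failure); and for the
Cu-Zn gene the single ATG lies at the 3′ end of intron 4, its last codon
(GAG) doubling as the acceptor AG. Consequently transcripts splicing I4
out contain no start codon at all, and only I4-retaining transcripts can
translate the domain-complete enzyme — the mechanism the pipeline is
built to detect. Construction is a pure function of (specs, design,
seed): filler draws that violate a guarantee are redrawn
deterministically.

**Read simulator.** Fragments are Normal(300, 50) truncated to
[2·read length, 1000] — the mapper's 1–2000 bp pair-span rule is a
tolerance, not a library geometry. Mate 1 reads the fragment start
forward, mate 2 the end reverse-complemented; errors are substitutions
only; qualities are constant Q40; provenance (isoform, fragment start)
is recorded on every pair. Per-isoform fragment counts are
`coverage × proportion × length / (2 × read length)`. The default event
mixture is 70% canonical with the remainder split equally over
single-event variants; read length and depth were never published, so
75 bp / 30× are configuration defaults, not claims.

**Ct tables** invert the Livak statistic: target Ct =
baseline − log2(fold) + N(0, sd); the reference gene gets its own
baseline plus the same noise; replicate-resolved, one reference
measurement per sample.

## Mapper

Exact 20-mer seeds at 5-base steps from both mate ends propose
placements; a mate may split into ≤ 3 blocks across reference skips of
4–2000 bp. Split points require GT at the donor and AG before the
acceptor, ≥ 8 bp anchors, and minimise total substitutions (ties: the
leftmost donor). Transcriptome mode allows ≤ 2 substitutions per mate;
genome mode is contiguous and exact — the published procedure mapped
genome reads at zero tolerance, and its "40 bp" transcriptome figure is
treated as the junction overhang a junction-aware mapper models
explicitly. Equal-cost placements of the same shape are dropped
(multi-mapping yields no junction evidence); pairs must land within
1–2000 bp in FR or RF orientation. Transcription bounds are the extreme
covered coordinates; per-base verification counts aligned blocks only
and reports the minimum depth alongside the verified verdict
(minimum ≥ 1).

Known consequence of 20-mer anchoring: a junction-crossing mate with
< 20 bases beyond the junction cannot be anchored on the far side; such
pairs drop (or, rarely, align contiguously with ≤ 2 terminal
substitutions). Junction recovery is unaffected at the depths used
(power analysis below), but 30–50% of pairs from intron-dense genes go
unmapped; callers wanting higher yield should raise coverage rather
than loosen the seed length.

## Splice calling

Junctions are distinct GT-AG skips supported by ≥ 2 unique mates
(default). Against a canonical model, a junction equal to an intron
supports `canonical`; sharing the acceptor with a shifted donor is
`alt5(offset)`; sharing the donor, `alt3(offset)`; an intron is
`retained` when ≥ 2 contiguous reads cross each boundary by ≥ 8 bp.
States accumulate — an intron may be retained *and* alternatively
spliced. Junctions sharing neither end are reported as novel, never
classified. When no model is given, canonical introns are the
maximally-supported junction per overlap cluster (ties: shorter intron,
then leftmost donor).

**Power analysis behind the event-recovery checks** (fixed before the
tests were run): the rarest variant isoform carries 30%/7 ≈ 4.3% of
transcripts in the Cu-Zn mixture. A junction read needs ≥ 20 bases on
each side, i.e. 36 of 75 start positions; at 250× total depth the
expected unique support for the weakest alternative-site junction is
≈ 250 × 0.043 × 36/75 ≈ 5, giving P(support < 2) ≈ 0.04 per event at
the weakest class and ~2 expected misses across the 300 event-seed
trials of the 20-seed recovery test — comfortably above the 95%
recovery requirement. Retention evidence (contiguous crossings, 60/75
positions) is stronger still.

## Isoform enumeration

Transcripts are the full Cartesian product of per-intron state sets
(lexicographic state order; a configurable cap of 10⁶ guards the
product). The ORF rule is: longest ATG-initiated frame ending at an
in-frame stop, ≥ 50 codons (configurable; an ATG without a downstream
in-frame stop never qualifies), ties to the 5′-most start. Proteins are
grouped by identical string; "distinct proteins" can be filtered to
all-with-ORF, domain-any or domain-complete — the published counts of
"potential" isoform proteins are reproducible only against the deposited
GenBank records, which require network access and are deliberately out
of scope here. Note one fixture-specific behaviour: the 54-bp
frame-preserving intron 7 of the Cu-Zn gene can be retained without
introducing a stop, yielding a second, 18-residue-longer domain-complete
protein; the necessity of I4 retention is unaffected.

## Homology screen

Smith–Waterman with affine gaps costs a gap of length *g*
`open + g·ext` (defaults 11/1, BLOSUM62). The row recurrence exploits
`open ≥ ext` to collapse the horizontal gap state into a running
maximum, so each DP row is a few vectorised numpy operations; traceback
prefers diagonal, then vertical, then horizontal moves with the
shortest run, making the reported position map deterministic.
E-values use fixed Karlin–Altschul constants λ = 0.267, K = 0.041 (the
standard gapped BLOSUM62/11,1 values — the original analysis delegated
these to BLASTP and stated only the 10⁻² threshold). Domain verdicts:
complete (all required residues matched through the alignment), partial
(≥ half), absent. Family calls are by best-scoring reference, ties by
reference id; Fe vs Mn discrimination is by reference label only, as the
two families share a fold. With calibrated e-values, ~1% of random
decoys necessarily clear the threshold alone; the conserved-residue
confirmation is what reduces the candidate set to the true family
members, mirroring the published two-step screen.

## Phylogeny

Partial deletion removes columns below 70% site coverage globally
before any pairwise comparison (the option named in the source tree's
caption; a per-pair variant would differ). p-distance is the mismatch
fraction over sites where both sequences are ungapped; a pair with no
comparable sites is an error naming the pair. NJ uses the Q-criterion
with deterministic tie-breaking (smallest index pair), the standard
branch-length formulas, negative estimates clamped to zero and recorded
on the tree, and a trifurcating root for the final three clusters.
Bootstrap replicates resample columns with replacement, re-apply
partial deletion, and count bipartitions; replicates that degenerate
(a pair with no comparable sites) are skipped and supports are
percentages of completed replicates.

## Expression

ΔCt is computed per replicate (target − reference within the same
sample), ΔΔCt against the calibrator-condition mean, and the fold as
`2^(−mean ΔΔCt)` — which makes the calibrator's fold exactly 1 for any
noise realisation. Amplification efficiency is assumed exactly 2 (no
Pfaffl correction), matching the method cited by the study. Standard
errors are delta-method transforms: `SE(fold) = fold · ln2 · SE(ΔCt)`.
The LSD display runs a one-way ANOVA, requires non-degenerate pooled
variance, tests all pairs with the pooled error term, and assigns
letters by insert-and-absorb over groups sorted by descending mean —
this guarantees two groups share a letter iff their pairwise test is
non-significant. A note on check design: a single 4-replicate table at
Ct noise 0.05 leaves ~3.5% sampling error on a recovered fold, so the
package's own closed-loop test averages log-estimates over eight seeded
tables per gene to put three standard errors inside its 5% band; the
acceptance script reports the single-table estimate, whose error is
well inside the stochastic comparison tolerance.

## What a green test establishes — and what it does not

The generators emulate clean desk-scale data: uniform fragment starts,
substitution-only errors, constant quality, one gene per reference
region, transcript mixtures with known proportions. They do not emulate
indels, coverage bias, quality-dependent errors, multi-gene references,
intron-less pseudogenes or real codon usage; decoy proteomes are
uniform-composition, which *overstates* random alignment scores
relative to real proteomes. Green closed-loop tests therefore establish
the correctness of the algorithms on their stated world, not
performance on arbitrary real libraries. Published figure-level
quantities (bar heights, the 0.949/0.385/0.421/0.983/0.981
correlations, the deposited-isoform counts, the 35-taxon tree topology)
depend on unpublished replicate data or external downloads and are
intentionally not asserted anywhere in the suite.
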