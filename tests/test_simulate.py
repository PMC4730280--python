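"""Synthetic-data generators: fixture layouts, determinism, closed loops."""

import numpy as np
import pytest

from sodsplice import io as sio
from sodsplice import simulate as sim
from sodsplice.errors import ConfigurationError, InputError
from sodsplice.models import CANONICAL, RETAINED, GeneModel, SequenceRecord


PRINTED_LAYOUTS = {
    "Vv_CuZnsod1": [52, 76, 80, 125, 57, 58, 54, 55],
    "Vv_Mnsod1": [154, 57, 56],
    "Vv_Mnsod2": [47, 72, 126, 119, 88, 61, 87],
}


def test_fixture_intron_layouts(fixtures):
    for fx in fixtures:
        lengths = [len(iv) for iv in fx.model.introns]
        assert lengths == PRINTED_LAYOUTS[fx.gene_id]
        for iv in fx.model.introns:
            donor, acceptor = fx.model.donor_acceptor(iv)
            assert (donor, acceptor) == ("GT", "AG")


def test_fixture_state_space_sizes(fixtures):
    assert [len(fx.state_vectors()) for fx in fixtures] == [96, 6, 32]


def test_zero_intron_gene_equals_exons():
    ref = SequenceRecord("r", "CCAA" + "ATGGCCCATTAA" + "GGCC")
    model = GeneModel(gene_id="g", reference=ref, tss=4, tes=16, introns=[])
    assert model.transcript() == "ATGGCCCATTAA"
    assert model.exons == [(4, 16)]


def test_initiation_codon_inside_retainable_intron(cuzn):
    """The canonical transcript has no ATG at all; retaining I4 exposes the
    unique start codon of the domain-complete frame (exhaustive scan)."""
    model = cuzn.model
    assert "ATG" not in model.transcript()
    for states in cuzn.state_vectors():
        t = model.transcript(states)
        if states[3].kind == "retained":
            assert "ATG" in t
        else:
            assert "ATG" not in t
    # the genomic region carries exactly one ATG: the functional start
    region = model.reference.residues
    assert region.count("ATG") == 1
    assert region.index("ATG") == cuzn.start_codon


def test_fixture_gff3_fasta_round_trip(tmp_path, mn1):
    fasta = tmp_path / "gene.fasta"
    sio.write_fasta([mn1.model.reference], fasta)
    text = sio.write_gff3(mn1.model)
    ref = sio.read_fasta(fasta)[0]
    back = sio.read_gff3(text, ref)
    assert back.gene_id == mn1.model.gene_id
    assert (back.tss, back.tes) == (mn1.model.tss, mn1.model.tes)
    assert [(i.start, i.end) for i in back.introns] == \
        [(i.start, i.end) for i in mn1.model.introns]
    assert back.reference.residues == mn1.model.reference.residues


def test_exon_design_too_short_raises():
    protein = sim.design_family_protein("Mn", seed=1, length=180)
    with pytest.raises(ConfigurationError):
        sim.ExonDesign(gene_id="g", protein=protein, intron_sites=(10, 5))


# ---------------------------------------------------------------------------
# Read simulation

def test_read_count_tracks_coverage(mn1):
    cfg = sim.SimulationConfig(coverage=30, error_rate=0.0, seed=4)
    pairs = sim.simulate_read_pairs(mn1.model, sim.canonical_mixture(), cfg)
    L = mn1.model.transcript_length()
    expected_mates = 30 * L / 75
    assert abs(2 * len(pairs) - expected_mates) <= 0.1 * expected_mates


def test_error_free_mates_are_exact_substrings(mn2):
    from sodsplice.models import reverse_complement
    cfg = sim.SimulationConfig(coverage=10, error_rate=0.0, seed=5)
    pairs = sim.simulate_read_pairs(mn2.model, sim.canonical_mixture(), cfg)
    iso = mn2.model.transcript()
    for p in pairs:
        assert p.mate1 in iso
        assert reverse_complement(p.mate2) in iso
        assert p.origin is not None


def test_simulation_deterministic_fastq(tmp_path, mn1):
    cfg = sim.SimulationConfig(coverage=12, error_rate=0.01, seed=9)
    f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    for f in (f1, f2):
        pairs = sim.simulate_read_pairs(mn1.model, sim.event_mixture(mn1), cfg)
        sio.write_fastq(pairs, f)
    assert f1.read_bytes() == f2.read_bytes()


def test_mixture_must_sum_to_one(mn1):
    cfg = sim.SimulationConfig(seed=0)
    bad = {tuple([CANONICAL] * 3): 0.7}
    with pytest.raises(InputError, match="sum"):
        sim.simulate_read_pairs(mn1.model, bad, cfg)


# ---------------------------------------------------------------------------
# Ct tables

def test_ct_table_noise_free_fold_one_gives_flat_dct():
    d = sim.CtDesign(genes=("g1",), conditions=("a", "b", "c"), calibrator="a",
                     fold_changes=(), replicates=3, ct_sd=0.0, seed=0)
    tab = sim.generate_ct_table(d)
    dct = (tab[tab.gene == "g1"].set_index(["condition", "replicate"])["ct"]
           - tab[tab.gene == "gapdh"].set_index(["condition", "replicate"])["ct"])
    assert dct.nunique() == 1


def test_ct_table_noise_free_fold_four_is_two_cycles():
    d = sim.CtDesign(genes=("g1",), conditions=("control", "treated"),
                     calibrator="control",
                     fold_changes=(("g1", "treated", 4.0),),
                     replicates=3, ct_sd=0.0, seed=0)
    tab = sim.generate_ct_table(d)
    g = tab[tab.gene == "g1"].groupby("condition")["ct"].mean()
    assert g["control"] - g["treated"] == pytest.approx(2.0)  # log2(4)


def test_ct_design_invariants():
    with pytest.raises(ConfigurationError):
        sim.CtDesign(genes=("g",), conditions=("a",), calibrator="a",
                     fold_changes=(), replicates=2)
    with pytest.raises(ConfigurationError):
        sim.CtDesign(genes=("g",), conditions=("a", "b"), calibrator="a",
                     fold_changes=(("g", "b", -1.0),))


# ---------------------------------------------------------------------------
# Proteome generation

def test_proteome_same_seed_identical(profiles):
    a = sim.generate_proteome(20, profiles.values(), seed=11)
    b = sim.generate_proteome(20, profiles.values(), seed=11)
    assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]


def test_proteome_single_embedded_no_decoys(profiles):
    from sodsplice.screen import screen_proteome
    prof = profiles["CuZn"]
    prot = sim.generate_proteome(0, [prof], seed=3)
    assert len(prot) == 1
    hits = screen_proteome(prot, [(prof.reference, "CuZn")],
                           profiles={"CuZn": prof})
    assert len(hits) == 1 and hits[0].verdict == "complete"
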