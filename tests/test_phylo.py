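"""Distance phylogeny: partial deletion, NJ exactness, bootstrap."""

import dendropy
import numpy as np
import pytest

from sodsplice.errors import InputError
from sodsplice.models import SequenceRecord
from sodsplice.phylo import (DistanceMatrix, PhyloConfig, _bipartitions,
                             bipartition_support, bootstrap_support, nj_tree,
                             pdistance_partial_deletion)

AA = list("ARNDCQEGHILKMFPSTWYV")


def _leaf_lengths(tree):
    return {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}


# ---------------------------------------------------------------------------
# p-distance

def test_gapless_alignment_is_plain_pdistance():
    aln = [SequenceRecord("A", "ACGTAC"), SequenceRecord("B", "ACGTAA")]
    dm = pdistance_partial_deletion(aln)
    assert dm.get("A", "B") == pytest.approx(1 / 6)


def test_partial_deletion_worked_example():
    aln = [SequenceRecord("A", "ACGT"), SequenceRecord("B", "A-GT"),
           SequenceRecord("C", "A-GA")]
    dm = pdistance_partial_deletion(aln, PhyloConfig(site_coverage=0.7))
    # column 2 (coverage 1/3) removed; d(A,C) over A,G,T vs A,G,A = 1/3
    assert dm.get("A", "C") == pytest.approx(1 / 3)
    assert dm.get("A", "B") == pytest.approx(0.0)


def test_identical_sequences_zero_distance():
    aln = [SequenceRecord(x, "MKHACD") for x in "ABC"]
    dm = pdistance_partial_deletion(aln)
    assert np.allclose(dm.values, 0)


def test_no_comparable_sites_error_names_pair():
    aln = [SequenceRecord("A", "AC--"), SequenceRecord("B", "--GT"),
           SequenceRecord("C", "ACGT")]
    with pytest.raises(InputError, match="'A' and 'B'"):
        pdistance_partial_deletion(aln, PhyloConfig(site_coverage=0.5))


def test_distances_in_unit_interval():
    rng = np.random.default_rng(0)
    aln = [SequenceRecord(f"t{i}", "".join(rng.choice(AA, 50)))
           for i in range(5)]
    dm = pdistance_partial_deletion(aln)
    assert (dm.values >= 0).all() and (dm.values <= 1).all()
    assert np.allclose(dm.values, dm.values.T)


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_three_taxon_closed_form():
    dm = DistanceMatrix(("A", "B", "C"),
                        np.array([[0, .2, .4], [.2, 0, .4], [.4, .4, 0]]))
    lengths = _leaf_lengths(nj_tree(dm))
    assert lengths["A"] == pytest.approx(0.1)
    assert lengths["B"] == pytest.approx(0.1)
    assert lengths["C"] == pytest.approx(0.3)


def test_nj_four_taxon_additive():
    """Additive matrix from ((A:1,B:2):1,(C:3,D:4)): topology AB|CD with
    internal branch 1, leaf branches recovered exactly."""
    labs = ("A", "B", "C", "D")
    M = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
                 dtype=float)
    tree = nj_tree(DistanceMatrix(labs, M))
    assert _bipartitions(tree) == {frozenset({"C", "D"})}
    lengths = _leaf_lengths(tree)
    assert [lengths[x] for x in labs] == pytest.approx([1, 2, 3, 4])
    internal = [n for n in tree.preorder_node_iter()
                if n.parent_node is not None and not n.is_leaf()]
    assert len(internal) == 1
    assert internal[0].edge.length == pytest.approx(1.0)


def _random_additive_tree(rng, n_taxa):
    """Random binary tree with positive branch lengths via dendropy."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_taxa)])
    nodes = [dendropy.Node(taxon=t) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            child.edge.length = float(rng.uniform(0.1, 1.0))
            parent.add_child(child)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for child in nodes:
        child.edge.length = float(rng.uniform(0.1, 1.0))
        root.add_child(child)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _leaf_distance_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(t.label for t in tree.taxon_namespace))
    n = len(labels)
    M = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                ta = tree.taxon_namespace.get_taxon(a)
                tb = tree.taxon_namespace.get_taxon(b)
                M[i, j] = M[j, i] = pdm.patristic_distance(ta, tb)
    return DistanceMatrix(labels, M)


@pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
def test_nj_recovers_random_additive_trees(n_taxa):
    rng = np.random.default_rng(100 + n_taxa)
    for _ in range(5):
        truth = _random_additive_tree(rng, n_taxa)
        dm = _leaf_distance_matrix(truth)
        got = nj_tree(dm)
        assert _bipartitions(got) == _bipartitions(truth)
        # additivity: path distances on the NJ tree reproduce the input
        back = _leaf_distance_matrix(got)
        assert np.allclose(back.values, dm.values, atol=1e-9)


def test_nj_taxon_order_invariance():
    rng = np.random.default_rng(42)
    truth = _random_additive_tree(rng, 6)
    dm = _leaf_distance_matrix(truth)
    perm = rng.permutation(len(dm.labels))
    dm2 = DistanceMatrix(tuple(dm.labels[i] for i in perm),
                         dm.values[np.ix_(perm, perm)])
    t1, t2 = nj_tree(dm), nj_tree(dm2)
    assert _bipartitions(t1) == _bipartitions(t2)
    assert _leaf_lengths(t1) == pytest.approx(_leaf_lengths(t2))


def test_nj_agrees_with_skbio_on_noisy_matrix():
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj
    rng = np.random.default_rng(9)
    truth = _random_additive_tree(rng, 7)
    dm = _leaf_distance_matrix(truth)
    noisy = dm.values + rng.uniform(0, 0.02, dm.values.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    mine = nj_tree(DistanceMatrix(dm.labels, noisy))
    other = sknj(SkDM(noisy, ids=list(dm.labels)))
    skbio_bips = set()
    all_taxa = frozenset(dm.labels)
    anchor = min(all_taxa)
    for node in other.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_taxa) - 1:
            skbio_bips.add(all_taxa - side if anchor in side else side)
    assert _bipartitions(mine) == skbio_bips


def test_nj_rejects_asymmetric_input():
    bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(InputError):
        DistanceMatrix(("A", "B", "C"), bad)


# ---------------------------------------------------------------------------
# bootstrap

def _two_family_alignment(rng, per_family=4, n_cols=120, noise=0.05):
    recs = []
    for fam in ("famA", "famB"):
        prof = rng.choice(AA, n_cols)
        for i in range(per_family):
            s = prof.copy()
            for k in np.nonzero(rng.random(n_cols) < noise)[0]:
                s[k] = rng.choice(AA)
            recs.append(SequenceRecord(f"{fam}_{i}", "".join(s)))
    return recs


def test_bootstrap_single_replicate_binary():
    rng = np.random.default_rng(31)
    recs = _two_family_alignment(rng)
    tree = bootstrap_support(recs, PhyloConfig(bootstrap_replicates=1, seed=5))
    supports = [int(n.label) for n in tree.preorder_node_iter()
                if n.label is not None]
    assert supports and set(supports) <= {0, 100}


def test_bootstrap_deterministic_per_seed():
    rng = np.random.default_rng(33)
    recs = _two_family_alignment(rng)
    cfg = PhyloConfig(bootstrap_replicates=50, seed=11)
    t1 = bootstrap_support(recs, cfg)
    t2 = bootstrap_support(recs, cfg)
    lab = lambda t: sorted(n.label for n in t.preorder_node_iter()
                           if n.label is not None)
    assert lab(t1) == lab(t2)


def test_family_bipartitions_strongly_supported():
    """Two diverged family profiles separate with high support, the
    pattern behind the strongly supported Cu-Zn and Mn branches."""
    rng = np.random.default_rng(35)
    recs = _two_family_alignment(rng)
    tree = bootstrap_support(recs, PhyloConfig(bootstrap_replicates=200,
                                               seed=1))
    support = bipartition_support(tree, [f"famA_{i}" for i in range(4)])
    assert support is not None and support >= 95
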