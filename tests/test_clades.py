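"""LTR indel fingerprints, clade clustering, NJ trees, midpoint rooting."""

import itertools

import dendropy
import numpy as np
import pytest

from ervclock._seq import random_dna
from ervclock.clades import (LtrFingerprint, cluster_fingerprints,
                             fingerprint_indels, gap_blocks, nj_tree)
from ervclock.consensus import align


def _patristic(newick, ids):
    tns = dendropy.TaxonNamespace([str(i) for i in ids])
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=tns)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tns}
    return {(a, b): pdm.patristic_distance(taxa[a], taxa[b])
            for a, b in itertools.combinations(ids, 2)}, tree


def test_shared_deletion_gives_identical_fingerprints(rng):
    base = random_dna(rng, 300)
    carrier = base[:100] + base[112:]          # shared 12 nt deletion
    block = align([base, carrier, carrier, base],
                  ids=["w1", "d1", "d2", "w2"])
    fps = fingerprint_indels(block, min_indel_length=5)
    assert fps[1].vector == fps[2].vector != fps[0].vector
    clades = cluster_fingerprints(fps)
    assert clades["d1"] == clades["d2"] != clades["w1"]


def test_private_insertion_flagged_unique(rng):
    base = random_dna(rng, 300)
    ins = base[:150] + random_dna(rng, 8) + base[150:]
    block = align([base, base, ins], ids=["a", "b", "u"])
    fps = fingerprint_indels(block, min_indel_length=5)
    unique = next(fp for fp in fps if fp.ltr_id == "u")
    assert unique.unique_indels
    assert not next(fp for fp in fps if fp.ltr_id == "a").unique_indels


def test_gap_free_alignment_single_clade(rng):
    s = random_dna(rng, 200)
    block = align([s, s, s], ids=list("abc"))
    assert gap_blocks(block) == []
    fps = fingerprint_indels(block)
    assert all(fp.vector == () for fp in fps)
    assert len(set(cluster_fingerprints(fps).values())) == 1


def test_cluster_threshold_zero_groups_exact_vectors():
    fps = [LtrFingerprint("a", (1, 0)), LtrFingerprint("b", (1, 0)),
           LtrFingerprint("c", (0, 1)), LtrFingerprint("d", (1, 1))]
    clades = cluster_fingerprints(fps, jaccard_threshold=0.0)
    assert clades["a"] == clades["b"]
    assert len({clades["a"], clades["c"], clades["d"]}) == 3
    # positive threshold merges near-identical vectors
    merged = cluster_fingerprints(fps, jaccard_threshold=0.5)
    assert merged["a"] == merged["d"]


def test_clade_labels_permutation_invariant():
    fps1 = [LtrFingerprint("a", (1, 0)), LtrFingerprint("b", (0, 1)),
            LtrFingerprint("c", (1, 0))]
    fps2 = [LtrFingerprint(f.ltr_id, f.vector) for f in reversed(fps1)]
    c1 = cluster_fingerprints(fps1)
    c2 = cluster_fingerprints(fps2)
    assert c1 == c2


def test_nj_recovers_additive_tree_exactly():
    # tree ((A:2,B:3):1,(C:4,D:5)) -> pairwise path lengths
    D = np.array([[0, 5, 7, 8],
                  [5, 0, 8, 9],
                  [7, 8, 0, 9],
                  [8, 9, 9, 0]], float)
    nwk = nj_tree(D, list("ABCD"))
    dists, _ = _patristic(nwk, list("ABCD"))
    for (a, b), d in dists.items():
        i, j = "ABCD".index(a), "ABCD".index(b)
        assert d == pytest.approx(D[i, j], abs=1e-9)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    dists, _ = _patristic(nj_tree(D, list("XYZ")), list("XYZ"))
    assert dists[("X", "Y")] == pytest.approx(3)
    assert dists[("X", "Z")] == pytest.approx(4)
    assert dists[("Y", "Z")] == pytest.approx(5)


def test_midpoint_root_of_ultrametric_tree_is_ultrametric():
    D = np.array([[0, 2, 4, 4],
                  [2, 0, 4, 4],
                  [4, 4, 0, 3],
                  [4, 4, 3, 0]], float)
    _, tree = _patristic(nj_tree(D, list("ABCD")), list("ABCD"))
    depths = [leaf.distance_from_root()
              for leaf in tree.leaf_node_iter()]
    assert all(d == pytest.approx(2.0, abs=1e-9) for d in depths)


def test_nj_topology_matches_scikit_bio(rng):
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    for rep in range(3):
        pts = rng.random((7, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        ids = [f"t{i}" for i in range(7)]
        tns = dendropy.TaxonNamespace(ids)
        mine = dendropy.Tree.get(data=nj_tree(D, ids), schema="newick",
                                 taxon_namespace=tns)
        theirs = dendropy.Tree.get(data=str(skbio_nj(DistanceMatrix(D, ids))),
                                   schema="newick", taxon_namespace=tns)
        mine.encode_bipartitions()
        theirs.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            mine, theirs) == 0


def test_nj_separates_planted_clusters(rng):
    n = 8
    D = np.full((n, n), 1.0)
    for i in range(n):
        D[i, i] = 0.0
    for grp in (range(4), range(4, 8)):
        for i in grp:
            for j in grp:
                if i != j:
                    D[i, j] = 0.05
    ids = [f"x{i}" for i in range(n)]
    _, tree = _patristic(nj_tree(D, ids), ids)
    tree.encode_bipartitions()
    want = frozenset(f"x{i}" for i in range(4))
    splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in tree.edges() if e.head_node}
    assert want in splits or frozenset(ids) - want in splits


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])
    bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        nj_tree(bad, list("abc"))
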