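"""CpG masking, K2P distance, age estimation and summaries."""

import math

import numpy as np
import pytest

from ervclock._seq import random_dna
from ervclock.dating import (AgeEstimate, SkippedEstimate,
                             gene_consensus_age, k2p_distance, ltr_pair_age,
                             mask_cpg,
                             split_dating_subgroups, summarize_ages)
from ervclock.simulate import SimulationConfig, evolve_sequence


def k2p_counting_oracle(a, b, masked_cols=()):
    """Independent per-site counting + closed-form oracle."""
    ts = tv = n = 0
    purines = "AG"
    for i, (x, y) in enumerate(zip(a, b)):
        if i in masked_cols or x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)


def test_mask_cpg_union_examples():
    m = mask_cpg(["AACGTT", "AACGTT"], mode="union")
    assert list(np.where(m)[0]) == [2, 3]
    # union convention: CpG in the first row only still masks the column
    m = mask_cpg(["TACG", "TTTT"], mode="union")
    assert list(np.where(m)[0]) == [2, 3]
    m = mask_cpg(["ATTA", "ATTA"], mode="union")
    assert not m.any()


def test_mask_cpg_context_supersets_union(rng):
    for _ in range(20):
        s1, s2 = random_dna(rng, 80), random_dna(rng, 80)
        u = mask_cpg([s1, s2], mode="union")
        c = mask_cpg([s1, s2], mode="context")
        assert (c | u == c).all()


def test_mask_cpg_skips_gap_columns_for_adjacency():
    # degapped adjacency: C-gap-G is still a CpG context
    m = mask_cpg(["AC-GT", "AC-GT"], mode="union")
    assert list(np.where(m)[0]) == [1, 3]


def test_mask_cpg_validation():
    with pytest.raises(ValueError):
        mask_cpg([])
    with pytest.raises(ValueError):
        mask_cpg(["ACG", "AC"])
    with pytest.raises(ValueError):
        mask_cpg(["ACG"], mode="bogus")


def test_k2p_identical_sequences():
    d = k2p_distance("ACGTTT", "ACGTTT")
    assert (d.P, d.Q, d.D) == (0.0, 0.0, 0.0)


def test_k2p_closed_form_values():
    # P=0.1, Q=0.05 on a constructed 20-site pair: 2 transitions (A<->G),
    # 1 transversion (A<->C)
    a = "A" * 20
    b = "G" * 2 + "C" * 1 + "A" * 17
    d = k2p_distance(a, b)
    assert (d.P, d.Q) == (0.1, 0.05)
    assert d.D == pytest.approx(
        -0.5 * math.log(0.75) - 0.25 * math.log(0.9), abs=1e-12)
    assert d.D == pytest.approx(0.17018, abs=5e-6)
    # single G<->T transversion over 4 sites: P=0, Q=0.25
    d = k2p_distance("ACGT", "ACTT")
    assert (d.P, d.Q) == (0.0, 0.25)
    assert d.D == pytest.approx(
        -0.5 * math.log(0.75) - 0.25 * math.log(0.5), abs=1e-12)


def test_k2p_symmetry_and_gap_exclusion(rng):
    a, b = "AC-GTN", "ACTG-A"
    d1, d2 = k2p_distance(a, b), k2p_distance(b, a)
    assert (d1.P, d1.Q, d1.D, d1.n_sites) == (d2.P, d2.Q, d2.D, d2.n_sites)
    assert d1.n_gap_excluded == 3
    assert d1.n_sites == 3


def test_k2p_saturation_is_explicit():
    d = k2p_distance("AAAA", "GGGG")
    assert d.saturated and d.D is None
    with pytest.raises(ValueError):
        k2p_distance("A", "C", mask=np.array([True]))


def test_k2p_never_below_raw_divergence(rng):
    for _ in range(50):
        a = random_dna(rng, 300)
        b = "".join(c if rng.random() > 0.1 else "ACGT"[rng.integers(4)]
                    for c in a)
        d = k2p_distance(a, b)
        if not d.saturated:
            assert d.D >= d.P + d.Q - 1e-12


def test_ltr_pair_age_formula(rng):
    # identical LTRs -> age exactly 0
    ltr = random_dna(rng, 500)
    est = ltr_pair_age(ltr, ltr)
    assert isinstance(est, AgeEstimate) and est.T == 0.0
    # T = D / (2 M): doubling M halves T exactly
    cfg = SimulationConfig(cpg_multiplier=1.0)
    g = np.random.default_rng(4)
    l3 = evolve_sequence(ltr, 2.0, cfg, g)
    t1 = ltr_pair_age(ltr, l3, M=0.0022).T
    t2 = ltr_pair_age(ltr, l3, M=0.0044).T
    assert t1 == pytest.approx(2 * t2, rel=1e-12)
    # missing LTR -> skipped with reason
    skip = ltr_pair_age(None, ltr)
    assert isinstance(skip, SkippedEstimate) and "missing" in skip.reason


def test_gene_consensus_divisor_modes(rng):
    cfg = SimulationConfig(cpg_multiplier=1.0)
    gene = random_dna(rng, 1500)
    aged = evolve_sequence(gene, 2.0, cfg, np.random.default_rng(2))
    e1 = gene_consensus_age(aged, gene, "gag", divisor=1)
    e2 = gene_consensus_age(aged, gene, "gag", divisor=2)
    assert e1.T == pytest.approx(2 * e2.T, rel=1e-12)
    assert gene_consensus_age(gene, gene, "gag").T == 0.0
    with pytest.raises(ValueError):
        gene_consensus_age(gene, gene, "gag", divisor=3)


def test_split_dating_subgroups_recovers_planted_clusters(rng):
    cfg = SimulationConfig(cpg_multiplier=1.0)
    a, b = random_dna(rng, 800), random_dna(rng, 800)
    seqs, ids = [], []
    for i in range(4):
        seqs.append(evolve_sequence(a, 1.0, cfg, np.random.default_rng(i)))
        ids.append(f"a{i}")
    for i in range(4):
        seqs.append(evolve_sequence(b, 1.0, cfg,
                                    np.random.default_rng(10 + i)))
        ids.append(f"b{i}")
    labels = split_dating_subgroups(seqs, ids, distance_threshold=0.04)
    assert len(set(labels.values())) == 2
    assert len({labels[f"a{i}"] for i in range(4)}) == 1
    assert len({labels[f"b{i}"] for i in range(4)}) == 1
    # homogeneous set below the cut -> one cluster
    labels = split_dating_subgroups(seqs[:4], ids[:4],
                                    distance_threshold=0.04)
    assert set(labels.values()) == {1}


def test_summarize_ages_statistics():
    def est(t, sg="A", gene=None, method="ltr_pair"):
        return AgeEstimate(provirus_id="x", method=method, gene=gene,
                           distance=None, M=0.0022, divisor=2, T=t,
                           subgroup=sg)
    out = summarize_ages([est(1.0), est(2.0), est(3.0)])
    s = out[0]
    assert (s.n, s.mean_T, s.sd_T, s.median_T) == (3, 2.0, 1.0, 2.0)
    assert s.render() == "~ 2.00 (± 1.00)"
    single = summarize_ages([est(1.5)])[0]
    assert single.n == 1 and single.sd_T == 0.0
    # skipped estimates are not summarized
    assert summarize_ages([SkippedEstimate("x", "ltr_pair", "r")]) == []


def test_k2p_matches_oracle_on_random_aligned_pairs(rng):
    for _ in range(200):
        n = int(rng.integers(50, 400))
        a = random_dna(rng, n)
        b = "".join(c if rng.random() > 0.08 else "ACGT"[rng.integers(4)]
                    for c in a)
        mask = mask_cpg([a, b], mode="union")
        d = k2p_distance(a, b, mask)
        if d.saturated:
            continue
        masked_cols = set(np.where(mask)[0])
        assert d.D == pytest.approx(
            k2p_counting_oracle(a, b, masked_cols), abs=1e-12)
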