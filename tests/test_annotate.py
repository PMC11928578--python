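"""LTR pair detection, gene projection, motifs, ORFs, deletions, subgroups."""

import numpy as np
import pytest

from ervclock._seq import random_dna, revcomp, translate
from ervclock.annotate import (RefAnnotation, assess_orfs, assign_subgroup,
                               detect_deletions, detect_ltr_pair, map_genes,
                               scan_motifs)
from ervclock.align import global_align
from ervclock.simulate import (SimulationConfig, build_ancestral_provirus,
                               evolve_sequence)


@pytest.fixture(scope="module")
def reference():
    cfg = SimulationConfig(rng_seed=3)
    from ervclock.simulate import _family_reference
    return RefAnnotation(*_family_reference(cfg))


@pytest.fixture(scope="module")
def provirus_a():
    cfg = SimulationConfig(rng_seed=3)
    return build_ancestral_provirus(cfg, "A")


def _locus(rng, provirus, left=4000, right=4000, tsd=None, L=None):
    """Flank a provirus with host sequence and a TSD.

    When the LTR length ``L`` is given, the TSD is chosen so that the
    first base compared beyond each true repeat boundary mismatches: at
    age 0 a chance match just outside the boundary is indistinguishable
    from repeat, so exact-recovery checks must construct it away.
    """
    if tsd is None:
        d = len(provirus) - L
        # left extension compares the last TSD base with the last internal
        # base; right extension compares the first post-LTR base with the
        # first TSD base
        last_internal = provirus[d - 1]
        first_internal = provirus[L]
        t0 = "A" if first_internal != "A" else "C"
        t4 = "A" if last_internal != "A" else "C"
        tsd = t0 + "CGT"[:3] + t4
    return (random_dna(rng, left) + tsd + provirus + tsd
            + random_dna(rng, right)), tsd


def test_identical_repeats_recovered_exactly(rng, provirus_a):
    seq, feat = provirus_a
    L = feat["ltr5"][1]
    locus, tsd = _locus(rng, seq, L=L)
    pair = detect_ltr_pair(locus)
    assert pair.ltr5 == (4005, 4005 + L)
    assert pair.ltr3 == (4005 + len(seq) - L, 4005 + len(seq))
    assert pair.n_differences == 0
    assert pair.tsd == tsd


def test_detection_invariant_to_flank_size(rng, provirus_a):
    seq, feat = provirus_a
    L = feat["ltr5"][1]
    l1, _ = _locus(rng, seq, left=3000, right=9000, L=L)
    l2, _ = _locus(np.random.default_rng(1), seq, left=8000, right=2000,
                   L=L)
    p1, p2 = detect_ltr_pair(l1), detect_ltr_pair(l2)
    assert p1.ltr5[0] - 3005 == p2.ltr5[0] - 8005
    assert (p1.ltr5[1] - p1.ltr5[0]) == (p2.ltr5[1] - p2.ltr5[0])


def test_aged_provirus_boundaries_within_tolerance(rng):
    cfg = SimulationConfig(rng_seed=5, cpg_multiplier=1.0)
    seq, feat = build_ancestral_provirus(cfg, "A")
    L = feat["ltr5"][1]
    ltr = seq[:L]
    internal = seq[L:len(seq) - L]
    g = np.random.default_rng(8)
    aged = (evolve_sequence(ltr, 1.0, cfg, g)
            + evolve_sequence(internal, 1.0, cfg, g)
            + evolve_sequence(ltr, 1.0, cfg, g))
    locus, _ = _locus(rng, aged, L=L)
    pair = detect_ltr_pair(locus)
    assert abs(pair.ltr5[0] - 4005) <= 5
    assert abs(pair.ltr5[1] - (4005 + L)) <= 5
    assert abs(pair.ltr3[1] - (4005 + len(aged))) <= 5


def test_random_sequence_has_no_provirus(rng):
    assert detect_ltr_pair(random_dna(rng, 20_000)) is None


def test_short_locus_rejected():
    with pytest.raises(ValueError):
        detect_ltr_pair("ACGT" * 40)


def test_gene_projection_identity(reference):
    genes, aln = map_genes(reference.internal, reference)
    off = reference.internal_offset
    for gene in ("gag", "pro", "pol", "env"):
        a, b = reference.features[gene]
        assert genes[gene] == (a - off, b - off)
    assert aln.identity == 100.0


def test_env_deletion_shortens_projected_interval(reference):
    internal = reference.internal
    env_a, env_b = reference.features["env"]
    off = reference.internal_offset
    s, e = env_a - off + 400, env_a - off + 400 + 1487
    deleted = internal[:s] + internal[e:]
    genes, aln = map_genes(deleted, reference)
    ga, gb = genes["env"]
    assert (gb - ga) == (env_b - env_a) - 1487
    sigs = detect_deletions(aln, reference)
    assert [(x.gene, x.expected, x.observed) for x in sigs] == \
        [("env", 1487, 1487)]


def test_missing_gene_reported_absent(reference):
    internal = reference.internal
    a, b = reference.features["gag"]
    off = reference.internal_offset
    genes, _ = map_genes(internal[:a - off] + internal[b - off:], reference)
    assert genes["gag"] is None


def test_low_identity_flags_unmapped(reference, rng):
    genes, aln = map_genes(random_dna(rng, 5000), reference)
    assert all(v is None for v in genes.values())
    assert aln.identity < 50


def test_deletion_tolerance_window(reference):
    internal = reference.internal
    pol_a = reference.features["pol"][0] - reference.internal_offset
    s = pol_a + 2000
    deleted = internal[:s] + internal[s + 1480:]  # 7 nt short of 1487
    aln = global_align(reference.internal, deleted,
                       open_gap=-12, extend=-0.5)
    sigs = detect_deletions(aln, reference,
                            expected_specs=((1487, "pol"),), tolerance=10)
    assert sigs[0].expected == 1487 and sigs[0].observed == 1480
    # outside tolerance -> "other"
    sigs = detect_deletions(aln, reference,
                            expected_specs=((1487, "pol"),), tolerance=5)
    assert sigs[0].expected is None


def test_ungapped_gene_yields_no_signature(reference):
    aln = global_align(reference.internal, reference.internal)
    assert detect_deletions(aln, reference) == []


def test_motif_states_and_variant_detection(reference, provirus_a):
    seq, feat = provirus_a
    genes = {g: feat[g] for g in ("gag", "pro", "pol", "env")}
    rep = scan_motifs(genes, seq, reference)
    assert rep.gag_late_domain_1 == "PRPPIY"
    assert rep.gag_late_domain_2 == "PPPY"
    assert rep.env_cettg == "CETTG"
    # single-residue CETTG change -> altered
    env_a = feat["env"][0]
    pos = env_a + 3 * 300          # CETTG planted at codon 300
    mutated = seq[:pos + 9] + ("C" if seq[pos + 9] != "C" else "T") \
        + seq[pos + 10:]
    rep = scan_motifs(genes, mutated, reference)
    assert rep.env_cettg == "altered"
    assert "CETAG" not in translate(mutated[feat["env"][0]:feat["env"][1]])


def test_orf_assessment_detects_planted_stop(reference, provirus_a):
    seq, feat = provirus_a
    genes = {g: feat[g] for g in ("gag", "pro", "pol", "env")}
    rep = assess_orfs(genes, seq, reference)
    assert all(rep.status[g] == "full_length" for g in genes)
    gag_a = feat["gag"][0]
    planted = seq[:gag_a + 360] + "TAA" + seq[gag_a + 363:]
    rep = assess_orfs(genes, planted, reference)
    assert rep.status["gag"] == "premature_stop"
    assert 120 in rep.stop_positions["gag"]


def test_truncated_gene_is_partial(reference):
    internal = reference.internal
    pol_a = reference.features["pol"][0] - reference.internal_offset
    s = pol_a + 600
    deleted = internal[:s] + internal[s + 2216:]
    genes, _ = map_genes(deleted, reference)
    rep = assess_orfs(genes, deleted, reference)
    assert rep.status["pol"] in ("partial", "premature_stop")
    assert rep.longest_orf["pol"] < reference.gene_length("pol") // 3


def test_subgroup_assignment_rules():
    cfg = SimulationConfig(rng_seed=3)
    cons = {g: build_ancestral_provirus(cfg, g)[0] for g in "ABC"}
    b = cons["B"]
    assert assign_subgroup(b, cons, env_deletion_present=True) == "B1"
    assert assign_subgroup(b, cons, env_deletion_present=False) == "B2"
    assert assign_subgroup(cons["A"], cons, False) == "A"
    # a sequence unrelated to every consensus stays unassigned
    junk = random_dna(np.random.default_rng(0), len(b))
    assert assign_subgroup(junk, cons, False) == "unassigned"
    with pytest.raises(ValueError):
        assign_subgroup(b, {}, False)


def test_reverse_complement_is_not_a_direct_repeat(rng, provirus_a):
    """An inverted copy must not be mistaken for an LTR pair."""
    seq, feat = provirus_a
    L = feat["ltr5"][1]
    ltr = seq[:L]
    locus = (random_dna(rng, 5000) + ltr + random_dna(rng, 6000)
             + revcomp(ltr) + random_dna(rng, 5000))
    assert detect_ltr_pair(locus) is None
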