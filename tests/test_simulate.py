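"""Simulator: ancestral structure, substitution process, planting, truth."""

import numpy as np
import pytest

from ervclock._seq import translate
from ervclock.simulate import (SimulationConfig, build_ancestral_provirus,
                               evolve_sequence, read_truth_tsv,
                               simulate_insertions, simulate_ltr_pairs,
                               write_truth_tsv)


@pytest.mark.parametrize("subgroup,late1,late2", [
    ("A", "PRPPIY", "PPPY"),
    ("B1", "PQPPVL", "TPPY"),
    ("B2", "PQPPVL", "TPPY"),
    ("C", "PQPPVL", "TPPY"),
])
def test_ancestral_provirus_motifs_and_ltr_identity(subgroup, late1, late2):
    cfg = SimulationConfig(rng_seed=3)
    seq, feat = build_ancestral_provirus(cfg, subgroup)
    gag = translate(seq[slice(*feat["gag"])])
    env = translate(seq[slice(*feat["env"])])
    assert late1 in gag and late2 in gag
    assert "CETTG" in env
    # LTRs identical at formation
    assert seq[slice(*feat["ltr5"])] == seq[slice(*feat["ltr3"])]
    # genes are intact ORFs: start codon, terminal stop, no internal stop
    for gene in ("gag", "pro", "pol", "env"):
        g = seq[slice(*feat[gene])]
        assert g.startswith("ATG")
        assert "*" not in translate(g)[:-1]


def test_unknown_subgroup_rejected():
    with pytest.raises(ValueError):
        build_ancestral_provirus(SimulationConfig(), "Z")


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(rate_M=0)
    with pytest.raises(ValueError):
        SimulationConfig(cpg_multiplier=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(ltr_length=50)
    with pytest.raises(ValueError):
        SimulationConfig(n_per_subgroup={"A": -1})


def test_evolve_zero_age_identity(rng):
    cfg = SimulationConfig()
    seq = "ACGTTGCA" * 50
    assert evolve_sequence(seq, 0.0, cfg, rng) == seq


def test_evolve_substitution_only_and_expected_rate():
    """Observed per-site difference matches the K80 expectation M*age
    (within Monte-Carlo error; back-mutation correction < 0.3% here)."""
    cfg = SimulationConfig(cpg_multiplier=1.0)
    base = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[base.integers(0, 4, 10_000)])
    n_diff = 0
    reps = 30
    for i in range(reps):
        out = evolve_sequence(seq, 2.0, cfg, np.random.default_rng(i))
        assert len(out) == len(seq)
        n_diff += sum(a != b for a, b in zip(seq, out))
    total = reps * len(seq)
    p = n_diff / total
    # exact K80 probability of observing a difference after M*t = 0.0044
    mt = cfg.rate_M * 2.0
    p_exp = 1 - (0.25 + 0.25 * np.exp(-mt) + 0.5 * np.exp(-1.5 * mt))
    se = np.sqrt(p_exp * (1 - p_exp) / total)
    assert abs(p - p_exp) < 4 * se


def test_evolve_kappa_biases_transitions():
    """With kappa=2, the single transition target receives ~2x the events
    of each single transversion target."""
    cfg = SimulationConfig(cpg_multiplier=1.0, kappa=2.0)
    seq = "A" * 120_000
    out = evolve_sequence(seq, 2.0, cfg, np.random.default_rng(7))
    counts = {b: 0 for b in "CGT"}
    for a, b in zip(seq, out):
        if a != b:
            counts[b] += 1
    ts = counts["G"]                      # A->G transition
    tv_each = (counts["C"] + counts["T"]) / 2
    assert ts / tv_each == pytest.approx(2.0, rel=0.35)


def test_cpg_multiplier_elevates_cpg_substitutions():
    cfg = SimulationConfig(cpg_multiplier=10.0)
    seq = "TACGTTTA" * 2000               # CpG at a fixed phase
    out = evolve_sequence(seq, 3.0, cfg, np.random.default_rng(1))
    cpg_set = set()
    for i in range(len(seq) - 1):
        if seq[i:i + 2] == "CG":
            cpg_set.update((i, i + 1))
    diff_cpg = sum(seq[i] != out[i] for i in cpg_set)
    other = [i for i in range(len(seq)) if i not in cpg_set]
    diff_other = sum(seq[i] != out[i] for i in other)
    rate_cpg = diff_cpg / len(cpg_set)
    rate_other = diff_other / len(other)
    assert rate_cpg > 3 * rate_other


def test_simulation_reproducible_and_length_conserved(small_sim):
    cfg = small_sim.config
    again = simulate_insertions(SimulationConfig(
        rng_seed=cfg.rng_seed, host_length=cfg.host_length,
        min_spacing=cfg.min_spacing,
        n_per_subgroup=dict(cfg.n_per_subgroup)))
    assert again.genome == small_sim.genome
    planted = sum(t.end - t.start + len(t.tsd) for t in small_sim.truth)
    assert len(small_sim.genome["chr1"]) == cfg.host_length + planted


def test_truth_intervals_slice_to_planted_ltrs(small_sim):
    g = small_sim.genome["chr1"]
    for t in small_sim.truth:
        ltr5 = g[t.start:t.start + t.ltr_length]
        ltr3 = g[t.end - t.ltr_length:t.end]
        # both ends of the interval are LTR copies of equal length whose
        # divergence is bounded by the planted age: expected pair
        # divergence is 2*age*M per site, inflated ~2.1x by the 10-fold
        # CpG multiplier acting on ~1/8 of sites; allow 5 sigma
        n_diff = sum(a != b for a, b in zip(ltr5, ltr3))
        assert len(ltr5) == len(ltr3) == t.ltr_length
        lam = 2 * t.true_age * 0.0022 * 2.2 * t.ltr_length
        assert n_diff <= lam + 5 * np.sqrt(lam) + 3
        # TSD flanks the provirus on both sides
        assert g[t.start - len(t.tsd):t.start] == t.tsd
        assert g[t.end:t.end + len(t.tsd)] == t.tsd


def test_zero_age_proviruses_have_identical_ltrs():
    cfg = SimulationConfig(rng_seed=2, host_length=300_000,
                           min_spacing=25_000,
                           age_distribution=("fixed", 0.0),
                           n_per_subgroup={"A": 3, "C": 2})
    res = simulate_insertions(cfg)
    g = res.genome["chr1"]
    assert len(res.truth) == 5
    for t in res.truth:
        assert g[t.start:t.start + t.ltr_length] == \
            g[t.end - t.ltr_length:t.end]


def test_ltr_divergence_monotone_in_age():
    cfg = SimulationConfig(cpg_multiplier=1.0)
    means = []
    for age in (0.0, 1.0, 3.0, 6.0):
        pairs = simulate_ltr_pairs(cfg, 30, age, seed=5)
        diffs = [sum(a != b for a, b in zip(x, y)) for x, y in pairs]
        means.append(np.mean(diffs))
    assert means == sorted(means)


def test_truth_tsv_round_trip(small_sim, tmp_path):
    path = tmp_path / "truth.tsv"
    write_truth_tsv(small_sim.truth, path)
    back = read_truth_tsv(path)
    assert len(back) == len(small_sim.truth)
    for a, b in zip(back, small_sim.truth):
        assert a == b


def test_host_capacity_error():
    cfg = SimulationConfig(rng_seed=0, host_length=100_000,
                           min_spacing=25_000,
                           n_per_subgroup={"A": 10})
    with pytest.raises(ValueError, match="cannot place"):
        simulate_insertions(cfg)
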