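"""End-to-end orchestration: simulate/mine -> annotate -> consensus ->
date -> LTR clades -> report, with a run manifest for reproducibility.

Every stage is a thin composition of the library modules; the pipeline adds
logging, record counting, deterministic output files, and a manifest with
input/output digests so identical configurations can be verified to
reproduce identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (ProvirusCall, RefAnnotation, annotate_locus,
                       assign_subgroup, env_deletion_present,
                       ltr_pair_for_dating)
from .clades import cluster_fingerprints, fingerprint_indels, nj_tree
from .consensus import align, flag_outliers, majority_consensus
from .dating import (DEFAULT_RATE_M, AgeEstimate, estimates_dataframe,
                     gene_consensus_age, k2p_distance, ltr_pair_age,
                     mask_cpg, split_dating_subgroups, summarize_ages)
from .features import GENES
from .io import (calls_report_rows, load_reference, read_fasta, sha256_paths,
                 write_calls_gff3, write_fasta, write_reference_gff3)
from .mining import extract_loci, import_tabular_hits, seed_search
from .simulate import SimulationConfig, simulate_insertions, write_truth_tsv

log = logging.getLogger("ervclock")


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""


@dataclass
class PipelineConfig:
    out_dir: str = "ervclock_out"
    # inputs: either a simulation config, or paths to real data
    simulation: SimulationConfig | None = None
    genome_fasta: str | None = None
    seeds_fasta: str | None = None
    reference_fasta: str | None = None
    reference_gff: str | None = None
    hits_tsv: str | None = None
    # stage parameters
    flank: int = 10_000
    min_hit_identity: float = 85.0
    min_hit_length: int = 100
    word_size: int = 16
    min_ltr_length: int = 100
    ltr_min_identity: float = 80.0
    deletion_tolerance: int = 10
    group_identity_floor: float = 70.0
    outlier_identity: float = 60.0
    rate_M: float = DEFAULT_RATE_M
    gene_divisor: int = 1
    cpg_mask: bool = True
    split_threshold: float | None = None
    min_indel_length: int = 3
    jaccard_threshold: float = 0.0
    aligner_cmd: str | None = None


@dataclass
class RunManifest:
    version: str
    config: dict
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    rng_seeds: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
            fh.write("\n")


@dataclass
class PipelineResult:
    manifest: RunManifest
    calls: list = field(default_factory=list)
    loci: list = field(default_factory=list)
    consensuses: dict = field(default_factory=dict)
    estimates: list = field(default_factory=list)
    summaries: list = field(default_factory=list)
    clades: dict = field(default_factory=dict)      # group -> {ltr_id: clade}
    tree_newick: str | None = None
    truth: list = field(default_factory=list)
    out_dir: Path | None = None


def _stage(manifest: RunManifest, name: str, count: int) -> None:
    manifest.counts[name] = count
    manifest.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")
    log.info("stage %s: %d records", name, count)


def provirus_sequence(call: ProvirusCall, locus_seq: str) -> str:
    return locus_seq[call.provirus[0]:call.provirus[1]]


def ltr_sequences(call: ProvirusCall, locus_seq: str) -> tuple[str, str]:
    return (locus_seq[slice(*call.ltr5)], locus_seq[slice(*call.ltr3)])


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config=dataclasses.asdict(cfg))
    result = PipelineResult(manifest=manifest, out_dir=out)

    # ---- inputs -----------------------------------------------------------
    if cfg.simulation is not None:
        sim = simulate_insertions(cfg.simulation)
        genome = sim.genome
        seeds = {g: s for g, (s, _) in sim.ancestors.items()}
        reference = RefAnnotation(*sim.reference)
        result.truth = sim.truth
        write_fasta(genome, out / "genome.fasta")
        write_fasta(seeds, out / "seeds.fasta")
        write_fasta({"reference": reference.seq}, out / "reference.fasta")
        write_reference_gff3(reference.features, "reference",
                             out / "reference.gff3")
        write_truth_tsv(sim.truth, out / "truth.tsv")
        manifest.rng_seeds["simulation"] = cfg.simulation.rng_seed
        _stage(manifest, "simulate", len(sim.truth))
    else:
        for what, path in (("genome", cfg.genome_fasta),
                           ("seeds", cfg.seeds_fasta),
                           ("reference FASTA", cfg.reference_fasta),
                           ("reference GFF3", cfg.reference_gff)):
            if path is None or not Path(path).exists():
                raise PipelineError(f"annotate: missing {what} input"
                                    if "reference" in what
                                    else f"mine: missing {what} input")
        genome = read_fasta(cfg.genome_fasta)
        seeds = read_fasta(cfg.seeds_fasta)
        reference = load_reference(cfg.reference_fasta, cfg.reference_gff)
        manifest.input_digests = sha256_paths(
            [cfg.genome_fasta, cfg.seeds_fasta, cfg.reference_fasta,
             cfg.reference_gff])

    # ---- mine -------------------------------------------------------------
    try:
        if cfg.hits_tsv:
            hits = import_tabular_hits(cfg.hits_tsv)
        else:
            hits = seed_search(genome, seeds,
                               min_identity=cfg.min_hit_identity,
                               min_length=cfg.min_hit_length,
                               word_size=cfg.word_size)
        loci = extract_loci(hits, genome, flank=cfg.flank)
    except Exception as exc:
        raise PipelineError(f"mine: {exc}") from exc
    result.loci = loci
    _stage(manifest, "mine", len(loci))

    # ---- annotate ---------------------------------------------------------
    calls = []
    locus_seqs = {}
    for i, locus in enumerate(loci):
        locus_id = f"locus_{i:04d}"
        call = annotate_locus(
            locus.sequence, reference, locus_id=locus_id,
            contig=locus.contig, locus_start=locus.start,
            strand=locus.strand, min_ltr_length=cfg.min_ltr_length,
            ltr_min_identity=cfg.ltr_min_identity,
            deletion_tolerance=cfg.deletion_tolerance)
        if call is None:
            log.info("locus %s: no provirus", locus_id)
            continue
        locus_seqs[locus_id] = locus.sequence
        calls.append(call)
    result.calls = calls
    _stage(manifest, "annotate", len(calls))

    # ---- grouping + consensus --------------------------------------------
    # bootstrap major groups by nearest seed, then per-group consensus
    for call in calls:
        pv = provirus_sequence(call, locus_seqs[call.locus_id])
        call.subgroup = assign_subgroup(
            pv, seeds, env_deletion_present(call),
            identity_floor=cfg.group_identity_floor)
    # one consensus per subgroup (A / B1 / B2 / C): mixing B1 and B2 in a
    # single group-B consensus would let the majority env deletion into the
    # consensus and distort nearest-consensus assignment for the other half
    group_members: dict[str, list] = {}
    for call in calls:
        if call.subgroup != "unassigned":
            group_members.setdefault(call.subgroup, []).append(call)
    consensuses = {}
    for group, members in sorted(group_members.items()):
        seqs = [provirus_sequence(c, locus_seqs[c.locus_id])
                for c in members]
        if len(seqs) == 1:
            consensuses[group] = seqs[0]
            continue
        block = align(seqs, ids=[c.locus_id for c in members],
                      aligner_cmd=cfg.aligner_cmd)
        if len(seqs) >= 3:
            excluded = flag_outliers(block, cfg.outlier_identity)
            if excluded:
                keep = [i for i, c in enumerate(members)
                        if c.locus_id not in excluded]
                block = block.subset(keep)
                log.info("group %s: excluded outliers %s", group, excluded)
        consensuses[group] = majority_consensus(block).sequence
    result.consensuses = consensuses
    # final assignment against the group consensuses
    for call in calls:
        pv = provirus_sequence(call, locus_seqs[call.locus_id])
        call.subgroup = assign_subgroup(
            pv, consensuses, env_deletion_present(call),
            identity_floor=cfg.group_identity_floor)
    write_fasta(consensuses,
                out / "consensus.fasta")
    _stage(manifest, "consensus", len(consensuses))

    # ---- dating -----------------------------------------------------------
    estimates = []
    for call in calls:
        l5, l3 = ltr_pair_for_dating(locus_seqs[call.locus_id],
                                     call.ltr5, call.ltr3)
        estimates.append(ltr_pair_age(l5, l3, M=cfg.rate_M,
                                      provirus_id=call.locus_id,
                                      cpg_mask=cfg.cpg_mask,
                                      subgroup=call.subgroup))
    # gene ages against per-subgroup gene consensuses
    by_subgroup: dict[str, list] = {}
    for call in calls:
        if call.subgroup != "unassigned":
            by_subgroup.setdefault(call.subgroup, []).append(call)
    for subgroup, members in sorted(by_subgroup.items()):
        for gene in GENES:
            have = [(c, locus_seqs[c.locus_id][slice(*c.genes[gene])])
                    for c in members if c.genes.get(gene)]
            if len(have) < 2:
                continue
            if cfg.split_threshold is not None:
                labels = split_dating_subgroups(
                    [s for _, s in have], [c.locus_id for c, _ in have],
                    distance_threshold=cfg.split_threshold,
                    cpg_mask=cfg.cpg_mask)
                clusters: dict[int, list] = {}
                for c, seq in have:
                    clusters.setdefault(labels[c.locus_id], []).append(
                        (c, seq))
            else:
                clusters = {1: have}
            for members_c in clusters.values():
                if len(members_c) < 2:
                    log.info("gene %s/%s: singleton dating cluster "
                             "skipped (%s)", subgroup, gene,
                             members_c[0][0].locus_id)
                    continue
                block = align([s for _, s in members_c],
                              ids=[c.locus_id for c, _ in members_c],
                              aligner_cmd=cfg.aligner_cmd)
                cons = majority_consensus(block).sequence
                for c, seq in members_c:
                    estimates.append(gene_consensus_age(
                        seq, cons, gene, M=cfg.rate_M,
                        divisor=cfg.gene_divisor, provirus_id=c.locus_id,
                        cpg_mask=cfg.cpg_mask, subgroup=subgroup))
    result.estimates = estimates
    result.summaries = summarize_ages(estimates)
    estimates_dataframe(estimates).to_csv(out / "ages.tsv", sep="\t",
                                          index=False)
    pd.DataFrame([{"subgroup": s.subgroup, "method": s.method,
                   "gene": s.gene or "", "n": s.n,
                   "mean_T": s.mean_T, "sd_T": s.sd_T,
                   "median_T": s.median_T, "rendered": s.render()}
                  for s in result.summaries]).to_csv(
        out / "age_summary.tsv", sep="\t", index=False)
    _stage(manifest, "date",
           sum(isinstance(e, AgeEstimate) for e in estimates))

    # ---- LTR clades -------------------------------------------------------
    ltr_records = []          # (ltr_id, group, sequence)
    for call in calls:
        if call.subgroup == "unassigned":
            continue
        l5, l3 = ltr_sequences(call, locus_seqs[call.locus_id])
        group = call.subgroup[0]
        ltr_records.append((f"{call.locus_id}.5ltr", group, l5))
        ltr_records.append((f"{call.locus_id}.3ltr", group, l3))
    clades = {}
    for group in sorted({g for _, g, _ in ltr_records}):
        grp = [(i, s) for i, g, s in ltr_records if g == group]
        if len(grp) < 2:
            clades[group] = {grp[0][0]: "clade_1"} if grp else {}
            continue
        block = align([s for _, s in grp], ids=[i for i, _ in grp],
                      aligner_cmd=cfg.aligner_cmd)
        fps = fingerprint_indels(block, cfg.min_indel_length)
        clades[group] = cluster_fingerprints(fps, cfg.jaccard_threshold)
    result.clades = clades
    if len(ltr_records) >= 3:
        ids = [i for i, _, _ in ltr_records]
        block = align([s for _, _, s in ltr_records], ids=ids,
                      aligner_cmd=cfg.aligner_cmd)
        mask = mask_cpg(block.rows) if cfg.cpg_mask else None
        n = len(ids)
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = k2p_distance(block.rows[i], block.rows[j], mask)
                dm[i, j] = dm[j, i] = 3.0 if d.saturated else d.D
        result.tree_newick = nj_tree(dm, ids)
        (out / "ltr_tree.nwk").write_text(result.tree_newick + "\n")
    clade_rows = [{"ltr_id": lid, "group": grp, "clade": lab}
                  for grp, mapping in sorted(clades.items())
                  for lid, lab in sorted(mapping.items())]
    pd.DataFrame(clade_rows).to_csv(out / "ltr_clades.tsv", sep="\t",
                                    index=False)
    _stage(manifest, "ltr_clades",
           sum(len(m) for m in clades.values()))

    # ---- outputs ----------------------------------------------------------
    pd.DataFrame(calls_report_rows(calls)).to_csv(
        out / "proviruses.tsv", sep="\t", index=False)
    write_calls_gff3(calls, out / "proviruses.gff3")
    report = render_report(result)
    (out / "report.txt").write_text(report)
    manifest.output_digests = sha256_paths(sorted(out.glob("*")))
    manifest.write(out / "manifest.json")
    return result


def render_report(result: PipelineResult) -> str:
    """Plain-text run report: counts, feature tallies, age grid, clades."""
    lines = [f"ervclock report (v{result.manifest.version})", "=" * 40, ""]
    calls = result.calls
    by_sg: dict[str, list] = {}
    for c in calls:
        by_sg.setdefault(c.subgroup, []).append(c)
    lines.append("Provirus counts per subgroup")
    for sg in sorted(by_sg):
        lines.append(f"  {sg:<12} {len(by_sg[sg])}")
    lines.append(f"  {'total':<12} {len(calls)}")
    lines.append("")

    lines.append("Motif states (late domain 1 / late domain 2 / CETTG)")
    for sg in sorted(by_sg):
        tally: dict[str, int] = {}
        for c in by_sg[sg]:
            key = (f"{c.motifs.gag_late_domain_1}/"
                   f"{c.motifs.gag_late_domain_2}/{c.motifs.env_cettg}")
            tally[key] = tally.get(key, 0) + 1
        for key in sorted(tally):
            lines.append(f"  {sg:<6} {key:<28} {tally[key]}")
    lines.append("")

    lines.append("ORF status (full-length gene count / proviruses)")
    for sg in sorted(by_sg):
        n = len(by_sg[sg])
        for gene in GENES:
            full = sum(c.orfs.status.get(gene) == "full_length"
                       for c in by_sg[sg])
            lines.append(f"  {sg:<6} {gene:<5} {full}/{n}")
    lines.append("")

    if result.summaries:
        lines.append("Age estimates, Myr (mean ± sample SD)")
        header = f"  {'subgroup':<10} {'LTR pair':<18}"
        for gene in GENES:
            header += f"{gene:<18}"
        lines.append(header)
        subgroups = sorted({s.subgroup for s in result.summaries})
        for sg in subgroups:
            row = f"  {sg:<10} "
            ltr = next((s for s in result.summaries
                        if s.subgroup == sg and s.method == "ltr_pair"),
                       None)
            row += f"{ltr.render() if ltr else '-':<18}"
            for gene in GENES:
                gs = next((s for s in result.summaries
                           if s.subgroup == sg and s.gene == gene), None)
                row += f"{gs.render() if gs else '-':<18}"
            lines.append(row)
    else:
        lines.append("Age estimates: not run")
    lines.append("")

    if result.clades:
        lines.append("LTR clades per major group")
        for group, mapping in sorted(result.clades.items()):
            n_clades = len(set(mapping.values()))
            lines.append(f"  {group:<6} {n_clades} clade(s), "
                         f"{len(mapping)} LTRs")
    else:
        lines.append("LTR clades: not run")
    lines.append("")
    return "\n".join(lines)
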