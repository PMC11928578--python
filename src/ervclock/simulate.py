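"""Synthetic germline-colonization genomes with known provirus ages.

Generates host genomes carrying planted gammaretroviral proviruses of
structure 5'LTR - gag - pro - pol - env - 3'LTR, flanked by target-site
duplications.  Each provirus has a known insertion age: both LTRs start
identical at formation and then accumulate substitutions independently under
a Kimura-style two-parameter process (transition/transversion ratio kappa)
at a per-site rate M, with CpG sites hypermutable by a configurable factor.
Subgroup-diagnostic features — large deletions, LTR indel combinations,
late-domain motif variants, premature stop codons — are planted per
configuration, and every planted fact is recorded in a machine-readable
truth table so downstream annotation and dating can be scored against known
truth.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import (AA_TO_CODONS, STOP_CODONS, TRANSITION, TRANSVERSIONS,
                   encode_aa, from_int_array, random_dna, to_int_array)
from .features import GENES, MOTIF_AA_OFFSET, classify_motifs

SUBGROUPS = ("A", "B1", "B2", "C")

# internal-region layout (lengths in nt); genes are in-frame ORFs
GENE_LENGTHS = {"gag": 1578, "pro": 381, "pol": 3597, "env": 1965}
PBS_LEN = 18
LEADER_LEN = 120
SPACER_LEN = 30
UTR3_LEN = 80
PPT = "AAAAGGGGGGAAGGG"  # polypurine tract

# gene-relative nt start of each diagnostic deletion window
DELETION_WINDOWS = {("pol", 133): 2000, ("pol", 2216): 600, ("env", 1487): 400}

# codon-index range for planted premature stops (clear of motifs & deletions)
STOP_CODON_RANGE = (50, 116)


@dataclass(frozen=True)
class LtrIndel:
    """One menu entry: an indel at a fixed LTR offset, shared by carriers."""
    offset: int
    length: int
    kind: str  # "insertion" | "deletion"

    @property
    def seq(self) -> str:
        # insertion content is a pure function of (offset, length) so every
        # carrier plants the same bases and carriers align to each other
        rng = np.random.default_rng(self.offset * 10007 + self.length)
        return random_dna(rng, self.length)


@dataclass(frozen=True)
class DeletionSpec:
    subgroup: str
    gene: str
    length: int
    probability: float


def _default_deletion_specs() -> list[DeletionSpec]:
    return [
        DeletionSpec("B1", "env", 1487, 1.0),      # defines B1 vs B2
        DeletionSpec("B1", "pol", 133, 131 / 183),
        DeletionSpec("B2", "pol", 2216, 21 / 158),
    ]


def _default_ltr_indel_menu() -> list[LtrIndel]:
    return [
        LtrIndel(60, 12, "deletion"),    # 0
        LtrIndel(150, 8, "insertion"),   # 1
        LtrIndel(230, 21, "deletion"),   # 2
        LtrIndel(320, 6, "deletion"),    # 3
        LtrIndel(410, 15, "insertion"),  # 4
    ]


def _default_ltr_combos() -> dict:
    # two LTR-indel combinations in group A, five across group B, one in C
    return {
        "A": [((), 0.5), ((0,), 0.5)],
        "B1": [((1,), 0.5), ((1, 2), 0.5)],
        "B2": [((3,), 0.4), ((4,), 0.3), ((2, 4), 0.3)],
        "C": [((), 1.0)],
    }


@dataclass
class SimulationConfig:
    rng_seed: int = 0
    host_length: int = 2_000_000
    n_per_subgroup: dict = field(
        default_factory=lambda: {"A": 13, "B1": 20, "B2": 14, "C": 3})
    rate_M: float = 0.0022          # substitutions / nt / Myr
    cpg_multiplier: float = 10.0    # fold rate increase at CpG sites
    kappa: float = 2.0              # transition/transversion rate ratio
    age_distribution: tuple = ("uniform", 0.0, 7.0)   # Myr
    ltr_length: int = 500
    tsd_length_range: tuple = (4, 6)
    min_spacing: int = 25_000       # between insertion sites
    deletion_specs: list = field(default_factory=_default_deletion_specs)
    ltr_indel_menu: list = field(default_factory=_default_ltr_indel_menu)
    ltr_combos: dict = field(default_factory=_default_ltr_combos)
    ltr_combo_assignment: str = "random"   # "random" | "cycle"
    stop_codon_probability: dict = field(
        default_factory=lambda: {"gag": 0.05, "pro": 0.02,
                                 "pol": 0.05, "env": 0.05})
    # motif planting: group-A ancestor keeps PRPPIY, groups B/C carry PQPPVL
    late1_by_group: dict = field(
        default_factory=lambda: {"A": "PRPPIY", "B": "PQPPVL", "C": "PQPPVL"})
    pppy_probability: dict = field(
        default_factory=lambda: {"A": 1.0, "B1": 35 / 183,
                                 "B2": 111 / 158, "C": 0.0})
    cettg_intact_probability: dict = field(
        default_factory=lambda: {"A": 75 / 86, "B1": 1.0, "B2": 1.0, "C": 1.0})
    subgroup_divergence_myr: float = 12.5  # branch family ancestor -> subgroup
    contig_name: str = "chr1"

    def __post_init__(self):
        if self.rate_M <= 0:
            raise ValueError("rate_M must be > 0")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.ltr_length < 100:
            raise ValueError("ltr_length must be >= 100")
        if any(n < 0 for n in self.n_per_subgroup.values()):
            raise ValueError("subgroup counts must be >= 0")
        for sg in self.n_per_subgroup:
            if sg not in SUBGROUPS:
                raise ValueError(f"unknown subgroup {sg!r}")
        for spec in self.deletion_specs:
            if (spec.gene, spec.length) not in DELETION_WINDOWS:
                raise ValueError(
                    f"no planting window for deletion {spec.gene}/{spec.length}")

    def draw_age(self, rng: np.random.Generator) -> float:
        kind = self.age_distribution[0]
        if kind == "uniform":
            lo, hi = self.age_distribution[1], self.age_distribution[2]
            return float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        if kind == "fixed":
            return float(self.age_distribution[1])
        raise ValueError(f"unknown age distribution {kind!r}")


# ---------------------------------------------------------------------------
# substitution process

def _cpg_sites(s: np.ndarray) -> np.ndarray:
    """Boolean mask: site participates in a CpG dinucleotide (C=1, G=2)."""
    cpg = (s[:-1] == 1) & (s[1:] == 2)
    mask = np.zeros(s.shape, dtype=bool)
    mask[:-1] |= cpg
    mask[1:] |= cpg
    return mask


def evolve_sequence(seq: str, age: float, config: SimulationConfig,
                    rng: np.random.Generator) -> str:
    """Evolve ``seq`` for ``age`` Myr under the two-parameter jump process.

    Per-site substitution rate is rate_M, multiplied by cpg_multiplier while
    the site sits in a CpG dinucleotide (context re-evaluated after every
    substitution).  Given a substitution, the transition is kappa times as
    likely as each of the two transversions.  Substitutions only: the
    returned sequence has the same length.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    if age == 0 or not seq:
        return seq
    s = to_int_array(seq)
    if (s < 0).any():
        raise ValueError("sequence must be over A/C/G/T")
    n = len(s)
    M, mult, kappa = config.rate_M, config.cpg_multiplier, config.kappa
    rates = np.where(_cpg_sites(s), M * mult, M)
    p_transition = kappa / (kappa + 2.0)
    t = 0.0
    while True:
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        if t > age:
            break
        i = int(np.searchsorted(np.cumsum(rates), rng.random() * total,
                                side="right"))
        i = min(i, n - 1)
        base = s[i]
        if rng.random() < p_transition:
            s[i] = TRANSITION[base]
        else:
            s[i] = TRANSVERSIONS[base][int(rng.integers(0, 2))]
        lo, hi = max(0, i - 1), min(n, i + 2)
        sub = s[max(0, lo - 1):min(n, hi + 1)]
        local = np.where(_cpg_sites(sub), M * mult, M)
        off = max(0, lo - 1)
        rates[lo:hi] = local[lo - off:hi - off]
    return from_int_array(s)


# ---------------------------------------------------------------------------
# ancestral provirus construction

def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))


_SENSE_CODONS = sorted(set(
    c for cods in AA_TO_CODONS.values() for c in cods) - STOP_CODONS)


def _random_orf(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = length_nt // 3
    body = [_SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
            for _ in range(n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _plant_aa(gene_seq: str, codon_offset: int, aa_motif: str,
              rng: np.random.Generator | None = None) -> str:
    nt = encode_aa(aa_motif, rng)
    i = 3 * codon_offset
    return gene_seq[:i] + nt + gene_seq[i + len(nt):]


def _repair_orf(gene_seq: str, rng: np.random.Generator) -> str:
    """Restore start/terminal codons and scrub internal stops after evolution."""
    seq = "ATG" + gene_seq[3:-3] + "TAA"
    out = []
    n = len(seq) // 3
    for i in range(n):
        codon = seq[3 * i:3 * i + 3]
        if 0 < i < n - 1 and codon in STOP_CODONS:
            codon = _SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))]
        out.append(codon)
    return "".join(out)


def _internal_layout() -> list[tuple[str, int]]:
    return [("pbs", PBS_LEN), ("leader", LEADER_LEN),
            ("gag", GENE_LENGTHS["gag"]), ("spacer1", SPACER_LEN),
            ("pro", GENE_LENGTHS["pro"]), ("spacer2", SPACER_LEN),
            ("pol", GENE_LENGTHS["pol"]), ("spacer3", SPACER_LEN),
            ("env", GENE_LENGTHS["env"]), ("utr3", UTR3_LEN),
            ("ppt", len(PPT))]


def _family_ancestor(config: SimulationConfig) -> tuple[str, str]:
    """(ltr, internal) of the family ancestor, with intact A-type motifs."""
    rng = _rng(config.rng_seed, 1)
    ltr = random_dna(rng, config.ltr_length)
    parts = {}
    for name, length in _internal_layout():
        if name in GENES:
            parts[name] = _random_orf(rng, length)
        elif name == "ppt":
            parts[name] = PPT
        else:
            parts[name] = random_dna(rng, length)
    parts["gag"] = _plant_aa(parts["gag"], MOTIF_AA_OFFSET["late1"], "PRPPIY")
    parts["gag"] = _plant_aa(parts["gag"], MOTIF_AA_OFFSET["late2"], "PPPY")
    parts["env"] = _plant_aa(parts["env"], MOTIF_AA_OFFSET["cettg"], "CETTG")
    internal = "".join(parts[name] for name, _ in _internal_layout())
    return ltr, internal


def _internal_offsets() -> dict:
    offsets, pos = {}, 0
    for name, length in _internal_layout():
        offsets[name] = (pos, pos + length)
        pos += length
    return offsets


def group_of(subgroup: str) -> str:
    """Major group of a subgroup label (B1/B2 -> B)."""
    return subgroup[0]


def build_ancestral_provirus(config: SimulationConfig,
                             subgroup: str) -> tuple[str, dict]:
    """Full-length ancestral provirus and feature map for a subgroup.

    The 5' and 3' LTRs are identical (a provirus at formation), all four
    genes are intact in-frame ORFs, and the group's canonical late-domain /
    CETTG motif forms are planted.  Deterministic in (config.rng_seed,
    subgroup).
    """
    if subgroup not in SUBGROUPS and subgroup not in ("B",):
        raise ValueError(f"unknown subgroup {subgroup!r}")
    group = group_of(subgroup)
    ltr, internal = _family_ancestor(config)
    div = config.subgroup_divergence_myr
    rng = _rng(config.rng_seed, 2, "ABC".index(group))
    if div > 0:
        ltr = evolve_sequence(ltr, div, config, rng)
        internal = evolve_sequence(internal, div, config, rng)
    offsets = _internal_offsets()
    pieces = {name: internal[a:b] for name, (a, b) in offsets.items()}
    for gene in GENES:
        pieces[gene] = _repair_orf(pieces[gene], rng)
    late1 = config.late1_by_group[group]
    late2 = "PPPY" if group == "A" else "TPPY"
    pieces["gag"] = _plant_aa(pieces["gag"], MOTIF_AA_OFFSET["late1"], late1)
    pieces["gag"] = _plant_aa(pieces["gag"], MOTIF_AA_OFFSET["late2"], late2)
    pieces["env"] = _plant_aa(pieces["env"], MOTIF_AA_OFFSET["cettg"], "CETTG")
    internal = "".join(pieces[name] for name, _ in _internal_layout())
    seq = ltr + internal + ltr
    L = len(ltr)
    features = {"ltr5": (0, L)}
    for name, (a, b) in offsets.items():
        features[name] = (a + L, b + L)
    features["ltr3"] = (len(seq) - L, len(seq))
    return seq, features


# ---------------------------------------------------------------------------
# planting

@dataclass
class TruthRecord:
    provirus_id: str
    subgroup: str
    contig: str
    start: int
    end: int
    strand: str
    true_age: float
    tsd: str
    ltr_length: int
    planted_deletions: list          # [(gene, length)]
    planted_ltr_indels: list         # menu indices
    planted_stops: list              # [(gene, codon index)]
    motif_states: dict               # motif -> state (scanned post-planting)
    genes: dict                      # gene -> (start, end), provirus-relative


@dataclass
class PlantedProvirus:
    provirus_id: str
    subgroup: str
    true_age: float
    seq: str
    features: dict                   # name -> (start, end) provirus coords
    ltr_length: int
    planted_deletions: list
    planted_ltr_indels: list
    planted_stops: list
    motif_states: dict


def _apply_ltr_indels(ltr: str, combo: tuple, menu: list[LtrIndel]) -> str:
    for idx in sorted(combo, key=lambda i: -menu[i].offset):
        v = menu[idx]
        if v.kind == "deletion":
            ltr = ltr[:v.offset] + ltr[v.offset + v.length:]
        elif v.kind == "insertion":
            ltr = ltr[:v.offset] + v.seq + ltr[v.offset:]
        else:
            raise ValueError(f"unknown indel kind {v.kind!r}")
    return ltr


def _shift_pos(pos: int, deletions: list[tuple[int, int]]) -> int:
    """Map a pre-deletion coordinate through a set of deletions (s, e)."""
    out = pos
    for s, e in deletions:
        if pos >= e:
            out -= e - s
        elif pos > s:
            out -= pos - s
    return out


def _draw_combo(config: SimulationConfig, subgroup: str,
                rng: np.random.Generator, index: int) -> tuple:
    combos = config.ltr_combos.get(subgroup, [((), 1.0)])
    if config.ltr_combo_assignment == "cycle":
        return tuple(combos[index % len(combos)][0])
    probs = np.array([p for _, p in combos], dtype=float)
    probs = probs / probs.sum()
    k = int(rng.choice(len(combos), p=probs))
    return tuple(combos[k][0])


def _plant_one(config: SimulationConfig, subgroup: str, index: int,
               ancestors: dict, rng: np.random.Generator) -> PlantedProvirus:
    group = group_of(subgroup)
    anc_seq, anc_features = ancestors[group]
    anc_ltr = anc_seq[:anc_features["ltr5"][1]]
    anc_internal = anc_seq[anc_features["ltr5"][1]:anc_features["ltr3"][0]]
    age = config.draw_age(rng)

    combo = _draw_combo(config, subgroup, rng, index)
    formation_ltr = _apply_ltr_indels(anc_ltr, combo, config.ltr_indel_menu)

    # per-provirus motif draws, planted before evolution
    offsets = _internal_offsets()
    internal = anc_internal
    gag_a, _ = offsets["gag"]
    env_a, _ = offsets["env"]
    late2 = ("PPPY" if rng.random() < config.pppy_probability[subgroup]
             else "TPPY")
    internal = (internal[:gag_a]
                + _plant_aa(internal[gag_a:offsets["gag"][1]],
                            MOTIF_AA_OFFSET["late2"], late2)
                + internal[offsets["gag"][1]:])
    if rng.random() >= config.cettg_intact_probability[subgroup]:
        internal = (internal[:env_a]
                    + _plant_aa(internal[env_a:offsets["env"][1]],
                                MOTIF_AA_OFFSET["cettg"], "CETAG")
                    + internal[offsets["env"][1]:])

    ltr5 = evolve_sequence(formation_ltr, age, config, rng)
    ltr3 = evolve_sequence(formation_ltr, age, config, rng)
    internal = evolve_sequence(internal, age, config, rng)

    # diagnostic deletions (exact planted lengths, fixed gene windows)
    deletions: list[tuple[int, int]] = []
    planted_deletions: list[tuple[str, int]] = []
    for spec in config.deletion_specs:
        if spec.subgroup != subgroup:
            continue
        if rng.random() < spec.probability:
            win = DELETION_WINDOWS[(spec.gene, spec.length)]
            start = offsets[spec.gene][0] + win
            deletions.append((start, start + spec.length))
            planted_deletions.append((spec.gene, spec.length))
    for s, e in sorted(deletions, key=lambda d: -d[0]):
        internal = internal[:s] + internal[e:]
    feat = {name: (_shift_pos(a, deletions), _shift_pos(b, deletions))
            for name, (a, b) in offsets.items()}

    # premature stop codons, planted upstream of motif/deletion windows
    planted_stops: list[tuple[str, int]] = []
    for gene in GENES:
        p = config.stop_codon_probability.get(gene, 0.0)
        if rng.random() < p:
            idx = int(rng.integers(*STOP_CODON_RANGE))
            pos = feat[gene][0] + 3 * idx
            internal = internal[:pos] + "TAA" + internal[pos + 3:]
            planted_stops.append((gene, idx))

    seq = ltr5 + internal + ltr3
    L = len(formation_ltr)
    features = {"ltr5": (0, L)}
    for name, (a, b) in feat.items():
        features[name] = (a + L, b + L)
    features["ltr3"] = (len(seq) - L, len(seq))

    gag_seq = seq[slice(*features["gag"])]
    env_seq = seq[slice(*features["env"])]
    motifs = classify_motifs(gag_seq, env_seq, GENE_LENGTHS["env"])
    motif_states = {"gag_late_domain_1": motifs.gag_late_domain_1,
                    "gag_late_domain_2": motifs.gag_late_domain_2,
                    "env_cettg": motifs.env_cettg}
    return PlantedProvirus(
        provirus_id=f"{subgroup}_{index:03d}", subgroup=subgroup,
        true_age=age, seq=seq, features=features, ltr_length=L,
        planted_deletions=planted_deletions,
        planted_ltr_indels=sorted(combo),
        planted_stops=planted_stops, motif_states=motif_states)


def simulate_proviruses(config: SimulationConfig) -> list[PlantedProvirus]:
    """Planted proviruses (no host genome), reproducible from rng_seed."""
    ancestors = {g: build_ancestral_provirus(config, g) for g in
                 sorted({group_of(sg) for sg, n in
                         config.n_per_subgroup.items() if n > 0})}
    out = []
    for sg in SUBGROUPS:
        n = config.n_per_subgroup.get(sg, 0)
        for i in range(n):
            rng = _rng(config.rng_seed, 3, SUBGROUPS.index(sg), i)
            out.append(_plant_one(config, sg, i, ancestors, rng))
    return out


@dataclass
class SimulationResult:
    genome: dict                     # contig -> sequence
    truth: list                      # list[TruthRecord]
    ancestors: dict                  # group -> (seq, features)
    reference: tuple                 # (family seq, features) for annotation
    config: SimulationConfig


def simulate_insertions(config: SimulationConfig) -> SimulationResult:
    """Plant proviruses into a random host genome with TSDs.

    The host background has uniform base composition.  Insertion sites are
    spaced at least ~min_spacing apart so every provirus lands in its own
    extraction locus at the default flank size.  Genome length equals
    host_length plus the planted provirus and TSD lengths exactly.
    """
    proviruses = simulate_proviruses(config)
    n = len(proviruses)
    rng = _rng(config.rng_seed, 4)
    host = random_dna(rng, config.host_length)

    n_slots = config.host_length // config.min_spacing
    if n > n_slots:
        raise ValueError(
            f"cannot place {n} proviruses in a {config.host_length} bp host "
            f"at min_spacing {config.min_spacing}")
    jitter = max(1, config.min_spacing // 8)
    slots = np.sort(rng.choice(n_slots, size=n, replace=False))
    positions = [int(s) * config.min_spacing + int(rng.integers(0, jitter))
                 for s in slots]

    lo, hi = config.tsd_length_range
    tsd_lens = [int(rng.integers(lo, hi + 1)) for _ in range(n)]

    order = rng.permutation(n)  # which provirus goes to which site
    parts, truth = [], []
    prev = 0
    offset = 0
    contig = config.contig_name
    for site_i, pos in enumerate(positions):
        pv = proviruses[int(order[site_i])]
        tl = tsd_lens[site_i]
        tsd = host[pos:pos + tl]
        parts.append(host[prev:pos + tl])
        parts.append(pv.seq)
        start = pos + tl + offset
        truth.append(TruthRecord(
            provirus_id=pv.provirus_id, subgroup=pv.subgroup, contig=contig,
            start=start, end=start + len(pv.seq), strand="+",
            true_age=pv.true_age, tsd=tsd, ltr_length=pv.ltr_length,
            planted_deletions=pv.planted_deletions,
            planted_ltr_indels=pv.planted_ltr_indels,
            planted_stops=pv.planted_stops, motif_states=pv.motif_states,
            genes={g: pv.features[g] for g in GENES}))
        offset += len(pv.seq) + tl
        prev = pos
    parts.append(host[prev:])
    genome = {contig: "".join(parts)}
    truth.sort(key=lambda t: t.start)

    groups = sorted({group_of(sg) for sg, cnt in
                     config.n_per_subgroup.items() if cnt > 0})
    ancestors = {g: build_ancestral_provirus(config, g) for g in groups}
    reference = _family_reference(config)
    return SimulationResult(genome=genome, truth=truth, ancestors=ancestors,
                            reference=reference, config=config)


def _family_reference(config: SimulationConfig) -> tuple[str, dict]:
    """Family-ancestor sequence + feature map: the annotation reference."""
    ltr, internal = _family_ancestor(config)
    seq = ltr + internal + ltr
    L = len(ltr)
    features = {"ltr5": (0, L)}
    for name, (a, b) in _internal_offsets().items():
        features[name] = (a + L, b + L)
    features["ltr3"] = (len(seq) - L, len(seq))
    return seq, features


def simulate_ltr_pairs(config: SimulationConfig, n: int, age: float,
                       seed: int | None = None) -> list[tuple[str, str]]:
    """n independent proviral LTR pairs evolved for ``age`` Myr.

    Each replicate forms a fresh random LTR of config.ltr_length and evolves
    two copies independently — the minimal model of a provirus insertion
    observed ``age`` Myr later.
    """
    base = config.rng_seed if seed is None else seed
    pairs = []
    for i in range(n):
        rng = _rng(base, 5, i)
        ltr = random_dna(rng, config.ltr_length)
        pairs.append((evolve_sequence(ltr, age, config, rng),
                      evolve_sequence(ltr, age, config, rng)))
    return pairs


# ---------------------------------------------------------------------------
# serialization

TRUTH_COLUMNS = ["provirus_id", "subgroup", "contig", "start", "end",
                 "strand", "true_age", "tsd", "ltr_length",
                 "planted_deletions", "planted_ltr_indels", "planted_stops",
                 "motif_states", "genes"]


def write_truth_tsv(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open, on the emitted "
                 "genome FASTA\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            row = [t.provirus_id, t.subgroup, t.contig, str(t.start),
                   str(t.end), t.strand, repr(t.true_age), t.tsd,
                   str(t.ltr_length), json.dumps(t.planted_deletions),
                   json.dumps(t.planted_ltr_indels),
                   json.dumps(t.planted_stops), json.dumps(t.motif_states),
                   json.dumps(t.genes)]
            fh.write("\t".join(row) + "\n")


def read_truth_tsv(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        rows = [ln.rstrip("\n") for ln in fh
                if ln.strip() and not ln.startswith("#")]
    for ln in rows[1:]:
        f = ln.split("\t")
        out.append(TruthRecord(
            provirus_id=f[0], subgroup=f[1], contig=f[2], start=int(f[3]),
            end=int(f[4]), strand=f[5], true_age=float(f[6]), tsd=f[7],
            ltr_length=int(f[8]),
            planted_deletions=[tuple(x) for x in json.loads(f[9])],
            planted_ltr_indels=json.loads(f[10]),
            planted_stops=[tuple(x) for x in json.loads(f[11])],
            motif_states=json.loads(f[12]),
            genes={k: tuple(v) for k, v in json.loads(f[13]).items()}))
    return out


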