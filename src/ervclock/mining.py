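"""Seed-similarity screening of a genome and flank extraction.

Finds loci similar to seed retroviral sequences with a k-mer anchored,
diagonal-run search whose operative contract is the percent-identity and
length screen, or imports precomputed hits from 12-column tabular
(BLAST outfmt-6-compatible) files produced by any external search tool.  Positive hits are expanded by a flank (default 10,000 bp) on both
sides, clamped to contig bounds, and overlapping loci are merged so a
multi-hit provirus yields a single extraction.

Coordinates are 0-based half-open genome coordinates throughout; tabular
import converts from 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp

DEFAULT_FLANK = 10_000
DEFAULT_MIN_IDENTITY = 85.0
DEFAULT_MIN_LENGTH = 100
DEFAULT_WORD_SIZE = 16

# a k-mer run is broken when consecutive anchors are farther apart than this
_MAX_ANCHOR_GAP = 400


@dataclass(frozen=True)
class SeedHit:
    contig: str
    start: int
    end: int
    strand: str
    identity: float        # percent
    length: int            # alignment/span length
    seed_id: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("hit start must be < end")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must be within [0, 100]")


@dataclass
class CandidateLocus:
    contig: str
    start: int
    end: int
    strand: str
    seed_hit_ids: list = field(default_factory=list)
    sequence: str = ""

    @property
    def locus_id(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"empty {what} sequence")
    if set(seq.upper()) - set("ACGTN"):
        raise ValueError(f"{what} contains non-DNA characters")


def _kmer_positions(seq: str, k: int) -> dict:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _diagonal_runs(anchors: list[tuple[int, int]], k: int):
    """Split (diagonal, genome_pos) anchors into runs of nearby positions."""
    by_diag: dict[int, list[int]] = {}
    for diag, gpos in anchors:
        by_diag.setdefault(diag, []).append(gpos)
    for diag, positions in sorted(by_diag.items()):
        positions.sort()
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= _MAX_ANCHOR_GAP:
                run.append(p)
            else:
                yield diag, run
                run = [p]
        yield diag, run


def seed_search(genome: dict, seeds: dict,
                min_identity: float = DEFAULT_MIN_IDENTITY,
                min_length: int = DEFAULT_MIN_LENGTH,
                word_size: int = DEFAULT_WORD_SIZE) -> list[SeedHit]:
    """k-mer seeded ungapped search of ``seeds`` against ``genome``.

    Both strands are searched; minus-strand hits are reported in plus-strand
    genome coordinates with strand "-".  Hits must pass the identity and
    length screens.  Deterministic output order: (contig, start, seed id).
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    if not genome:
        raise ValueError("empty genome")
    if not seeds:
        raise ValueError("empty seed set")
    # one combined index over every (seed, strand): the genome is scanned once
    index: dict[str, list] = {}
    queries: dict[tuple, str] = {}
    for seed_id, sseq in seeds.items():
        _check_dna(sseq, f"seed {seed_id}")
        for strand, query in (("+", sseq.upper()),
                              ("-", revcomp(sseq.upper()))):
            queries[(seed_id, strand)] = query
            for kmer, positions in _kmer_positions(query, word_size).items():
                for qpos in positions:
                    index.setdefault(kmer, []).append((seed_id, strand, qpos))

    hits = []
    for contig, gseq in genome.items():
        _check_dna(gseq, f"genome contig {contig}")
        gseq = gseq.upper()
        anchors: dict[tuple, list] = {}
        for i in range(len(gseq) - word_size + 1):
            entry = index.get(gseq[i:i + word_size])
            if entry is None:
                continue
            for seed_id, strand, qpos in entry:
                anchors.setdefault((seed_id, strand), []).append(
                    (i - qpos, i))
        for (seed_id, strand) in sorted(anchors):
            query = queries[(seed_id, strand)]
            for diag, run in _diagonal_runs(anchors[(seed_id, strand)],
                                            word_size):
                g0, g1 = run[0], run[-1] + word_size
                q0 = g0 - diag
                span = gseq[g0:g1]
                qspan = query[q0:q0 + len(span)]
                if len(span) < min_length:
                    continue
                matches = sum(a == b and a != "N"
                              for a, b in zip(span, qspan))
                identity = 100.0 * matches / len(span)
                if identity < min_identity:
                    continue
                hits.append(SeedHit(contig=contig, start=g0, end=g1,
                                    strand=strand, identity=identity,
                                    length=len(span), seed_id=seed_id))
    hits.sort(key=lambda h: (h.contig, h.start, h.seed_id))
    return hits


def import_tabular_hits(path, seed_is_query: bool = True) -> list[SeedHit]:
    """Read 12-column tabular hits (query, subject, identity, length,
    mismatches, gapopens, qstart, qend, sstart, send, evalue, bitscore).

    Subject coordinates (1-based inclusive) become 0-based half-open genome
    coordinates; sstart > send marks a minus-strand hit.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"row {lineno}: expected 12 columns, got {len(cols)}")
            try:
                identity = float(cols[2])
                length = int(cols[3])
                sstart, send = int(cols[8]), int(cols[9])
            except ValueError as exc:
                raise ValueError(f"row {lineno}: non-numeric field "
                                 f"({exc})") from None
            if not 0.0 <= identity <= 100.0:
                raise ValueError(f"row {lineno}: identity out of range")
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            query, subject = cols[0], cols[1]
            seed_id, contig = ((query, subject) if seed_is_query
                               else (subject, query))
            hits.append(SeedHit(contig=contig, start=lo - 1, end=hi,
                                strand=strand, identity=identity,
                                length=length, seed_id=seed_id))
    hits.sort(key=lambda h: (h.contig, h.start, h.seed_id))
    return hits


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; idempotent and order-independent."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def extract_loci(hits: list[SeedHit], genome: dict,
                 flank: int = DEFAULT_FLANK,
                 merge: bool = True) -> list[CandidateLocus]:
    """Expand hits by ``flank`` on both sides, clamp, merge, and slice.

    The locus strand is the strand of its longest contributing hit;
    minus-strand loci carry the reverse-complemented sequence so annotation
    downstream is strand-agnostic.
    """
    for h in hits:
        if h.contig not in genome:
            raise KeyError(f"hit contig {h.contig!r} absent from genome")
    loci = []
    by_contig: dict[str, list[SeedHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    for contig in sorted(by_contig):
        clen = len(genome[contig])
        expanded = [(max(0, h.start - flank), min(clen, h.end + flank), h)
                    for h in by_contig[contig]]
        if merge:
            merged = merge_intervals([(s, e) for s, e, _ in expanded])
        else:
            merged = sorted({(s, e) for s, e, _ in expanded})
        for s, e in merged:
            members = [h for xs, xe, h in expanded if xs >= s and xe <= e] \
                if merge else \
                      [h for xs, xe, h in expanded if (xs, xe) == (s, e)]
            dominant = max(members, key=lambda h: (h.length, h.identity))
            seq = genome[contig][s:e]
            if dominant.strand == "-":
                seq = revcomp(seq)
            loci.append(CandidateLocus(
                contig=contig, start=s, end=e, strand=dominant.strand,
                seed_hit_ids=[f"{h.seed_id}:{h.start}-{h.end}"
                              for h in members],
                sequence=seq))
    return loci


def write_bed(loci: list[CandidateLocus], path) -> None:
    with open(path, "w") as fh:
        for i, loc in enumerate(loci):
            fh.write(f"{loc.contig}\t{loc.start}\t{loc.end}\t"
                     f"locus_{i:04d}\t0\t{loc.strand}\n")
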