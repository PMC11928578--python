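"""Reference-guided structural annotation of candidate proviral loci.

For each extracted locus this module finds the LTR pair (the provirus's
defining direct repeats), the target-site duplication, the gag/pro/pol/env
gene intervals (projected from a reference provirus annotation through a
global pairwise alignment), late-domain and CETTG motif states, ORF
intactness, and the subgroup-diagnostic large deletions; finally it assigns
a subgroup by nearest-consensus identity, with the env deletion splitting
group B into B1 (deletion) and B2 (no deletion).

LTR pair detection is a self-comparison: the highest-scoring pair of
similar direct repeats at least ``min_separation`` apart, with boundaries
placed by maximum-likelihood ungapped extension (match +1 / mismatch -3
x-drop with outermost-argmax), then trimmed so each boundary ends on a
clean window of 4 consecutive matched pairs — without the trim, chance
matches just beyond the true boundary occasionally drag unrelated flanking
bases into the repeat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import PairwiseAlignment, fast_identity, global_align
from .features import (GENES, MotifReport, OrfReport, classify_motifs,
                       orf_status)

_K = 12                     # k-mer anchor size for the self-comparison
_MIN_ANCHORS = 5
_XDROP = 15
_MATCH, _MISMATCH = 1, -3
_CLEAN_WINDOW = 4


@dataclass
class LtrPair:
    ltr5: tuple               # (start, end) in locus coordinates
    ltr3: tuple
    tsd: str | None
    identity: float           # percent over the repeat extent
    n_differences: int


@dataclass
class DeletionSignature:
    gene: str
    expected: int | None      # 133 / 1487 / 2216, or None for "other"
    observed: int
    present: bool
    tolerance: int


@dataclass
class ProvirusCall:
    locus_id: str
    contig: str
    locus_start: int          # genome coordinate of locus position 0
    strand: str
    provirus: tuple           # (start, end) in locus coordinates
    ltr5: tuple
    ltr3: tuple
    tsd: str | None
    genes: dict = field(default_factory=dict)   # gene -> interval or None
    subgroup: str = "unassigned"
    motifs: MotifReport = field(default_factory=MotifReport)
    orfs: OrfReport = field(default_factory=OrfReport)
    deletions: list = field(default_factory=list)
    mapping_identity: float = 0.0
    flags: list = field(default_factory=list)


@dataclass
class RefAnnotation:
    """Reference provirus: sequence plus feature intervals (0-based)."""
    seq: str
    features: dict            # name -> (start, end); needs ltr5/ltr3 + genes

    @property
    def internal(self) -> str:
        return self.seq[self.features["ltr5"][1]:self.features["ltr3"][0]]

    @property
    def internal_offset(self) -> int:
        return self.features["ltr5"][1]

    def gene_length(self, gene: str) -> int:
        a, b = self.features[gene]
        return b - a


# ---------------------------------------------------------------------------
# LTR pair detection

def _extend(seq: str, d: int, start: int, step: int) -> int:
    """Ungapped x-drop extension comparing seq[p] to seq[p+d].

    Returns the outermost position (inclusive) of the best-scoring
    extension from ``start`` in direction ``step``; ``start - step`` (an
    empty extension) when nothing scores positive.
    """
    n = len(seq)
    best_pos = start - step
    best = score = 0
    p = start
    while 0 <= p and p + d < n:
        score += _MATCH if seq[p] == seq[p + d] else _MISMATCH
        if score >= best:
            best, best_pos = score, p
        if score < best - _XDROP:
            break
        p += step
    return best_pos


def _trim_clean(seq: str, d: int, lo: int, hi: int) -> tuple[int, int]:
    """Shrink [lo, hi] until each end terminates in _CLEAN_WINDOW matches."""
    def dirty(edge: int, step: int) -> bool:
        w = [seq[edge - step * k] == seq[edge - step * k + d]
             for k in range(_CLEAN_WINDOW)]
        return not all(w)
    while hi - lo + 1 > _CLEAN_WINDOW and dirty(hi, 1):
        hi -= 1
    while hi - lo + 1 > _CLEAN_WINDOW and dirty(lo, -1):
        lo += 1
    return lo, hi


def detect_ltr_pair(seq: str, min_ltr_length: int = 100,
                    min_identity: float = 80.0,
                    min_separation: int = 4000) -> LtrPair | None:
    """Find the highest-scoring pair of direct repeats in a locus.

    Returns None (a "no provirus" outcome) when no repeat pair passes the
    length/identity thresholds.
    """
    seq = seq.upper()
    n = len(seq)
    if n <= 2 * min_ltr_length:
        raise ValueError("locus shorter than twice min_ltr_length")
    index: dict[str, list[int]] = {}
    for i in range(n - _K + 1):
        kmer = seq[i:i + _K]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    anchors: dict[int, list[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                d = positions[y] - positions[x]
                if d >= min_separation:
                    anchors.setdefault(d, []).append(positions[x])
    best_call = None
    best_score = -1
    for d, starts in sorted(anchors.items()):
        if len(starts) < _MIN_ANCHORS:
            continue
        starts.sort()
        core_lo, core_hi = starts[0], starts[-1] + _K - 1
        lo = _extend(seq, d, core_lo - 1, -1)
        hi = _extend(seq, d, core_hi + 1, +1)
        lo, hi = _trim_clean(seq, d, lo, hi)
        length = hi - lo + 1
        if length < min_ltr_length:
            continue
        matches = sum(seq[p] == seq[p + d] for p in range(lo, hi + 1))
        identity = 100.0 * matches / length
        if identity < min_identity:
            continue
        if matches > best_score:
            best_score = matches
            best_call = (lo, hi + 1, d, identity, length - matches)
    if best_call is None:
        return None
    a0, a1, d, identity, ndiff = best_call
    tsd = None
    for L in range(10, 3, -1):
        left = seq[a0 - L:a0] if a0 - L >= 0 else ""
        right = seq[a1 + d:a1 + d + L]
        if len(left) == L and len(right) == L and left == right:
            tsd = left
            break
    return LtrPair(ltr5=(a0, a1), ltr3=(a0 + d, a1 + d), tsd=tsd,
                   identity=identity, n_differences=ndiff)


# ---------------------------------------------------------------------------
# reference-guided gene annotation

def map_genes(internal_seq: str, reference: RefAnnotation,
              identity_floor: float = 50.0
              ) -> tuple[dict, PairwiseAlignment | None]:
    """Project reference gene boundaries onto a provirus internal region.

    Returns (gene -> locus-internal interval or None, alignment).  When the
    global alignment identity falls below ``identity_floor`` genes are
    unmapped and the alignment is still returned for diagnostics.
    """
    # gap-length-preserving scoring: expensive open, near-free extension,
    # so a planted multi-hundred-nt deletion stays one contiguous gap run
    # and its length is measured exactly (cheap extension tempts the
    # aligner to shave bases off long gaps wherever chance matches exist)
    aln = global_align(reference.internal, internal_seq,
                       open_gap=-12, extend=-0.5)
    genes: dict[str, tuple | None] = {g: None for g in GENES}
    if aln.identity < identity_floor:
        return genes, aln
    off = reference.internal_offset
    for gene in GENES:
        a, b = reference.features[gene]
        qa, qb = aln.project(a - off), aln.project(b - off)
        genes[gene] = (qa, qb) if qb - qa > 0 else None
    return genes, aln


def detect_deletions(aln: PairwiseAlignment, reference: RefAnnotation,
                     expected_specs: tuple = ((133, "pol"), (2216, "pol"),
                                              (1487, "env")),
                     tolerance: int = 10,
                     min_other: int = 50) -> list[DeletionSignature]:
    """Match reference-relative gap runs against expected deletion lengths.

    A gap run whose length is within ``tolerance`` of an expected length
    for its gene yields a present signature; unmatched runs of at least
    ``min_other`` nt are reported with expected=None ("other").
    """
    off = reference.internal_offset
    out = []
    for ref_start, ref_end, length in aln.ref_gap_runs():
        mid = off + (ref_start + ref_end) // 2
        gene = next((g for g in GENES
                     if reference.features[g][0] <= mid
                     < reference.features[g][1]), None)
        if gene is None:
            continue
        match = next((exp for exp, g in expected_specs
                      if g == gene and abs(length - exp) <= tolerance), None)
        if match is not None:
            out.append(DeletionSignature(gene=gene, expected=match,
                                         observed=length, present=True,
                                         tolerance=tolerance))
        elif length >= min_other:
            out.append(DeletionSignature(gene=gene, expected=None,
                                         observed=length, present=True,
                                         tolerance=tolerance))
    return out


def scan_motifs(genes: dict, locus_seq: str,
                reference: RefAnnotation) -> MotifReport:
    """Motif states from the mapped gag/env intervals (frame 0)."""
    gag = locus_seq[slice(*genes["gag"])] if genes.get("gag") else None
    env = locus_seq[slice(*genes["env"])] if genes.get("env") else None
    return classify_motifs(gag, env, reference.gene_length("env"))


def assess_orfs(genes: dict, locus_seq: str, reference: RefAnnotation,
                full_length_fraction: float = 0.9) -> OrfReport:
    """Per-gene ORF status, internal stop positions, longest ORF length."""
    rep = OrfReport()
    for gene in GENES:
        interval = genes.get(gene)
        seq = locus_seq[slice(*interval)] if interval else None
        status, stops, longest = orf_status(
            seq, reference.gene_length(gene), full_length_fraction)
        rep.status[gene] = status
        rep.stop_positions[gene] = stops
        rep.longest_orf[gene] = longest
    return rep


def assign_subgroup(provirus_seq: str, consensuses: dict,
                    env_deletion_present: bool,
                    identity_floor: float = 70.0) -> str:
    """Nearest-consensus major group; env deletion splits B into B1/B2."""
    if not consensuses:
        raise ValueError("at least one consensus required")
    best_label, best_ident = None, -1.0
    for label in sorted(consensuses):
        ident = fast_identity(provirus_seq, consensuses[label])
        if ident > best_ident:
            best_label, best_ident = label, ident
    if best_ident < identity_floor:
        return "unassigned"
    group = best_label[0]
    if group == "B":
        return "B1" if env_deletion_present else "B2"
    return group


def annotate_locus(locus_seq: str, reference: RefAnnotation,
                   locus_id: str = "", contig: str = "", locus_start: int = 0,
                   strand: str = "+", min_ltr_length: int = 100,
                   ltr_min_identity: float = 80.0,
                   deletion_tolerance: int = 10) -> ProvirusCall | None:
    """Full structural annotation of one locus; None if no provirus found."""
    pair = detect_ltr_pair(locus_seq, min_ltr_length=min_ltr_length,
                           min_identity=ltr_min_identity)
    if pair is None:
        return None
    internal = locus_seq[pair.ltr5[1]:pair.ltr3[0]]
    genes_internal, aln = map_genes(internal, reference)
    call = ProvirusCall(
        locus_id=locus_id, contig=contig, locus_start=locus_start,
        strand=strand, provirus=(pair.ltr5[0], pair.ltr3[1]),
        ltr5=pair.ltr5, ltr3=pair.ltr3, tsd=pair.tsd,
        mapping_identity=aln.identity if aln else 0.0)
    if all(v is None for v in genes_internal.values()):
        call.flags.append("genes_unmapped")
        return call
    shift = pair.ltr5[1]
    call.genes = {g: ((iv[0] + shift, iv[1] + shift) if iv else None)
                  for g, iv in genes_internal.items()}
    call.deletions = detect_deletions(aln, reference,
                                      tolerance=deletion_tolerance)
    call.motifs = scan_motifs(call.genes, locus_seq, reference)
    call.orfs = assess_orfs(call.genes, locus_seq, reference)
    return call


def env_deletion_present(call: ProvirusCall, expected: int = 1487) -> bool:
    return any(sig.gene == "env" and sig.expected == expected
               for sig in call.deletions)


DATING_MARGIN = 10


def ltr_pair_for_dating(locus_seq: str, ltr5: tuple, ltr3: tuple,
                        margin: int = DATING_MARGIN) -> tuple[str, str]:
    """The LTR pair slices used for divergence dating, minus end margins.

    Detected repeat boundaries carry a few base pairs of uncertainty, and
    an overshot boundary aligns unrelated flanking/internal bases whose
    ~75% mismatch rate would contaminate the divergence estimate.  Both
    slices are therefore trimmed by a fixed margin at each end; because
    the trim is content-blind it cannot bias the per-site divergence of
    what remains.  Boundary coordinates reported in the ProvirusCall are
    NOT trimmed.
    """
    a = locus_seq[slice(*ltr5)]
    b = locus_seq[slice(*ltr3)]
    if len(a) > 4 * margin and len(b) > 4 * margin:
        a = a[margin:-margin]
        b = b[margin:-margin]
    return a, b
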