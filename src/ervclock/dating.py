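"""CpG-masked Kimura-2-parameter distances and provirus age estimation.

A provirus's 5' and 3' LTRs are identical at integration and subsequently
diverge independently at the host's neutral substitution rate M
(substitutions/nt/Myr).  The K2P-corrected distance D between the two LTRs
therefore dates the insertion as

    T = D / (2 * M)

the factor 2 counting the two independently evolving copies.  Gene-based
ages use divergence from a subgroup majority-rule consensus (an ancestral
proxy), with the divisor configurable: c = 1 treats the consensus as the
ancestor (divergence accrues along one lineage, the default), c = 2 treats
it as a contemporary relative.

CpG dinucleotide sites are excluded before counting, because spontaneous
deamination of 5-methylcytosine inflates their substitution rate and would
bias ages upward.  Two masking conventions are implemented (both evaluated
on gap-stripped adjacency, unioned over rows):

* ``"union"`` — mask the two columns of every CpG observed in any row.
  This is the convention alignment viewers apply, but it is *biased*: a
  substitution that lands a C before a G (or a G after a C) creates a CpG
  and thereby masks its own site, so differing sites are masked more often
  than matching ones.  Under K80 with uniform composition the deficit is
  computable by enumerating (ancestral, derived) base pairs:
  P(masked | site differs) = 0.242 vs P(masked) = 0.125, shrinking D by a
  factor (1-0.242)/(1-0.125) = 0.866.
* ``"context"`` (default) — mask every site whose previous base is C or
  whose next base is G in any row.  This covers every member of every
  actual CpG *and* every site that could enter a CpG through its own
  mutation; mask status depends only on a site's neighbors, never on its
  own base, so it cannot correlate with whether the site differs — the
  resulting clock is unbiased (fewer compared sites, slightly higher
  variance).

K2P: with transition proportion P and transversion proportion Q over the
compared sites,  D = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import GAP, global_align

DEFAULT_RATE_M = 0.0022   # substitutions / nt / Myr (mammalian average)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


@dataclass
class DistanceResult:
    P: float                 # transition proportion
    Q: float                 # transversion proportion
    D: float | None          # K2P distance; None when saturated
    n_sites: int             # compared sites after all exclusions
    n_masked_cpg: int
    n_gap_excluded: int
    saturated: bool = False


@dataclass
class AgeEstimate:
    provirus_id: str
    method: str              # "ltr_pair" | "gene_consensus"
    gene: str | None
    distance: DistanceResult
    M: float
    divisor: int
    T: float                 # Myr
    subgroup: str | None = None


@dataclass
class SkippedEstimate:
    provirus_id: str
    method: str
    reason: str
    gene: str | None = None
    subgroup: str | None = None


DEFAULT_MASK_MODE = "context"


def mask_cpg(rows: list[str], mode: str = DEFAULT_MASK_MODE) -> np.ndarray:
    """Boolean mask over alignment columns: True = CpG-excluded.

    ``mode="union"`` masks both members of every CpG observed in any row;
    ``mode="context"`` (default) masks every site whose gap-stripped
    previous base is C or next base is G in any row — a superset of the
    union mask whose status is independent of the site's own base (see
    module docstring for why this removes the union convention's
    divergence bias).
    """
    if not rows:
        raise ValueError("no rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be aligned (equal length)")
    if mode not in ("union", "context"):
        raise ValueError(f"unknown mask mode {mode!r}")
    ncol = len(rows[0])
    mask = np.zeros(ncol, dtype=bool)
    for row in rows:
        nongap = [(col, ch) for col, ch in enumerate(row.upper())
                  if ch != GAP]
        for k, (col, ch) in enumerate(nongap):
            prev_ch = nongap[k - 1][1] if k > 0 else None
            next_ch = nongap[k + 1][1] if k + 1 < len(nongap) else None
            if mode == "union":
                if ch == "C" and next_ch == "G":
                    mask[col] = True
                    mask[nongap[k + 1][0]] = True
            else:
                if prev_ch == "C" or next_ch == "G":
                    mask[col] = True
    return mask


def k2p_distance(row_a: str, row_b: str,
                 mask: np.ndarray | None = None) -> DistanceResult:
    """K2P distance between two aligned rows, excluding masked columns.

    Columns with gaps or ambiguity codes in either row are excluded from
    the comparison (counted separately from the CpG mask).  Saturation
    (log argument <= 0) is reported as an explicit outcome, not an
    exception or infinity.  Raises when no sites remain.
    """
    a, b = row_a.upper(), row_b.upper()
    if len(a) != len(b):
        raise ValueError("rows must be aligned (equal length)")
    if mask is None:
        mask = np.zeros(len(a), dtype=bool)
    n_sites = transitions = transversions = 0
    n_cpg = n_gap = 0
    for i, (ca, cb) in enumerate(zip(a, b)):
        if ca not in _VALID or cb not in _VALID:
            n_gap += 1
            continue
        if mask[i]:
            n_cpg += 1
            continue
        n_sites += 1
        if ca == cb:
            continue
        same_class = ((ca in PURINES) == (cb in PURINES))
        if same_class:
            transitions += 1
        else:
            transversions += 1
    if n_sites == 0:
        raise ValueError("zero compared sites after masking/exclusion")
    P = transitions / n_sites
    Q = transversions / n_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return DistanceResult(P=P, Q=Q, D=None, n_sites=n_sites,
                              n_masked_cpg=n_cpg, n_gap_excluded=n_gap,
                              saturated=True)
    D = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceResult(P=P, Q=Q, D=D, n_sites=n_sites, n_masked_cpg=n_cpg,
                          n_gap_excluded=n_gap)


def pair_distance(seq_a: str, seq_b: str, cpg_mask: bool = True,
                  mask_mode: str = DEFAULT_MASK_MODE) -> DistanceResult:
    """Align two unaligned sequences and compute their masked K2P distance."""
    if seq_a == seq_b:
        rows = (seq_a, seq_b)
    else:
        aln = global_align(seq_a, seq_b)
        rows = (aln.ref, aln.query)
    mask = mask_cpg(list(rows), mode=mask_mode) if cpg_mask else None
    return k2p_distance(rows[0], rows[1], mask)


def ltr_pair_age(ltr5: str | None, ltr3: str | None,
                 M: float = DEFAULT_RATE_M, provirus_id: str = "",
                 cpg_mask: bool = True, mask_mode: str = DEFAULT_MASK_MODE,
                 subgroup: str | None = None):
    """Age from a provirus's own LTR pair: T = D / (2 M).

    Returns an AgeEstimate, or a SkippedEstimate when an LTR is missing or
    the pair is saturated.
    """
    if not ltr5 or not ltr3:
        return SkippedEstimate(provirus_id=provirus_id, method="ltr_pair",
                               reason="missing LTR", subgroup=subgroup)
    dist = pair_distance(ltr5, ltr3, cpg_mask=cpg_mask,
                         mask_mode=mask_mode)
    if dist.saturated:
        return SkippedEstimate(provirus_id=provirus_id, method="ltr_pair",
                               reason="saturated distance",
                               subgroup=subgroup)
    return AgeEstimate(provirus_id=provirus_id, method="ltr_pair", gene=None,
                       distance=dist, M=M, divisor=2,
                       T=dist.D / (2.0 * M), subgroup=subgroup)


def gene_consensus_age(gene_seq: str, consensus_seq: str, gene: str,
                       M: float = DEFAULT_RATE_M, divisor: int = 1,
                       provirus_id: str = "", cpg_mask: bool = True,
                       mask_mode: str = DEFAULT_MASK_MODE,
                       subgroup: str | None = None):
    """Age from a gene's divergence to its subgroup consensus: T = D/(c M)."""
    if divisor not in (1, 2):
        raise ValueError("divisor must be 1 or 2")
    dist = pair_distance(gene_seq, consensus_seq, cpg_mask=cpg_mask,
                         mask_mode=mask_mode)
    if dist.saturated:
        return SkippedEstimate(provirus_id=provirus_id,
                               method="gene_consensus", gene=gene,
                               reason="saturated distance",
                               subgroup=subgroup)
    return AgeEstimate(provirus_id=provirus_id, method="gene_consensus",
                       gene=gene, distance=dist, M=M, divisor=divisor,
                       T=dist.D / (divisor * M), subgroup=subgroup)


def split_dating_subgroups(sequences: list[str], ids: list,
                           distance_threshold: float = 0.04,
                           cpg_mask: bool = True) -> dict:
    """Partition gene sequences for more accurate consensus dating.

    Average-linkage hierarchical clustering on pairwise masked K2P
    distances, cut at ``distance_threshold``.  Saturated pairs get a large
    finite distance.  Cluster labels are deterministic: ordered by cluster
    size (descending) then smallest member id.  Returns id -> cluster label
    (int, 1-based).
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pair_distance(sequences[i], sequences[j], cpg_mask=cpg_mask)
            dm[i, j] = dm[j, i] = 3.0 if d.saturated else d.D
    labels = fcluster(linkage(squareform(dm), method="average"),
                      t=distance_threshold, criterion="distance")
    clusters: dict[int, list] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    ordered = sorted(clusters.values(),
                     key=lambda m: (-len(m), str(ids[m[0]])))
    out = {}
    for new_label, members in enumerate(ordered, start=1):
        for i in members:
            out[ids[i]] = new_label
    return out


@dataclass
class SubgroupAgeSummary:
    subgroup: str
    method: str
    gene: str | None
    n: int
    mean_T: float
    sd_T: float
    median_T: float

    def render(self) -> str:
        """Table-style "~ mean (± sd)" with 2 decimals."""
        return f"~ {self.mean_T:.2f} (± {self.sd_T:.2f})"


def summarize_ages(estimates: list[AgeEstimate]) -> list[SubgroupAgeSummary]:
    """Per-(subgroup, method, gene) n / mean / sample SD / median."""
    rows = [(e.subgroup or "all", e.method, e.gene or "", e.T)
            for e in estimates if isinstance(e, AgeEstimate)]
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["subgroup", "method", "gene", "T"])
    out = []
    for (sg, method, gene), grp in df.groupby(["subgroup", "method", "gene"],
                                              sort=True):
        T = grp["T"].to_numpy()
        sd = float(np.std(T, ddof=1)) if len(T) > 1 else 0.0
        out.append(SubgroupAgeSummary(
            subgroup=sg, method=method, gene=gene or None, n=len(T),
            mean_T=float(np.mean(T)), sd_T=sd, median_T=float(np.median(T))))
    return out


def estimates_dataframe(estimates: list) -> pd.DataFrame:
    """Flat per-estimate table (supplementary-table shape)."""
    rows = []
    for e in estimates:
        if isinstance(e, AgeEstimate):
            d = e.distance
            rows.append({
                "provirus_id": e.provirus_id, "subgroup": e.subgroup,
                "method": e.method, "gene": e.gene, "P": d.P, "Q": d.Q,
                "D": d.D, "n_sites": d.n_sites,
                "n_masked_cpg": d.n_masked_cpg,
                "n_gap_excluded": d.n_gap_excluded, "M": e.M,
                "divisor": e.divisor, "T": e.T, "skipped": "",
            })
        else:
            rows.append({"provirus_id": e.provirus_id, "subgroup": e.subgroup,
                         "method": e.method, "gene": e.gene,
                         "skipped": e.reason})
    return pd.DataFrame(rows)
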