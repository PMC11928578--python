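"""Pairwise alignment helpers shared across the pipeline.

Global affine-gap alignments (match 2, mismatch -3, gap open -5, gap extend
-2 by default) are delegated to Bio.Align.PairwiseAligner; fast percent
identity screens use edlib's edit distance.  A small dataclass carries the
gapped rows plus a reference→query coordinate projection, which the
annotator uses to lift reference gene boundaries onto candidate proviruses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import edlib
from Bio import Align

GAP = "-"


@lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, open_gap: float,
             extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = open_gap
    al.extend_gap_score = extend
    return al


@dataclass
class PairwiseAlignment:
    ref: str            # gapped reference/first row
    query: str          # gapped query/second row
    score: float

    @property
    def n_columns(self) -> int:
        return len(self.ref)

    @property
    def identity(self) -> float:
        """Percent of alignment columns that are exact base matches."""
        matches = sum(a == b and a != GAP
                      for a, b in zip(self.ref, self.query))
        return 100.0 * matches / max(1, self.n_columns)

    def project(self, ref_pos: int) -> int:
        """Map a reference coordinate to a query coordinate.

        A reference position deleted from the query maps to the query
        position where the deletion occurred (so half-open intervals project
        to well-formed, possibly shortened, intervals).
        """
        r = q = 0
        for cr, cq in zip(self.ref, self.query):
            if r == ref_pos and cr != GAP:
                return q
            if cr != GAP:
                r += 1
            if cq != GAP:
                q += 1
        return q

    def ref_gap_runs(self) -> list[tuple[int, int, int]]:
        """Deletions in the query relative to the reference.

        Returns (ref_start, ref_end, length) for each maximal run of
        reference bases aligned to gaps in the query.
        """
        runs = []
        r = 0
        run_start = None
        for cr, cq in zip(self.ref, self.query):
            if cr != GAP:
                if cq == GAP:
                    if run_start is None:
                        run_start = r
                else:
                    if run_start is not None:
                        runs.append((run_start, r, r - run_start))
                        run_start = None
                r += 1
            # query insertions do not interrupt a deletion run bookkeeping:
            # a cq base with cr gap ends any run implicitly next ref base
        if run_start is not None:
            runs.append((run_start, r, r - run_start))
        return runs


def global_align(ref: str, query: str, match: float = 2,
                 mismatch: float = -3, open_gap: float = -5,
                 extend: float = -2) -> PairwiseAlignment:
    """Global pairwise alignment with affine gaps; deterministic traceback."""
    al = _aligner(match, mismatch, open_gap, extend)
    aln = al.align(ref.upper(), query.upper())[0]
    return PairwiseAlignment(ref=str(aln[0]), query=str(aln[1]),
                             score=float(aln.score))


def fast_identity(a: str, b: str) -> float:
    """Percent identity from edlib's global edit distance.

    Normalized by the longer sequence; an inexpensive screen used where
    only a coarse identity threshold matters (e.g. subgroup assignment).
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a.upper(), b.upper(), mode="NW", task="distance")
    return 100.0 * (1.0 - d["editDistance"] / max(len(a), len(b)))
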