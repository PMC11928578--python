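"""Multiple alignment management and majority-rule consensus construction.

A recently expanded ERV family is well approximated by its majority-rule
consensus, which serves as the ancestral-sequence proxy for
divergence-based dating.  This module aligns family members (built-in
center-star progressive alignment, or any external aligner via a command
template), builds per-column majority consensuses, and iteratively excludes
members that align too poorly to the family consensus.

Majority rule: per column the most frequent symbol wins, gaps counting as a
symbol; columns won by the gap are omitted from the consensus string (but
retained in the column map); ties are broken by fixed base order
A < C < G < T, and any base beats the gap on a base-gap tie.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .align import GAP, global_align

BUILTIN_MAX_SEQS = 300
BUILTIN_MAX_LEN = 12_000

_BASE_RANK = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class AlignmentBlock:
    ids: list
    rows: list                      # equal-length gapped strings

    def __post_init__(self):
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def subset(self, keep: list[int]) -> "AlignmentBlock":
        return AlignmentBlock(ids=[self.ids[i] for i in keep],
                              rows=[self.rows[i] for i in keep])


@dataclass
class ConsensusProfile:
    sequence: str
    support: list = field(default_factory=list)   # fraction per position
    column_map: list = field(default_factory=list)  # position -> column
    n_members: int = 0


def _kmer_set(seq: str, k: int = 8) -> set:
    return {seq[i:i + k] for i in range(max(0, len(seq) - k + 1))}


def _pick_center(seqs: list[str]) -> int:
    sets = [_kmer_set(s) for s in seqs]
    best, best_score = 0, -1.0
    for i in range(len(seqs)):
        score = sum(len(sets[i] & sets[j]) for j in range(len(seqs))
                    if j != i)
        if score > best_score:
            best, best_score = i, score
    return best


def _center_star(seqs: list[str]) -> list[str]:
    """Progressive center-star alignment via pairwise global alignments.

    Pairwise scoring uses an expensive gap open with near-free extension:
    within an ERV family true indels are discrete shared events whose
    lengths carry signal, so the aligner must neither fragment them nor
    trade mismatch clusters for short spurious gaps.
    """
    c = _pick_center(seqs)
    center = seqs[c]
    n_pos = len(center) + 1
    # per member: insertions[p] = bases inserted before center position p,
    # and the member's symbol aligned to each center base
    member_ins, member_cols = [], []
    for s in seqs:
        aln = global_align(center, s, open_gap=-12, extend=-0.5)
        ins = [""] * n_pos
        cols = []
        p = 0
        for cr, cq in zip(aln.ref, aln.query):
            if cr == GAP:
                ins[p] += cq
            else:
                cols.append(cq)
                p += 1
        member_ins.append(ins)
        member_cols.append(cols)
    max_ins = [max(len(mi[p]) for mi in member_ins) for p in range(n_pos)]
    rows = []
    for ins, cols in zip(member_ins, member_cols):
        parts = []
        for p in range(n_pos):
            parts.append(ins[p] + GAP * (max_ins[p] - len(ins[p])))
            if p < len(center):
                parts.append(cols[p])
        rows.append("".join(parts))
    return rows


def _run_external(seqs: list[str], ids: list, command: str) -> list[str]:
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        with open(infile, "w") as fh:
            for name, s in zip(ids, seqs):
                fh.write(f">{name}\n{s}\n")
        cmd = command.replace("{input}", str(infile))
        capture = "{output}" not in cmd
        cmd = cmd.replace("{output}", str(outfile))
        proc = subprocess.run(shlex.split(cmd), capture_output=True,
                              text=True, check=True)
        text = proc.stdout if capture else outfile.read_text()
    rows_by_id = {}
    name, chunks = None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                rows_by_id[name] = "".join(chunks)
            name, chunks = line[1:].split()[0], []
        else:
            chunks.append(line.strip())
    if name is not None:
        rows_by_id[name] = "".join(chunks)
    return [rows_by_id[str(i)].upper() for i in ids]


def align(sequences: list[str], ids: list | None = None,
          aligner_cmd: str | None = None) -> AlignmentBlock:
    """Multiple alignment of DNA sequences.

    Uses the built-in center-star progressive aligner (suitable up to
    ~300 sequences x 12 kb) unless ``aligner_cmd`` gives an external
    command template with ``{input}`` (and optionally ``{output}``)
    placeholders, e.g. ``"mafft --quiet {input}"``.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences to align")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    sequences = [s.upper() for s in sequences]
    if aligner_cmd:
        rows = _run_external(sequences, ids, aligner_cmd)
    else:
        if (len(sequences) > BUILTIN_MAX_SEQS
                or max(map(len, sequences)) > BUILTIN_MAX_LEN):
            raise ValueError(
                "instance exceeds built-in aligner limits "
                f"({BUILTIN_MAX_SEQS} seqs x {BUILTIN_MAX_LEN} bp); "
                "provide aligner_cmd")
        rows = _center_star(sequences)
    block = AlignmentBlock(ids=list(ids), rows=rows)
    for i, s in enumerate(sequences):
        if block.degapped(i) != s:
            raise AssertionError("aligner violated round-trip invariant")
    return block


def majority_consensus(block: AlignmentBlock) -> ConsensusProfile:
    """Per-column majority symbol; gap-majority columns omitted."""
    if not block.rows:
        raise ValueError("empty alignment block")
    n = len(block.rows)
    seq, support, colmap = [], [], []
    for col in range(block.n_columns):
        counts = Counter(row[col] for row in block.rows)
        winner = min(counts,
                     key=lambda s: (-counts[s],
                                    _BASE_RANK.get(s, 4) if s != GAP else 99))
        if winner == GAP:
            continue
        seq.append(winner)
        support.append(counts[winner] / n)
        colmap.append(col)
    return ConsensusProfile(sequence="".join(seq), support=support,
                            column_map=colmap, n_members=n)


def _identity_to_consensus(block: AlignmentBlock, i: int,
                           profile: ConsensusProfile) -> float:
    row = block.rows[i]
    matches = sum(row[col] == base
                  for col, base in zip(profile.column_map, profile.sequence))
    denom = max(len(block.degapped(i)), len(profile.sequence))
    return 100.0 * matches / max(1, denom)


def flag_outliers(block: AlignmentBlock,
                  min_identity: float = 60.0) -> list:
    """Iteratively exclude members below ``min_identity`` to the consensus.

    After each removal the consensus is recomputed from the remaining rows.
    Removal order is deterministic: lowest identity first, ties by id.
    Raises if the threshold would exclude every member.
    """
    if len(block.rows) < 3:
        raise ValueError("outlier flagging needs >= 3 members")
    keep = list(range(len(block.rows)))
    excluded = []
    while True:
        if not keep:
            raise ValueError(
                f"identity threshold {min_identity} would exclude all "
                "members")
        current = block.subset(keep)
        profile = majority_consensus(current)
        idents = [(_identity_to_consensus(current, j, profile),
                   current.ids[j], j) for j in range(len(keep))]
        worst = min(idents, key=lambda t: (t[0], str(t[1])))
        if worst[0] >= min_identity:
            return excluded
        excluded.append(worst[1])
        keep.pop(worst[2])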