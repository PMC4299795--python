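"""Majority-rule consensus building with ORF repair.

Given aligned copies of an element family, the consensus takes the most
frequent state per column (gap-majority columns are omitted), then repairs
premature stop codons and frame-disrupting indel columns inside annotated
ORF spans by substituting the next-most-frequent column state.  The repair
is the deterministic, reproducible equivalent of curating a repeat-family
consensus by hand, and the reverse-transcriptase span is re-translated to
decide whether an intact RT could be reconstructed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import edlib
import numpy as np
from Bio.Seq import Seq

GAP = "-"
# column tie-break: gap wins ties, then alphabetical
_STATE_ORDER = {GAP: 0, "A": 1, "C": 2, "G": 3, "T": 4}
STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class CopyAlignment:
    """Aligned nucleotide copies of one element family."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class RepairEntry:
    column: int  # consensus coordinate
    original: str
    substituted: str
    reason: str  # "nonsense" | "frameshift"


@dataclass
class ConsensusRecord:
    raw: str
    repaired: str
    log: list[RepairEntry] = field(default_factory=list)
    rt_intact: bool = True


def _column_counts(alignment: CopyAlignment) -> list[dict[str, int]]:
    cols = []
    for c in range(alignment.n_columns):
        counts: dict[str, int] = {}
        for r in alignment.rows:
            counts[r[c]] = counts.get(r[c], 0) + 1
        cols.append(counts)
    return cols


def _ranked_states(counts: dict[str, int]) -> list[str]:
    return sorted(counts, key=lambda s: (-counts[s], _STATE_ORDER.get(s, 9)))


def majority_consensus(alignment: CopyAlignment) -> tuple[str, list[int]]:
    """Majority-rule consensus and the alignment column of each consensus
    position.  Gap-majority columns are omitted; ties resolve gap < A < C <
    G < T."""
    out = []
    colmap = []
    for c, counts in enumerate(_column_counts(alignment)):
        state = _ranked_states(counts)[0]
        if state != GAP:
            out.append(state)
            colmap.append(c)
    return "".join(out), colmap


def _runner_up(counts: dict[str, int], not_state: str) -> list[str]:
    return [s for s in _ranked_states(counts) if s != not_state]


def _top_level_spans(domain_map: dict[str, tuple[int, int]]) -> list[tuple[str, tuple[int, int]]]:
    """Spans not nested inside another span (e.g. RT/IN sit inside pol)."""
    items = sorted(domain_map.items(), key=lambda kv: (kv[1][0], -(kv[1][1] - kv[1][0])))
    out = []
    for name, (s, e) in items:
        if any(os <= s and e <= oe and (os, oe) != (s, e)
               for _, (os, oe) in items):
            continue
        out.append((name, (s, e)))
    return out


def repair_orfs(alignment: CopyAlignment, domain_map: dict[str, tuple[int, int]],
                raw: str | None = None,
                colmap: list[int] | None = None) -> ConsensusRecord:
    """Repair nonsense and frameshift artefacts of consensus building.

    ``domain_map`` gives ORF spans in raw-consensus coordinates (half-open);
    repairs never touch columns outside these spans.  At each premature stop
    codon the highest-count alternative column state that removes the stop
    is substituted; if an ORF span's length is not a frame multiple, the
    most nearly tied indel column inside the span is flipped between
    kept/omitted to restore the frame.  Unresolvable sites are left in
    place and, when they fall in the RT span, flag ``rt_intact=False``.
    """
    if raw is None or colmap is None:
        raw, colmap = majority_consensus(alignment)
    counts = _column_counts(alignment)
    seq = list(raw)
    colmap = list(colmap)
    log: list[RepairEntry] = []
    rt_intact = True
    delta = 0  # cumulative shift applied to spans downstream of indel edits
    edits: list[tuple[int, int]] = []  # (position, +-1)

    for name, (s0, e0) in _top_level_spans(domain_map):
        s, e = s0 + delta, e0 + delta

        # --- frame restoration ------------------------------------------
        if (e - s) % 3 != 0:
            cands: list[tuple[int, str, int]] = []  # (tie-closeness, action, col)
            for ci in range(s, min(e, len(seq))):
                col = counts[colmap[ci]]
                g = col.get(GAP, 0)
                n = sum(col.values())
                if 0 < g <= n - g and (e - s - 1) % 3 == 0:
                    cands.append((n - 2 * g, "drop", ci))
            span_cols = set(colmap[s:min(e, len(seq))])
            if s < len(colmap) and e - 1 <= len(colmap):
                for c in range(colmap[s], colmap[min(e, len(seq)) - 1] + 1):
                    if c in span_cols:
                        continue
                    col = counts[c]
                    g = col.get(GAP, 0)
                    if g < sum(col.values()) and (e - s + 1) % 3 == 0:
                        cands.append((2 * g - sum(col.values()), "restore", c))
            cands.sort()
            if cands:
                _, action, c = cands[0]
                if action == "drop":
                    log.append(RepairEntry(c, seq[c], GAP, "frameshift"))
                    del seq[c], colmap[c]
                    e -= 1
                    delta -= 1
                    edits.append((c, -1))
                else:
                    state = _runner_up(counts[c], GAP)[0]
                    ci = bisect.bisect_left(colmap, c)
                    seq.insert(ci, state)
                    colmap.insert(ci, c)
                    log.append(RepairEntry(ci, GAP, state, "frameshift"))
                    e += 1
                    delta += 1
                    edits.append((ci, +1))
            elif _overlaps(domain_map.get("RT"), (s0, e0)):
                rt_intact = False

        # --- nonsense repair: premature stops only (final codon is the
        # natural terminator) ---------------------------------------------
        last = min(e, len(seq) - (len(seq) - s) % 3) - 3
        for pos in range(s, last, 3):
            codon = "".join(seq[pos:pos + 3])
            if codon not in STOPS:
                continue
            options = []
            for off in range(3):
                ci = pos + off
                for state in _runner_up(counts[colmap[ci]], seq[ci]):
                    if state == GAP:
                        continue
                    trial = list(codon)
                    trial[off] = state
                    if "".join(trial) not in STOPS:
                        options.append((-counts[colmap[ci]].get(state, 0), off, state))
            if options:
                options.sort()
                _, off, state = options[0]
                ci = pos + off
                log.append(RepairEntry(ci, seq[ci], state, "nonsense"))
                seq[ci] = state
            elif _overlaps(domain_map.get("RT"), (pos - delta, pos + 3 - delta)):
                rt_intact = False

    def shift(x: int) -> int:
        return x + sum(d for p, d in edits if p < x)

    repaired = "".join(seq)
    rec = ConsensusRecord(raw=raw, repaired=repaired, log=log, rt_intact=rt_intact)
    if "RT" in domain_map:
        s, e = domain_map["RT"]
        rec.rt_intact = rec.rt_intact and (
            reconstruct_rt(repaired, {"RT": (shift(s), shift(e))}) is not None)
    return rec


def _overlaps(a: tuple[int, int] | None, b: tuple[int, int]) -> bool:
    return a is not None and a[0] < b[1] and b[0] < a[1]


def reconstruct_rt(repaired: str, domain_map: dict[str, tuple[int, int]]) -> str | None:
    """Translation of the RT span, or None if a stop or frame break remains."""
    if "RT" not in domain_map:
        raise ValueError("domain map lacks an RT span")
    s, e = domain_map["RT"]
    sub = repaired[s:e]
    if len(sub) % 3:
        return None
    aa = str(Seq(sub).translate())
    if "*" in aa:
        return None
    return aa


def build_consensus(alignment: CopyAlignment,
                    domain_map: dict[str, tuple[int, int]]) -> ConsensusRecord:
    """Majority consensus followed by ORF repair (convenience wrapper)."""
    raw, colmap = majority_consensus(alignment)
    return repair_orfs(alignment, domain_map, raw=raw, colmap=colmap)


# --------------------------------------------------------------------------
# built-in center-star progressive aligner

def _pairwise_rows(a: str, b: str) -> tuple[str, str]:
    # affine gap costs: unit-cost edit alignments open spurious indel pairs
    # between equal-length diverged copies, which breaks reading frames
    from Bio import Align
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -4
    al.extend_gap_score = -1
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def center_star_align(ids: list[str], seqs: list[str]) -> CopyAlignment:
    """Center-star multiple alignment: the sequence minimising total edit
    distance to the others anchors pairwise alignments that are merged
    column-wise ('once a gap, always a gap').  Adequate for the
    high-identity copy sets consensus building works on; any external
    aligner's FASTA output can be supplied instead."""
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    n = len(seqs)
    totals = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")["editDistance"]
            totals[i] += d
            totals[j] += d
    center = int(np.argmin(totals))
    center_seq = seqs[center]
    # merge pairwise alignments onto center coordinates
    aligned_center = center_seq
    rows: dict[int, str] = {center: center_seq}
    gap_runs: dict[int, int] = {}  # gaps inserted after center position i

    pair_alns = {}
    for j in range(n):
        if j == center:
            continue
        ca, ja = _pairwise_rows(center_seq, seqs[j])
        pair_alns[j] = (ca, ja)
        # count gaps in center row between consecutive center residues
        pos = 0
        run = 0
        for ch in ca:
            if ch == GAP:
                run += 1
            else:
                if run:
                    gap_runs[pos] = max(gap_runs.get(pos, 0), run)
                    run = 0
                pos += 1
        if run:
            gap_runs[pos] = max(gap_runs.get(pos, 0), run)

    def expand_center(row: str) -> str:
        out = []
        pos = 0
        if 0 in gap_runs:
            out.append(GAP * gap_runs[0])
        for ch in row:
            out.append(ch)
            pos += 1
            if pos in gap_runs:
                out.append(GAP * gap_runs[pos])
        return "".join(out)

    final_rows = [""] * n
    final_rows[center] = expand_center(center_seq)
    width = len(final_rows[center])
    for j, (ca, ja) in pair_alns.items():
        out = []
        pos = 0  # center residues consumed
        run = 0  # gaps since last center residue
        pending: list[str] = []
        emitted = 0

        def flush(target_gaps: int):
            nonlocal pending
            pad = target_gaps - len(pending)
            return GAP * max(pad, 0) + "".join(pending)

        for cch, jch in zip(ca, ja):
            if cch == GAP:
                pending.append(jch)
            else:
                out.append(flush(gap_runs.get(pos, 0)))
                pending = []
                out.append(jch)
                pos += 1
        out.append(flush(gap_runs.get(pos, 0)))
        row = "".join(out)
        row += GAP * (width - len(row))
        final_rows[j] = row
    return CopyAlignment(ids=list(ids), rows=final_rows)
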