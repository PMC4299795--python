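"""Detection of LTR-flanked proviruses and solo LTRs.

The detector finds candidate direct-repeat (LTR) pairs by 12-mer seeding
with X-drop boundary extension, verifies them by global alignment identity,
looks for an exact target-site duplication immediately outside the repeat,
scans the internal region's six-frame translation for retroviral domain
signatures, and scores the resulting chain with a transparent additive
score: each motif contributes 0-100 (percent similarity to its signature),
an LTR pair adds 50 and a TSD adds 25.  The chain cut-off of 250 admits
divergent proviruses; 300 is the conventional reporting threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from Bio.Seq import Seq

from ._align import global_identity
from .motifs import SIGNATURES

DETECT_CUTOFF = 250
REPORT_CUTOFF = 300


@dataclass
class LTRPair:
    scaffold: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float
    aln_len: int

    @property
    def span(self) -> tuple[int, int]:
        return self.ltr5[0], self.ltr3[1]


@dataclass
class TSD:
    sequence: str
    exact_match: bool = True

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class DomainHit:
    domain: str
    frame: int  # 0..2 forward, -1..-3 reverse
    start: int  # nt, relative to the scanned (internal) sequence
    end: int
    score: float  # 0-100


@dataclass
class ProvirusCall:
    id: str
    pair: LTRPair
    tsd: TSD | None
    hits: list[DomainHit] = field(default_factory=list)
    chain_score: float = 0.0
    complete: bool = False
    pol_aa: str = ""
    gag_aa: str = ""

    @property
    def scaffold(self) -> str:
        return self.pair.scaffold

    @property
    def start(self) -> int:
        return self.pair.ltr5[0]

    @property
    def end(self) -> int:
        return self.pair.ltr3[1]

    def hit(self, domain: str) -> DomainHit | None:
        for h in self.hits:
            if h.domain == domain:
                return h
        return None


@dataclass
class SoloLTRCall:
    scaffold: str
    start: int
    end: int
    tsd: TSD | None
    library_entry: str | None
    identity: float


# --------------------------------------------------------------------------
# LTR pair finding

def _as_scaffolds(genome) -> dict[str, str]:
    if isinstance(genome, str):
        return {"seq": genome}
    if hasattr(genome, "scaffolds"):
        return genome.scaffolds
    return dict(genome)


def _xdrop_extend(s: str, i: int, j: int, direction: int,
                  xdrop: int = 8, mismatch: int = -2) -> int:
    """Ungapped extension along a fixed diagonal; returns the number of
    steps to the score maximum."""
    best = cur = 0
    best_k = 0
    k = 1
    n = len(s)
    while True:
        a, b = i + direction * k, j + direction * k
        if a < 0 or b < 0 or a >= n or b >= n or (direction > 0 and a >= j):
            break
        cur += 1 if s[a] == s[b] else mismatch
        if cur > best:
            best, best_k = cur, k
        if cur < best - xdrop:
            break
        k += 1
    return best_k


def find_ltr_pairs(genome, min_ltr_len: int = 200, min_identity: float = 0.60,
                   sep_range: tuple[int, int] = (1000, 15000),
                   k: int = 12) -> list[LTRPair]:
    """Direct-repeat pairs meeting the length/identity/separation thresholds.

    Separation is measured start-to-start.  Candidates are found by exact
    k-mer seeding, clustered along diagonals, extended ungapped with X-drop,
    and verified by global alignment identity; overlapping candidates are
    resolved greedily by identity x length.
    """
    pairs: list[LTRPair] = []
    for name, seq in _as_scaffolds(genome).items():
        n = len(seq)
        index: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            index.setdefault(seq[i:i + k], []).append(i)
        seeds: list[tuple[int, int]] = []
        for positions in index.values():
            if len(positions) < 2 or len(positions) > 50:
                continue
            for ai in range(len(positions)):
                for bi in range(ai + 1, len(positions)):
                    sep = positions[bi] - positions[ai]
                    if sep_range[0] <= sep <= sep_range[1]:
                        seeds.append((positions[ai], positions[bi]))
        seeds.sort()
        clusters: list[dict] = []
        for i, j in seeds:
            placed = False
            for c in clusters:
                if 0 <= i - c["max_i"] <= 600 and abs((j - i) - c["diag"]) <= 60 \
                        and j >= c["max_j"]:
                    c["max_i"], c["max_j"] = i, j
                    c["diag"] = j - i
                    placed = True
                    break
            if not placed:
                clusters.append({"min_i": i, "min_j": j, "max_i": i, "max_j": j,
                                 "diag0": j - i, "diag": j - i})
        candidates: list[LTRPair] = []
        for c in clusters:
            left = _xdrop_extend(seq, c["min_i"], c["min_j"], -1)
            right = _xdrop_extend(seq, c["max_i"] + k - 1, c["max_j"] + k - 1, +1)
            a0, a1 = c["min_i"] - left, c["max_i"] + k + right
            b0, b1 = c["min_j"] - left, c["max_j"] + k + right
            if a1 - a0 < min_ltr_len or a1 > b0:
                continue
            if not sep_range[0] <= b0 - a0 <= sep_range[1]:
                continue
            ident, cols = global_identity(seq[a0:a1], seq[b0:b1])
            if ident >= min_identity:
                candidates.append(LTRPair(name, (a0, a1), (b0, b1), ident, cols))
        candidates.sort(key=lambda p: -(p.identity * p.aln_len))
        chosen: list[LTRPair] = []
        for cand in candidates:
            s0, s1 = cand.span
            if all(s1 <= o.span[0] or s0 >= o.span[1] for o in chosen):
                chosen.append(cand)
        pairs.extend(chosen)
    pairs.sort(key=lambda p: (p.scaffold, p.ltr5[0]))
    return pairs


# --------------------------------------------------------------------------
# target-site duplications

def _longest_exact_tsd(seq: str, a: int, b: int, kmin: int, kmax: int) -> int:
    """Longest k in [kmin, kmax] with seq[a-k:a] == seq[b:b+k]."""
    best = 0
    for kk in range(kmin, kmax + 1):
        if a - kk < 0 or b + kk > len(seq):
            break
        if seq[a - kk:a] == seq[b:b + kk]:
            best = kk
    return best


def detect_tsd(genome, pair: LTRPair, k_range: tuple[int, int] = (3, 8)) -> TSD | None:
    """Longest exact duplication flanking the repeat pair, or None.

    Compares the k bases immediately 5' of the 5' LTR with the k bases
    immediately 3' of the 3' LTR at the pair's stated boundaries."""
    seq = _as_scaffolds(genome)[pair.scaffold]
    a, b = pair.ltr5[0], pair.ltr3[1]
    best = _longest_exact_tsd(seq, a, b, k_range[0], k_range[1])
    if best == 0:
        return None
    return TSD(sequence=seq[a - best:a])


def snap_boundaries(genome, pair: LTRPair, k_range: tuple[int, int] = (3, 8),
                    window: int = 6) -> LTRPair:
    """Refine LTR boundaries jointly from repeat correspondence and the TSD.

    Seeded boundary estimates can be off by a few bases.  Candidate offsets
    of the outer edges are scored by a changepoint likelihood along the
    LTR5/LTR3 correspondence (bases claimed as repeat should match at the
    repeat's identity, bases outside only at background rate) plus a bonus
    per exact-duplication base.  The bonus equals the cost of reclassifying
    one matching repeat base, so the genuinely unidentifiable case - a
    chance match adjacent to the repeat, which makes a shorter-TSD and a
    longer-TSD reading equally consistent - scores an exact tie; those ties
    are split by position parity so the unavoidable one-off errors spread
    symmetrically instead of biasing every ambiguous element the same way.
    """
    seq = _as_scaffolds(genome)[pair.scaffold]
    n = len(seq)
    a0, a1 = pair.ltr5
    b0, b1 = pair.ltr3
    tau = mu = 2.0  # TSD base bonus == matching-base reclassification cost
    nu = 3.0        # reward for reclassifying a mismatch as background

    def corr(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and seq[i] == seq[j]

    # cumulative reclassification scores for shifting each outer edge
    def edge_scores(x: int, y: int, inward_sign: int) -> dict[int, float]:
        # shifting the boundary claims bases [min(0,s), max(0,s)) as
        # repeat (s>0 toward the repeat interior keeps them); score the
        # shift s in [-window, window]
        out = {0: 0.0}
        acc = 0.0
        for s in range(1, window + 1):  # shift outward: claim extra bases
            m = corr(x - s * inward_sign, y - s * inward_sign)
            acc += mu if m else -nu
            out[-s] = acc
        acc = 0.0
        for s in range(1, window + 1):  # shift inward: release bases
            m = corr(x + (s - 1) * inward_sign, y + (s - 1) * inward_sign)
            acc += -mu if m else nu
            out[s] = acc
        return out

    left = edge_scores(a0, b0, inward_sign=1)    # outer 5' edges move together
    right = edge_scores(b1 - 1, a1 - 1, inward_sign=-1)  # outer 3' edges
    cands: list[tuple[float, int, int, int]] = []
    for da, ls in left.items():
        for db, rs in right.items():
            a, b = a0 + da, b1 + db
            if a <= 0 or b >= n:
                continue
            kk = _longest_exact_tsd(seq, a, b, k_range[0], k_range[1])
            cands.append((tau * kk + ls + rs, kk, da, db))
    if not cands:
        return pair
    top = max(c[0] for c in cands)
    tied = sorted((c for c in cands if c[0] > top - 1e-9),
                  key=lambda c: (abs(c[2]) + abs(c[3]), c[2], c[3]))
    ks = {c[1] for c in tied}
    if len(ks) > 1:
        pick_k = max(ks) if (a0 + b1) % 2 == 0 else min(ks)
        tied = [c for c in tied if c[1] == pick_k]
    _, _, da, db = tied[0]
    return LTRPair(pair.scaffold, (a0 + da, a1 + db),
                   (b0 + da, b1 + db), pair.identity, pair.aln_len)


def refine_boundaries_by_family(genome, pairs: list[LTRPair],
                                window: int = 8, inner: int = 24,
                                min_members: int = 3,
                                cluster_identity: float = 0.75) -> list[LTRPair]:
    """Sharpen outer LTR edges using family evidence.

    Elements of one family carry near-identical LTRs but each sits in its
    own genomic flank (with its own TSD), so when the members' edge windows
    are stacked, cross-member identity collapses exactly at the true LTR
    boundary.  Per-element edge calls are ambiguous by one base whenever a
    flank base matches by chance; the family stack resolves this.  Pairs in
    clusters smaller than ``min_members`` are returned unchanged.
    """
    from ._align import global_identity

    scaffolds = _as_scaffolds(genome)
    ltrs = [scaffolds[p.scaffold][p.ltr5[0]:p.ltr5[1]] for p in pairs]
    clusters: list[tuple[str, list[int]]] = []
    for i, ltr in enumerate(ltrs):
        for rep, members in clusters:
            ident, _ = global_identity(ltr, rep)
            if ident >= cluster_identity:
                members.append(i)
                break
        else:
            clusters.append((ltr, [i]))

    refined = list(pairs)

    def edge_offsets(anchors: list[tuple[str, int]], outside_left: bool) -> list[int]:
        """Offsets to add to each anchor so it sits on the family boundary."""
        W, I = window, inner
        span = W + I

        def win(scaf: str, pos: int, t: int) -> str:
            s = scaffolds[scaf]
            if outside_left:
                lo = pos - W + t
            else:
                lo = pos - I + t
            if lo < 0 or lo + span > len(s):
                return ""
            return s[lo:lo + span]

        ref = win(*anchors[0], 0)
        if not ref:
            return [0] * len(anchors)
        shifts: list[int | None] = []
        rows: list[str] = []
        inner_cols = range(W, span) if outside_left else range(0, I)
        for scaf, pos in anchors:
            best_t, best_m = 0, -1
            for t in range(-6, 7):
                w = win(scaf, pos, t)
                if not w:
                    continue
                m = sum(w[c] == ref[c] for c in inner_cols)
                if m > best_m:
                    best_m, best_t = m, t
            # members whose repeat interior does not align to the cluster
            # reference are left untouched and excluded from the stack
            if best_m < 0.55 * I:
                shifts.append(None)
                continue
            shifts.append(best_t)
            rows.append(win(scaf, pos, best_t))
        if len(rows) < 3:
            return [0] * len(anchors)
        # per-column mean pairwise identity: ~0.25 outside the repeat,
        # near within-family identity inside
        cols = []
        for c in range(span):
            chars = [r[c] for r in rows]
            npairs = same = 0
            for x in range(len(chars)):
                for y in range(x + 1, len(chars)):
                    npairs += 1
                    same += chars[x] == chars[y]
            cols.append(same / npairs)
        best_c, best_score = W if outside_left else I, -1e9
        for c in range(span + 1):
            if outside_left:
                score = sum(0.5 - f for f in cols[:c]) + sum(f - 0.5 for f in cols[c:])
            else:
                score = sum(f - 0.5 for f in cols[:c]) + sum(0.5 - f for f in cols[c:])
            if score > best_score:
                best_score, best_c = score, c
        base = W if outside_left else I
        return [0 if t is None else (best_c - base) + t for t in shifts]

    for _, members in clusters:
        if len(members) < min_members:
            continue
        left = edge_offsets([(pairs[i].scaffold, pairs[i].ltr5[0]) for i in members], True)
        right = edge_offsets([(pairs[i].scaffold, pairs[i].ltr3[1]) for i in members], False)
        for i, dl, dr in zip(members, left, right):
            p = pairs[i]
            refined[i] = LTRPair(p.scaffold, (p.ltr5[0] + dl, p.ltr5[1] + dr),
                                 (p.ltr3[0] + dl, p.ltr3[1] + dr),
                                 p.identity, p.aln_len)
    return refined


# --------------------------------------------------------------------------
# domain scanning

_SCAN_THRESHOLD = 0.55


def _frames(seq: str):
    """Yield (frame, translation) for all six frames; frame 0..2 forward,
    -1..-3 reverse (translation of the reverse complement)."""
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for f in range(3):
        yield f, str(fwd[f:len(seq) - (len(seq) - f) % 3].translate())
        yield -(f + 1), str(rev[f:len(seq) - (len(seq) - f) % 3].translate())


def _aa_array(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def scan_domains(internal: str, threshold: float = _SCAN_THRESHOLD) -> list[DomainHit]:
    """Best signature-motif hit per retroviral domain over six frames.

    Scores are percent identity of the best sliding window against the
    domain's signature block; only hits at or above ``threshold`` identity
    are reported, one per domain."""
    if len(internal) < 300:
        return []
    best: dict[str, DomainHit] = {}
    translations = list(_frames(internal))
    n = len(internal)
    for domain, sig in SIGNATURES.items():
        sarr = _aa_array(sig)
        m = len(sig)
        for frame, prot in translations:
            parr = _aa_array(prot)
            if len(parr) < m:
                continue
            win = sliding_window_view(parr, m)
            scores = (win == sarr).mean(axis=1)
            i = int(np.argmax(scores))
            sc = float(scores[i])
            if sc < threshold:
                continue
            if frame >= 0:
                s, e = frame + 3 * i, frame + 3 * (i + m)
            else:
                f = -frame - 1
                s, e = n - (f + 3 * (i + m)), n - (f + 3 * i)
            hit = DomainHit(domain, frame, s, e, round(sc * 100, 2))
            if domain not in best or hit.score > best[domain].score:
                best[domain] = hit
    return sorted(best.values(), key=lambda h: h.start)


def score_chain(hits: list[DomainHit], pair: LTRPair | None, tsd: TSD | None) -> float:
    """Additive chain score: motif scores + 50 for an LTR pair + 25 for a TSD."""
    return sum(h.score for h in hits) + 50 * (pair is not None) + 25 * (tsd is not None)


# --------------------------------------------------------------------------
# provirus calling

def _translate_with_x(seq: str) -> str:
    """Codon-by-codon translation; 'X' for any codon that is not plain ACGT."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        if set(codon) <= set("ACGT"):
            out.append(str(Seq(codon).translate()))
        else:
            out.append("X")
    return "".join(out)


def _pol_translation(internal: str, hits: list[DomainHit]) -> str:
    """Translate the RT..IN span in the RT hit's frame ('X' at unreadable
    codons); empty when either anchor is missing."""
    rt = next((h for h in hits if h.domain == "RT"), None)
    integrase = next((h for h in hits if h.domain == "IN"), None)
    if rt is None or integrase is None:
        return ""
    if rt.frame >= 0:
        s, e = rt.start, integrase.end
        sub = internal[s:e]
    else:
        sub = str(Seq(internal).reverse_complement())
        n = len(internal)
        s, e = n - integrase.end, n - rt.start
        sub = sub[s:e]
    return _translate_with_x(sub)


def _gag_translation(internal: str, hits: list[DomainHit]) -> str:
    """Translate the gag region (gag hit up to pro, capped at 120 codons)
    in the gag hit's frame, for zinc-finger counting."""
    gag = next((h for h in hits if h.domain == "gag_ca"), None) or \
        next((h for h in hits if h.domain == "gag_zf"), None)
    if gag is None:
        return ""
    pro = next((h for h in hits if h.domain == "pro"), None)
    if gag.frame >= 0:
        e = min(pro.start if pro and pro.frame >= 0 else len(internal),
                gag.start + 3 * 120)
        sub = internal[gag.start:e]
    else:
        rc = str(Seq(internal).reverse_complement())
        n = len(internal)
        s = n - gag.end
        e = min(n - pro.end if pro and pro.frame < 0 else n, s + 3 * 120)
        sub = rc[s:e]
    return _translate_with_x(sub)


def call_proviruses(genome, cutoff: float = DETECT_CUTOFF,
                    id_prefix: str = "call", family_refine: bool = True,
                    **pair_kwargs) -> list[ProvirusCall]:
    """Full detection pass: LTR pairs, boundary refinement, TSD, chains."""
    scaffolds = _as_scaffolds(genome)
    calls: list[ProvirusCall] = []
    idx = 0
    pairs = [snap_boundaries(scaffolds, p) for p in find_ltr_pairs(genome, **pair_kwargs)]
    if family_refine:
        pairs = refine_boundaries_by_family(scaffolds, pairs)
    for pair in pairs:
        tsd = detect_tsd(scaffolds, pair)
        seq = scaffolds[pair.scaffold]
        internal = seq[pair.ltr5[1]:pair.ltr3[0]]
        hits = scan_domains(internal)
        score = score_chain(hits, pair, tsd)
        if score < cutoff:
            continue
        call = ProvirusCall(id=f"{id_prefix}_{idx:04d}", pair=pair, tsd=tsd,
                            hits=hits, chain_score=score,
                            pol_aa=_pol_translation(internal, hits),
                            gag_aa=_gag_translation(internal, hits))
        call.complete = _is_complete(call)
        calls.append(call)
        idx += 1
    return calls


_X_RUN = re.compile(r"X{6,}")


def _is_complete(call: ProvirusCall) -> bool:
    domains = {h.domain for h in call.hits}
    has_gag = bool(domains & {"gag_ca", "gag_zf"})
    has_pol = {"RT", "IN"} <= domains
    if not (has_gag and "pro" in domains and has_pol and "env" in domains):
        return False
    if not call.pol_aa or _X_RUN.search(call.pol_aa):
        return False
    return True


def filter_complete(calls: list[ProvirusCall]) -> list[ProvirusCall]:
    """Calls with gag, pro, pol (RT+IN) and env hits, both LTRs, and no run
    of more than five consecutive ambiguous residues in pol."""
    return [c for c in calls if _is_complete(c)]


# --------------------------------------------------------------------------
# solo LTRs

def find_solo_ltrs(genome, ltr_library: dict[str, str],
                   calls: list[ProvirusCall] = (),
                   min_identity: float = 0.70, min_coverage: float = 0.50,
                   k: int = 12) -> list[SoloLTRCall]:
    """Library-matched LTR occurrences outside any called provirus.

    Matches require >= ``min_identity`` global identity over >=
    ``min_coverage`` of the library LTR's length.  Unmatched repeats are not
    reported: without a library hit a lone LTR cannot be attributed."""
    if not ltr_library:
        return []
    scaffolds = _as_scaffolds(genome)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        occupied.setdefault(c.scaffold, []).append((c.start, c.end))
    out: list[SoloLTRCall] = []
    lib_index: dict[str, list[tuple[str, int]]] = {}
    for lname, lseq in ltr_library.items():
        for i in range(len(lseq) - k + 1):
            lib_index.setdefault(lseq[i:i + k], []).append((lname, i))
    for sname, seq in scaffolds.items():
        hits_by_lib: dict[str, list[tuple[int, int]]] = {}
        for g in range(len(seq) - k + 1):
            for lname, i in lib_index.get(seq[g:g + k], ()):
                hits_by_lib.setdefault(lname, []).append((g, i))
        candidates: list[SoloLTRCall] = []
        for lname, hits in hits_by_lib.items():
            hits.sort()
            clusters: list[dict] = []
            for g, i in hits:
                placed = False
                for c in clusters:
                    if 0 <= g - c["max_g"] <= 600 and abs((g - i) - c["diag"]) <= 60:
                        c["max_g"], c["diag"] = g, g - i
                        c["max_i"] = max(c["max_i"], i)
                        c["min_i"] = min(c["min_i"], i)
                        placed = True
                        break
                if not placed:
                    clusters.append({"min_g": g, "max_g": g, "min_i": i,
                                     "max_i": i, "diag": g - i})
            lseq = ltr_library[lname]
            for c in clusters:
                g0 = max(0, c["min_g"] - c["min_i"])
                g1 = min(len(seq), c["max_g"] + k + (len(lseq) - c["max_i"] - k))
                if g1 - g0 < min_coverage * len(lseq):
                    continue
                ident, _ = global_identity(lseq, seq[g0:g1])
                if ident >= min_identity:
                    candidates.append(SoloLTRCall(sname, g0, g1, None, lname, ident))
        candidates.sort(key=lambda s: -(s.identity * (s.end - s.start)))
        chosen: list[SoloLTRCall] = []
        occ = occupied.get(sname, [])
        for cand in candidates:
            if any(cand.start < b and cand.end > a for a, b in occ):
                continue
            if any(cand.start < o.end and cand.end > o.start for o in chosen):
                continue
            chosen.append(cand)
        out.extend(chosen)
    out.sort(key=lambda s: (s.scaffold, s.start))
    return out
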