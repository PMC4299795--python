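"""Host-gene captures inside proviruses and selection tests on them.

Two capture architectures are recognised: a host-derived ORF inserted
between pol and env with the retroviral domains intact (the KIT-ligand
pattern), and a host-derived ORF replacing the envelope gene (the nectin3
pattern).  Captured ORFs kept intact across copies are candidates for
purifying selection, tested with the codon-based Z test on Nei-Gojobori
(proportion-method) synonymous/nonsynonymous distances: Z = (dS - dN) /
sqrt(Var(dS) + Var(dN)), variances from a codon-site bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table as _SDT
from Bio.Seq import Seq

from .consensus import center_star_align
from .detect import ProvirusCall

GAP = "-"
STOPS = set(_SDT.stop_codons)
_BASES = "ACGT"
SENSE_CODONS = sorted(set(_SDT.forward_table) )
_AA = dict(_SDT.forward_table)


# --------------------------------------------------------------------------
# Nei-Gojobori machinery (precomputed lookup tables)

def _codon_sites(codon: str) -> tuple[float, float]:
    """Potential synonymous / nonsynonymous sites: one third of the
    single-mutation neighbours of each kind, stop neighbours excluded, so
    S + N = 3 x (1 - stop-neighbour fraction)."""
    syn = non = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOPS:
                continue
            if _AA[alt] == _AA[codon]:
                syn += 1
            else:
                non += 1
    return syn / 3.0, non / 3.0


def _pair_differences(a: str, b: str) -> tuple[float, float]:
    """Observed synonymous / nonsynonymous differences between two sense
    codons, averaged over all minimal mutational pathways that avoid stop
    codons (all pathways, if every one passes through a stop)."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                blocked = True
                break
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in paths]
    sd = float(np.mean([p[0] for p in open_paths]))
    nd = float(np.mean([p[1] for p in open_paths]))
    # pathways through stops shed steps; renormalise to the full difference count
    total = sd + nd
    if total and total != len(diff):
        sd, nd = sd * len(diff) / total, nd * len(diff) / total
    return sd, nd


_SITES = {c: _codon_sites(c) for c in SENSE_CODONS}
_DIFFS: dict[tuple[str, str], tuple[float, float]] = {}


def _diffs(a: str, b: str) -> tuple[float, float]:
    key = (a, b) if a <= b else (b, a)
    if key not in _DIFFS:
        _DIFFS[key] = _pair_differences(*key)
    return _DIFFS[key]


def _codon_columns(rows: list[str]) -> list[list[str]]:
    """Gap-free, stop-free codon columns shared by all rows."""
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be aligned")
    ncol = len(rows[0]) // 3
    cols = []
    for c in range(ncol):
        codons = [r[3 * c:3 * c + 3] for r in rows]
        if any(set(cd) - set(_BASES) for cd in codons):
            continue
        if any(cd in STOPS for cd in codons):
            raise ValueError("alignment contains internal stop codons")
        cols.append(codons)
    return cols


def nei_gojobori_dnds(rows: list[str]) -> tuple[float, float, dict]:
    """Nei-Gojobori proportion-method dN and dS for a codon alignment.

    Pairwise Nd/N and Sd/S are averaged over all sequence pairs (no
    distance correction).  Returns (dN, dS, info) with per-pair sums in
    ``info``."""
    cols = _codon_columns(rows)
    if not cols:
        raise ValueError("no comparable codon columns")
    n = len(rows)
    if n < 2:
        raise ValueError("need at least two sequences")
    dn_list, ds_list = [], []
    for i, j in itertools.combinations(range(n), 2):
        Sd = Nd = S = N = 0.0
        for codons in cols:
            a, b = codons[i], codons[j]
            sa, na = _SITES[a]
            sb, nb = _SITES[b]
            S += (sa + sb) / 2
            N += (na + nb) / 2
            sd, nd = _diffs(a, b)
            Sd += sd
            Nd += nd
        ds_list.append(Sd / S if S else 0.0)
        dn_list.append(Nd / N if N else 0.0)
    info = {"n_codons": len(cols), "n_pairs": len(dn_list)}
    return float(np.mean(dn_list)), float(np.mean(ds_list)), info


@dataclass
class SelectionTestResult:
    dN: float
    dS: float
    var_dN: float
    var_dS: float
    z: float | None
    p: float | None
    n_codons: int
    alternative: str
    applicable: bool = True


def codon_z_test(rows: list[str], alternative: str = "purifying",
                 n_boot: int = 1000, seed: int = 0) -> SelectionTestResult:
    """Codon-based Z test of selection on a codon alignment.

    ``purifying`` tests dS > dN one-tailed; ``positive`` tests dN > dS;
    ``neutral-reject`` is two-tailed.  Variances come from resampling codon
    sites ``n_boot`` times.  Alignments with no differences at all are
    flagged not applicable."""
    if alternative not in ("purifying", "positive", "neutral-reject"):
        raise ValueError(f"unknown alternative {alternative!r}")
    cols = _codon_columns(rows)
    ncod = len(cols)
    if ncod < 30:
        raise ValueError("fewer than 30 comparable codons")
    n = len(rows)
    pairs = list(itertools.combinations(range(n), 2))
    npairs = len(pairs)
    sd = np.zeros((npairs, ncod))
    nd = np.zeros((npairs, ncod))
    s = np.zeros((npairs, ncod))
    nn = np.zeros((npairs, ncod))
    for c, codons in enumerate(cols):
        for p, (i, j) in enumerate(pairs):
            a, b = codons[i], codons[j]
            sa, na = _SITES[a]
            sb, nb = _SITES[b]
            s[p, c] = (sa + sb) / 2
            nn[p, c] = (na + nb) / 2
            sd[p, c], nd[p, c] = _diffs(a, b)

    dS = float(np.mean(sd.sum(axis=1) / s.sum(axis=1)))
    dN = float(np.mean(nd.sum(axis=1) / nn.sum(axis=1)))
    if not sd.sum() and not nd.sum():
        return SelectionTestResult(dN, dS, 0.0, 0.0, None, None, ncod,
                                   alternative, applicable=False)
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(ncod, np.full(ncod, 1.0 / ncod), size=n_boot)
    with np.errstate(invalid="ignore", divide="ignore"):
        ds_b = np.nanmean((weights @ sd.T) / (weights @ s.T), axis=1)
        dn_b = np.nanmean((weights @ nd.T) / (weights @ nn.T), axis=1)
    var_ds = float(np.nanvar(ds_b, ddof=1))
    var_dn = float(np.nanvar(dn_b, ddof=1))
    se = np.sqrt(var_ds + var_dn)
    if se == 0:
        return SelectionTestResult(dN, dS, var_dn, var_ds, None, None, ncod,
                                   alternative, applicable=False)
    if alternative == "purifying":
        z = (dS - dN) / se
        p = float(norm.sf(z))
    elif alternative == "positive":
        z = (dN - dS) / se
        p = float(norm.sf(z))
    else:
        z = (dS - dN) / se
        p = float(2 * norm.sf(abs(z)))
    return SelectionTestResult(dN, dS, var_dn, var_ds, float(z), p, ncod, alternative)


# --------------------------------------------------------------------------
# capture detection

@dataclass
class CaptureEvent:
    provirus_id: str
    start: int  # nt, internal-sequence coordinates
    end: int
    frame: int
    host_id: str
    identity: float
    coverage: float
    mode: str  # "between_pol_env" | "replacing_env"
    orf_aa: str = ""
    orf_nt: str = ""


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _orfs(internal: str, min_codons: int):
    """ATG-initiated ORFs of >= ``min_codons`` codons in all six frames;
    yields (start, end, frame, aa, nt) in forward internal coordinates."""
    n = len(internal)
    rc = str(Seq(internal).reverse_complement())
    for strand, seq in ((1, internal), (-1, rc)):
        for f in range(3):
            aa = str(Seq(seq[f:n - (n - f) % 3]).translate())
            start = None
            for i, ch in enumerate(aa + "*"):
                if ch == "M" and start is None:
                    start = i
                elif ch == "*" and start is not None:
                    if i - start >= min_codons:
                        s_nt, e_nt = f + 3 * start, f + 3 * (i + 1)
                        if strand == 1:
                            yield s_nt, e_nt, f, aa[start:i], seq[s_nt:e_nt]
                        else:
                            yield n - e_nt, n - s_nt, -(f + 1), aa[start:i], seq[s_nt:e_nt]
                    start = None


def detect_capture(call: ProvirusCall, internal: str, hosts: dict[str, str],
                   min_codons: int = 80, min_identity: float = 0.40,
                   min_coverage: float = 0.60) -> list[CaptureEvent]:
    """Host-gene-derived ORFs inside a provirus.

    ORFs of >= 80 codons that do not overlap retroviral domain hits are
    aligned (local, BLOSUM62) against the host protein set; hits at >= 40%
    identity over >= 60% of the host protein become capture events.  Mode
    is ``replacing_env`` when the provirus has no env hit, otherwise
    ``between_pol_env``."""
    if not hosts:
        raise ValueError("empty host protein set")
    aligner = _protein_aligner()
    domain_spans = [(h.start, h.end) for h in call.hits]
    env_present = call.hit("env") is not None
    out: list[CaptureEvent] = []
    for s, e, frame, aa, nt in _orfs(internal, min_codons):
        if any(s < de and e > ds for ds, de in domain_spans):
            continue
        best = None
        for hid, hseq in hosts.items():
            alns = aligner.align(aa, hseq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            counts = aln.counts()
            alen = counts.aligned
            ident = counts.identities / alen if alen else 0.0
            hspan = aln.aligned[1]
            cov = sum(b - a for a, b in hspan) / len(hseq)
            if ident >= min_identity and cov >= min_coverage:
                if best is None or ident * cov > best[0]:
                    best = (ident * cov, hid, ident, cov)
        if best is None:
            continue
        _, hid, ident, cov = best
        mode = "between_pol_env" if env_present else "replacing_env"
        out.append(CaptureEvent(call.id, s, e, frame, hid, round(ident, 4),
                                round(cov, 4), mode, orf_aa=aa, orf_nt=nt))
    # keep the single best ORF per host hit region
    out.sort(key=lambda ev: -(ev.identity * ev.coverage))
    chosen: list[CaptureEvent] = []
    for ev in out:
        if all(ev.end <= c.start or ev.start >= c.end for c in chosen):
            chosen.append(ev)
    chosen.sort(key=lambda ev: ev.start)
    return chosen


# --------------------------------------------------------------------------
# captured-ORF alignment utilities

@dataclass
class InframeIndel:
    row_id: str
    column: int  # nt column of the gap start
    codons: int
    context: str  # flanking peptide context of the ungapped partner


@dataclass
class IndelReport:
    in_frame: list[InframeIndel] = field(default_factory=list)
    frame_disrupting: list[InframeIndel] = field(default_factory=list)


def codon_align(ids: list[str], orf_nts: list[str]) -> tuple[list[str], list[str]]:
    """Codon-aware alignment: align translations, then expand each residue
    to its codon and each gap to '---'."""
    aas = [str(Seq(nt[:len(nt) - len(nt) % 3]).translate()).rstrip("*") for nt in orf_nts]
    if any("*" in aa for aa in aas):
        raise ValueError("ORF contains an internal stop")
    aln = center_star_align(ids, aas)
    rows = []
    for aa_row, nt in zip(aln.rows, orf_nts):
        out = []
        k = 0
        for ch in aa_row:
            if ch == GAP:
                out.append(GAP * 3)
            else:
                out.append(nt[3 * k:3 * k + 3])
                k += 1
        rows.append("".join(out))
    return aln.ids, rows


def find_inframe_indels(ids: list[str], rows: list[str]) -> IndelReport:
    """Gap runs in a codon alignment, split into in-frame (length a
    multiple of three) and frame-disrupting runs, with flanking peptide
    context from an ungapped row."""
    if len(rows) < 2:
        raise ValueError("need at least two aligned ORFs")
    report = IndelReport()
    width = len(rows[0])
    for rid, row in zip(ids, rows):
        i = 0
        while i < width:
            if row[i] != GAP:
                i += 1
                continue
            j = i
            while j < width and row[j] == GAP:
                j += 1
            partner = next((r for r in rows if GAP not in r[i:j]), None)
            context = ""
            if partner is not None:
                lo, hi = max(0, i - 12), min(width, j + 12)
                context = str(Seq(partner[i:j].replace(GAP, "")).translate()) \
                    if (j - i) % 3 == 0 else ""
                if not context:
                    context = partner[lo:hi]
            entry = InframeIndel(rid, i, (j - i) // 3, context)
            if (j - i) % 3 == 0:
                report.in_frame.append(entry)
            else:
                report.frame_disrupting.append(entry)
            i = j
    return report


# --------------------------------------------------------------------------
# codon-evolution simulator (for calibration and power studies)

def simulate_codon_alignment(n_seqs: int, n_codons: int, subs_per_site: float,
                             omega: float = 1.0, seed: int = 0) -> list[str]:
    """Star-phylogeny codon evolution from a random sense-codon ancestor.

    Each sequence independently receives Poisson(subs_per_site * 3 *
    n_codons) substitution attempts; mutations creating stop codons are
    rejected and nonsynonymous changes are accepted with probability
    ``omega`` - omega 1 is the neutral null, omega < 1 purifying
    selection."""
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    rows = []
    for _ in range(n_seqs):
        seq = list("".join(codons))
        n_events = rng.poisson(subs_per_site * 3 * n_codons)
        for _ in range(n_events):
            pos = int(rng.integers(0, 3 * n_codons))
            old = seq[pos]
            new = _BASES[rng.integers(4)]
            if new == old:
                continue
            ci = pos // 3
            codon = "".join(seq[3 * ci:3 * ci + 3])
            trial = codon[:pos % 3] + new + codon[pos % 3 + 1:]
            if trial in STOPS:
                continue
            if _AA[trial] != _AA[codon] and rng.random() >= omega:
                continue
            seq[pos] = new
        rows.append("".join(seq))
    return rows
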