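"""Orthologous insertions between two genomes, from flanking sequence.

An insertion shared by two species at the homologous site proves it
predates their divergence.  Candidates are paired by reciprocal-best
flanking-sequence similarity: 500 bp of unambiguous, non-repetitive
sequence is taken from either side of each call (outside the TSD), and a
pair is accepted when both flanks align at >= 80% global identity.
Group-level species distributions are cross-checked against LTR-based age
estimates: a group present in species that diverged T_div My ago cannot be
younger than T_div.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import global_identity
from .detect import ProvirusCall, _as_scaffolds

FLANK_LEN = 500
IDENTITY_THRESHOLD = 0.80

# species divergence priors (My): alligator lineage vs crocodile/gharial
# 97-103 My, crocodile vs gharial 47-49 My; minima used for flagging
DEFAULT_DIVERGENCE_MY = {
    frozenset({"alligator", "crocodile"}): 97.0,
    frozenset({"alligator", "gharial"}): 97.0,
    frozenset({"crocodile", "gharial"}): 47.0,
}


@dataclass
class FlankPair:
    call_id: str
    upstream: str
    downstream: str
    usable: bool
    reason: str | None = None


@dataclass
class OrthologCall:
    id_a: str
    id_b: str
    upstream_identity: float
    downstream_identity: float
    accepted: bool


def extract_flanks(genome, call: ProvirusCall, flank_len: int = FLANK_LEN,
                   erv_library: dict[str, str] | None = None,
                   max_n_fraction: float = 0.05) -> FlankPair:
    """Flanks taken immediately outside the TSD; unusable when truncated by
    a scaffold edge, too ambiguous, or matching the ERV/LTR library
    (the non-repetitive requirement)."""
    seq = _as_scaffolds(genome)[call.scaffold]
    t = call.tsd.length if call.tsd else 0
    lo = call.start - t - flank_len
    hi = call.end + t + flank_len
    if lo < 0 or hi > len(seq):
        return FlankPair(call.id, "", "", False, "scaffold_edge")
    up = seq[lo:call.start - t]
    down = seq[call.end + t:hi]
    for flank in (up, down):
        if flank.count("N") / flank_len > max_n_fraction:
            return FlankPair(call.id, up, down, False, "ambiguous")
    if erv_library:
        from .detect import find_solo_ltrs
        for name, flank in (("up", up), ("down", down)):
            hits = find_solo_ltrs({"f": flank}, erv_library)
            if hits:
                return FlankPair(call.id, up, down, False, "repetitive")
    return FlankPair(call.id, up, down, True)


def call_orthologs(calls_a: list[ProvirusCall], calls_b: list[ProvirusCall],
                   genome_a, genome_b, threshold: float = IDENTITY_THRESHOLD,
                   flank_len: int = FLANK_LEN,
                   erv_library: dict[str, str] | None = None) -> list[OrthologCall]:
    """One-to-one ortholog calls by reciprocal-best flank similarity.

    Both the upstream and the downstream flank must reach ``threshold``
    global-alignment identity (stricter than averaging the two)."""
    flanks_a = [extract_flanks(genome_a, c, flank_len, erv_library) for c in calls_a]
    flanks_b = [extract_flanks(genome_b, c, flank_len, erv_library) for c in calls_b]
    flanks_a = [f for f in flanks_a if f.usable]
    flanks_b = [f for f in flanks_b if f.usable]
    scored: list[tuple[float, float, float, str, str]] = []
    for fa in flanks_a:
        for fb in flanks_b:
            up, _ = global_identity(fa.upstream, fb.upstream)
            down, _ = global_identity(fa.downstream, fb.downstream)
            scored.append((up + down, up, down, fa.call_id, fb.call_id))
    scored.sort(key=lambda x: (-x[0], x[3], x[4]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    out: list[OrthologCall] = []
    for total, up, down, ida, idb in scored:
        if ida in used_a or idb in used_b:
            continue
        accepted = up >= threshold and down >= threshold
        if not accepted:
            continue
        used_a.add(ida)
        used_b.add(idb)
        out.append(OrthologCall(ida, idb, up, down, True))
    out.sort(key=lambda o: (o.id_a, o.id_b))
    return out


def crosscheck_distribution_age(groups, divergence_my: dict | None = None) -> list[dict]:
    """Flag groups whose LTR-based age is younger than the divergence of
    the species they span.

    ``groups`` is an iterable of objects with ``group_id``, ``species``
    (set) and ``age`` (AgeEstimate or None).  Returns one record per group
    with the minimum required age and a ``flagged`` boolean."""
    table = {frozenset(k): v for k, v in (divergence_my or DEFAULT_DIVERGENCE_MY).items()}
    out = []
    for g in groups:
        required = 0.0
        for pair, t_my in table.items():
            if pair <= frozenset(g.species):
                required = max(required, t_my)
        age_my = g.age.T_my if g.age is not None else None
        flagged = (required > 0 and age_my is not None and age_my < required)
        out.append({"group_id": g.group_id, "species": sorted(g.species),
                    "age_my": age_my, "required_my": required, "flagged": flagged})
    return out
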