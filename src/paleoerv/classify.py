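"""ERV class assignment (ERV1/ERV2/ERV3/ERV4).

Structural assignment scores a call's feature vector - TSD length,
zinc-finger count in gag, GPY/F presence downstream of integrase, dUTPase
location, env presence - against the four class columns.  Classes III and
IV are structurally near-identical (class IV lacks dUTPase and keeps a
relatively intact env, but so do some class III lineages), so phylogenetic
placement of the pol/RT protein takes precedence whenever it is decisive.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import motifs
from .consensus import center_star_align
from .detect import ProvirusCall, DomainHit
from .grouping import DistanceMatrix, annotate_supports, bootstrap_supports, nj_tree

LABELS = motifs.ERV_CLASSES
AMBIGUOUS = "ambiguous"
INTERMEDIATE = "intermediate"
UNCLASSIFIED = "unclassified"


@dataclass
class ClassProfile:
    """Structural feature vector (Table-style class characteristics)."""

    tsd_length: int | None
    zinc_fingers: int
    gpy_f_present: bool
    dutpase_location: str | None  # None | "within_pro" | "downstream_of_IN"
    env_present: bool


@dataclass
class ClassCall:
    structural: str
    phylogenetic: str
    final: str
    notes: str = ""


# --------------------------------------------------------------------------
# feature extraction

def extract_class_features(call: ProvirusCall, internal_aa_by_frame=None) -> ClassProfile:
    """Read the structural feature vector off a detection call.

    Zinc fingers are counted as CCHC (C-x2-C-x4-H-x4-C) matches within the
    gag region (internal start up to the pro hit); dUTPase location is
    taken relative to the pro and integrase hits.  Missing features record
    as none/0 rather than errors."""
    tsd_len = call.tsd.length if call.tsd else None
    hits = {h.domain: h for h in call.hits}
    if call.gag_aa:
        zf = len(motifs.ZF_REGEX.findall(call.gag_aa))
    elif "gag_zf" in hits:
        zf = 1
    else:
        zf = 0
    dut = None
    if "dUTPase" in hits:
        d = hits["dUTPase"]
        pro, integrase = hits.get("pro"), hits.get("IN")
        if integrase is not None and _after(d, integrase):
            dut = "downstream_of_IN"
        elif pro is not None and _near(d, pro):
            dut = "within_pro"
        elif integrase is not None:
            dut = "within_pol"
        else:
            dut = "within_pro"
    return ClassProfile(
        tsd_length=tsd_len,
        zinc_fingers=min(zf, 2),
        gpy_f_present="GPY_F" in hits,
        dutpase_location=dut,
        env_present="env" in hits,
    )


def _after(a: DomainHit, b: DomainHit) -> bool:
    return a.start >= b.end if b.frame >= 0 else a.end <= b.start


def _near(a: DomainHit, b: DomainHit, window: int = 400) -> bool:
    return abs(a.start - b.start) <= window + (b.end - b.start)


# --------------------------------------------------------------------------
# structural rule

def classify_structural(profile: ClassProfile) -> str:
    """Score the profile against the four class columns; argmax label,
    ``ambiguous`` on ties or when two or fewer features match.

    dUTPase *absence* is weak evidence (half weight): some lineages have
    lost it, and non-primate lentiviral elements carry it within pol."""
    scores: dict[str, float] = {}
    for cls, feat in motifs.CLASS_TABLE.items():
        s = 0.0
        if profile.tsd_length is not None and profile.tsd_length == feat.tsd_length:
            s += 1.0
        if profile.zinc_fingers and feat.zinc_fingers:
            s += 1.0 if profile.zinc_fingers == feat.zinc_fingers or cls == "ERV1" else 0.5
        elif profile.zinc_fingers == 0 and feat.zinc_fingers == 0:
            s += 1.0
        if profile.gpy_f_present == feat.gpy_f_present:
            s += 1.0
        # dUTPase absence is uninformative (lineages lose it); only an
        # observed dUTPase scores, and its location splits classes II/III
        if profile.dutpase_location is not None and \
                profile.dutpase_location == feat.dutpase_location:
            s += 1.0
        if profile.env_present == feat.env_present:
            s += 1.0
        scores[cls] = s
    best = max(scores.values())
    winners = [c for c, s in scores.items() if s == best]
    matched = best
    if len(winners) != 1 or matched <= 2.0:
        return AMBIGUOUS
    return winners[0]


# --------------------------------------------------------------------------
# phylogenetic placement

def place_by_rt(rt_aa: str, panel: list[tuple[str, str, str]] | None = None,
                support_threshold: float = 0.70, n_reps: int = 200,
                seed: int = 0) -> str:
    """Class of the supported clade an RT query joins in an NJ tree built
    against a labelled reference panel; ``intermediate`` when no supported
    clade with a single panel class contains the query.

    The packaged panel carries three representatives per class plus two
    Gypsy-like outgroup sequences; any labelled panel can be substituted.
    """
    if len(rt_aa) < 100:
        raise ValueError("RT query shorter than 100 residues")
    panel = panel if panel is not None else motifs.rt_reference_panel()
    ids = ["query"] + [name for name, _, _ in panel]
    class_of = {name: cls for name, cls, _ in panel}
    seqs = [rt_aa] + [seq for _, _, seq in panel]
    aln = center_star_align(ids, seqs)
    supports = bootstrap_supports(aln.ids, aln.rows, n_reps=n_reps, seed=seed)
    dm = DistanceMatrix.from_alignment(aln.ids, aln.rows)
    tree = nj_tree(dm)
    annotate_supports(tree, supports)
    names = tree.leaf_names()
    best: tuple[int, str] | None = None
    for node in tree.walk():
        if node is tree or not node.children:
            continue
        side = node.leaf_names()
        for clade in (side, names - side):
            if "query" not in clade:
                continue
            members = clade - {"query"}
            if not members:
                continue
            key = min(side, names - side, key=lambda s: (len(s), tuple(sorted(s))))
            if supports.get(key, 0.0) <= support_threshold:
                continue
            classes = {class_of[m] for m in members}
            if len(classes) == 1 and "outgroup" not in classes:
                cand = (len(clade), classes.pop())
                if best is None or cand[0] < best[0]:
                    best = cand
    return best[1] if best else INTERMEDIATE


# --------------------------------------------------------------------------
# final call

def assign_class(structural: str, phylogenetic: str) -> ClassCall:
    """Phylogeny takes precedence unless it is ``intermediate``; then the
    structural label, unless ambiguous; else ``unclassified``."""
    if phylogenetic not in (INTERMEDIATE,):
        final = phylogenetic
        note = "phylogenetic placement decisive"
    elif structural != AMBIGUOUS:
        final = structural
        note = "phylogeny unresolved; structural features decisive"
    else:
        final = UNCLASSIFIED
        note = "neither phylogeny nor structure decisive"
    return ClassCall(structural=structural, phylogenetic=phylogenetic,
                     final=final, notes=note)
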