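"""Synthetic genomes with planted LTR proviruses and a ground-truth ledger.

Genomes are i.i.d. background sequence into which complete proviruses
(LTR5 + gag/pro/pol/env + LTR3), solo LTRs, orthologous insertions shared
between a species pair, and host-gene captures are planted.  Every planted
element is recorded in a machine-readable truth ledger so that detection,
grouping, dating, orthology and capture calling can be scored against known
answers.

Age is encoded as LTR-LTR divergence: both LTRs descend from one ancestral
repeat and each accumulates Poisson(d/2) substitution events per site under
a Kimura two-parameter process, so re-measuring the pair with the K2P
estimator recovers d without bias.  Target-site duplications are exact at
planting time and use the class-specific lengths (4/6/5/5 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import motifs
from .motifs import CLASS_TABLE, SIGNATURES, reverse_translate

DNA = "ACGT"
_BASES = np.frombuffer(b"ACGT", dtype="S1")

CAPTURE_MODES = (None, "between_pol_env", "replacing_env")


# --------------------------------------------------------------------------
# configuration / truth types

@dataclass
class Degradation:
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    force_nonsense: bool = False


@dataclass
class InsertSpec:
    """One element to plant: class, age, decay, capture/solo status."""

    class_label: str
    age_divergence: float = 0.0
    degradation: Degradation = field(default_factory=Degradation)
    capture: str | None = None
    solo: bool = False
    family: int = 0
    capture_deletion_codons: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_TABLE:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if self.age_divergence < 0:
            raise ValueError("age_divergence must be >= 0")
        if self.capture not in CAPTURE_MODES:
            raise ValueError(f"unknown capture mode {self.capture!r}")
        if self.capture and self.solo:
            raise ValueError("capture modes are mutually exclusive with solo")


@dataclass
class SimulationConfig:
    genome_length: int
    gc_content: float = 0.44
    n_scaffolds: int = 1
    insert_specs: list[InsertSpec] = field(default_factory=list)
    seed: int = 0
    ltr_len: int = 400
    internal_len: int = 6000
    min_spacing: int = 1400

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10,000")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")


@dataclass
class PlantedTruth:
    """Simulator ledger entry for one planted element (0-based, half-open)."""

    element_id: str
    scaffold: str
    start: int
    end: int
    class_label: str
    tsd_sequence: str
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    true_divergence: float
    capture_mode: str | None = None
    ortholog_partner_id: str | None = None
    is_solo: bool = False
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)
    family: int = 0


@dataclass
class GenomeBuild:
    """A simulated genome plus its truth ledger and host protein set."""

    scaffolds: dict[str, str]
    truth: list[PlantedTruth]
    hosts: dict[str, str] = field(default_factory=motifs.host_proteins)
    species: str = "sim"

    def element(self, element_id: str) -> PlantedTruth:
        for t in self.truth:
            if t.element_id == element_id:
                return t
        raise KeyError(element_id)

    def element_seq(self, t: PlantedTruth) -> str:
        return self.scaffolds[t.scaffold][t.start:t.end]


# --------------------------------------------------------------------------
# elementary sequence operations

def generate_background(length: int, gc: float, seed=None) -> str:
    """I.i.d. background sequence with expected GC content ``gc``."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def mutate_k2p(seq: str, d: float, rng: np.random.Generator, kappa: float = 2.0) -> str:
    """Apply Poisson(d) K2P substitution events per site (transition:single
    transversion rate ratio ``kappa``); homoplasy is allowed, so ``d`` is the
    expected number of events per site, matching the K2P distance scale."""
    if d <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    counts = rng.poisson(d, size=len(arr))
    transition = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}
    transversions = {b"A": b"CT", b"G": b"CT", b"C": b"AG", b"T": b"AG"}
    p_ts = kappa / (kappa + 2.0)
    for i in np.nonzero(counts)[0]:
        for _ in range(counts[i]):
            b = bytes(arr[i])
            if rng.random() < p_ts:
                arr[i] = transition[b]
            else:
                tv = transversions[b]
                arr[i] = tv[rng.integers(2):][:1]
    return arr.tobytes().decode()


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Single-hit substitutions: each site changes to a different base with
    probability ``rate`` (no homoplasy)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def _apply_indels(seq: str, events: list[tuple[int, int, str]]):
    """Apply (position, signed length, insertion) events; return the edited
    sequence and an old->new coordinate map of length len(seq)+1."""
    n = len(seq)
    m = np.empty(n + 1, dtype=np.int64)
    out: list[str] = []
    cur = new = 0
    for pos, length, ins in sorted(events):
        if pos < cur:
            continue  # swallowed by an earlier deletion
        out.append(seq[cur:pos])
        m[cur:pos] = np.arange(new, new + pos - cur)
        new += pos - cur
        cur = pos
        if length < 0:
            dl = min(-length, n - pos)
            m[cur:cur + dl] = new
            cur += dl
        else:
            out.append(ins)
            new += length
    out.append(seq[cur:])
    m[cur:n] = np.arange(new, new + n - cur)
    new += n - cur
    m[n] = new
    return "".join(out), m


def degrade_with_map(seq: str, sub_rate: float, indel_rate: float,
                     rng: np.random.Generator, max_indel: int = 30):
    """Substitutions + geometric-length indels; returns (sequence, coordinate
    map) so that annotated spans can be carried through the edit."""
    if not 0 <= sub_rate < 1 or not 0 <= indel_rate < 1:
        raise ValueError("rates must lie in [0, 1)")
    seq = _substitute(seq, sub_rate, rng)
    events: list[tuple[int, int, str]] = []
    if indel_rate > 0:
        for i in np.nonzero(rng.random(len(seq)) < indel_rate)[0]:
            length = min(int(rng.geometric(0.5)), max_indel)
            if rng.random() < 0.5:
                events.append((int(i), -length, ""))
            else:
                ins = rng.choice(_BASES, size=length).tobytes().decode()
                events.append((int(i), length, ins))
    return _apply_indels(seq, events)


def _force_pol_stop(seq: str, pol_span: tuple[int, int], rng: np.random.Generator) -> str:
    """Write a TAA at a random internal codon of pol (frame anchored at the
    pol start) so the copy carries at least one premature stop."""
    s, e = pol_span
    ncod = (e - s) // 3
    k = int(rng.integers(10, max(11, ncod - 10)))
    pos = s + 3 * k
    return seq[:pos] + "TAA" + seq[pos + 3:]


def degrade(sequence: str, sub_rate: float, indel_rate: float = 0.0,
            force_nonsense: bool = False, seed=None,
            pol_span: tuple[int, int] | None = None) -> str:
    """Public degradation operator (see :func:`degrade_with_map`).

    ``force_nonsense`` requires ``pol_span`` (coordinates in the input) and
    guarantees a premature stop codon inside pol.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out, m = degrade_with_map(sequence, sub_rate, indel_rate, rng)
    if force_nonsense:
        if pol_span is None:
            raise ValueError("force_nonsense requires pol_span")
        out = _force_pol_stop(out, (int(m[pol_span[0]]), int(m[pol_span[1]])), rng)
    return out


# --------------------------------------------------------------------------
# provirus construction

@dataclass
class ProvirusSeq:
    seq: str
    class_label: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    domains: dict[str, tuple[int, int]]
    true_divergence: float
    capture_mode: str | None = None
    family: int = 0


@dataclass
class _FamilyAncestor:
    ltr: str
    internal: str
    domains: dict[str, tuple[int, int]]  # relative to internal start


class ProvirusFactory:
    """Builds proviruses; caches per-family ancestral sequences so that
    members of one family are recognisable descendants of one ancestor."""

    def __init__(self, seed: int, ltr_len: int = 400, internal_len: int = 6000,
                 family_divergence: float = 0.05):
        self.seed = int(seed)
        self.ltr_len = ltr_len
        self.internal_len = internal_len
        self.family_divergence = family_divergence
        self._families: dict[tuple, _FamilyAncestor] = {}
        self.hosts = motifs.host_proteins()

    # -- family ancestor ---------------------------------------------------

    def _gene(self, aa: str, rng) -> str:
        return "ATG" + reverse_translate(aa, rng) + "TAA"

    def _ancestor(self, spec: InsertSpec) -> _FamilyAncestor:
        key = (spec.class_label, spec.family, spec.capture)
        if key in self._families:
            return self._families[key]
        feat = CLASS_TABLE[spec.class_label]
        cls_i = motifs.ERV_CLASSES.index(spec.class_label)
        ss = np.random.SeedSequence((self.seed, 11, cls_i, spec.family))
        rng = np.random.default_rng(ss)
        cent = motifs.CLASS_CENTROIDS[spec.class_label]
        fd = self.family_divergence
        var = {k: motifs.mutate_protein(v, fd, rng) for k, v in cent.items()}
        rp = lambda n: motifs.random_protein(n, rng)

        # gag -------------------------------------------------------------
        gag_parts = [rp(15), SIGNATURES["gag_ca"], rp(10)]
        for _ in range(feat.zinc_fingers):
            gag_parts += [SIGNATURES["gag_zf"], rp(4)]
        gag_parts += [var["gag"], rp(10)]
        gag_aa = "".join(gag_parts)
        # pro -------------------------------------------------------------
        pro_parts = [rp(8), SIGNATURES["pro"]]
        if feat.dutpase_location == "within_pro":
            pro_parts += [rp(3), SIGNATURES["dUTPase"]]
        pro_parts += [var["pro"], rp(8)]
        pro_aa = "".join(pro_parts)
        # pol: RT (core+variable), RNaseH, IN, optional GPY/F and dUTPase --
        pre, mid1, mid2 = rp(10), rp(12), rp(10)
        rt_aa = motifs.RT_CORE + var["RT"]
        pol_parts = [pre, rt_aa, mid1, SIGNATURES["RNaseH"], mid2, SIGNATURES["IN"]]
        if feat.gpy_f_present:
            pol_parts += [rp(3), SIGNATURES["GPY_F"]]
        if feat.dutpase_location == "downstream_of_IN":
            pol_parts += [rp(3), SIGNATURES["dUTPase"]]
        pol_parts += [var["pol_tail"], rp(8)]
        pol_aa = "".join(pol_parts)
        # env -------------------------------------------------------------
        env_aa = rp(8) + SIGNATURES["env"] + var["env"] + rp(10)

        genes: list[tuple[str, str]] = [("gag", gag_aa), ("pro", pro_aa), ("pol", pol_aa)]
        if spec.capture == "between_pol_env":
            genes.append(("capture", self.hosts["kitlg_like"]))
            genes.append(("env", env_aa))
        elif spec.capture == "replacing_env":
            genes.append(("capture", self.hosts["nectin3_like"]))
        else:
            genes.append(("env", env_aa))

        gene_nt = [(name, self._gene(aa, rng)) for name, aa in genes]
        coding = sum(len(s) for _, s in gene_nt)
        n_spacers = len(gene_nt) + 1
        pad = max(self.internal_len - coding, 60 * n_spacers)
        cuts = np.sort(rng.integers(0, pad - 60 * n_spacers + 1, size=n_spacers - 1))
        spacer_lens = np.diff(np.concatenate(([0], cuts, [pad - 60 * n_spacers]))) + 60

        parts: list[str] = []
        domains: dict[str, tuple[int, int]] = {}
        pos = 0
        for i, (name, nt) in enumerate(gene_nt):
            sp = generate_background(int(spacer_lens[i]), 0.5, rng)
            parts.append(sp)
            pos += len(sp)
            domains[name] = (pos, pos + len(nt))
            if name == "pol":
                off = pos + 3  # past ATG
                rt_s = off + 3 * len(pre)
                domains["RT"] = (rt_s, rt_s + 3 * len(rt_aa))
                in_s = off + 3 * (len(pre) + len(rt_aa) + len(mid1) + len(SIGNATURES["RNaseH"]) + len(mid2))
                domains["IN"] = (in_s, in_s + 3 * len(SIGNATURES["IN"]))
            parts.append(nt)
            pos += len(nt)
        tail = generate_background(int(spacer_lens[-1]), 0.5, rng)
        parts.append(tail)
        internal = "".join(parts)
        ltr = generate_background(self.ltr_len, 0.5, rng)
        anc = _FamilyAncestor(ltr=ltr, internal=internal, domains=domains)
        self._families[key] = anc
        return anc

    # -- per-element build -------------------------------------------------

    def build(self, spec: InsertSpec, rng: np.random.Generator) -> ProvirusSeq:
        anc = self._ancestor(spec)
        d = spec.age_divergence
        ltr5 = mutate_k2p(anc.ltr, d / 2, rng)
        ltr3 = mutate_k2p(anc.ltr, d / 2, rng)
        internal = anc.internal
        domains = dict(anc.domains)

        if spec.capture_deletion_codons:
            cs, ce = domains["capture"]
            k = 3 * spec.capture_deletion_codons
            mid = cs + 3 + 3 * ((ce - cs - 6) // 6)  # codon boundary mid-ORF
            internal, m = _apply_indels(internal, [(mid, -k, "")])
            domains = {n: (int(m[a]), int(m[b])) for n, (a, b) in domains.items()}

        L = self.ltr_len
        seq = ltr5 + internal + ltr3
        domains = {n: (a + L, b + L) for n, (a, b) in domains.items()}
        deg = spec.degradation
        true_d = d
        if deg.sub_rate or deg.indel_rate or deg.force_nonsense:
            seq, m = degrade_with_map(seq, deg.sub_rate, deg.indel_rate, rng)
            domains = {n: (int(m[a]), int(m[b])) for n, (a, b) in domains.items()}
            ltr5_span = (0, int(m[L]))
            ltr3_span = (int(m[len(ltr5) + len(internal)]), len(seq))
            if deg.force_nonsense:
                seq = _force_pol_stop(seq, domains["pol"], rng)
            true_d = d + 2 * deg.sub_rate  # LTR decay adds to the age signal
        else:
            ltr5_span = (0, L)
            ltr3_span = (len(seq) - L, len(seq))
        return ProvirusSeq(seq=seq, class_label=spec.class_label, ltr5=ltr5_span,
                           ltr3=ltr3_span, domains=domains, true_divergence=true_d,
                           capture_mode=spec.capture, family=spec.family)


def build_provirus(spec: InsertSpec, seed: int) -> ProvirusSeq:
    """Build a single provirus from a fresh factory (convenience wrapper)."""
    factory = ProvirusFactory(seed)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 17)))
    return factory.build(spec, rng)


# --------------------------------------------------------------------------
# planting

def plant(scaffold: str, provirus: str, site: int, tsd_length: int,
          occupied: list[tuple[int, int]] | None = None):
    """Insert a provirus at ``site``, duplicating the ``tsd_length`` bases at
    the site so they flank the insertion on both sides.

    Returns (edited scaffold, element start, element end, tsd sequence) in
    0-based half-open coordinates on the edited scaffold.
    """
    if not 0 <= site <= len(scaffold) - tsd_length:
        raise ValueError("site outside scaffold")
    for a, b in occupied or ():
        if a <= site < b:
            raise ValueError("site lies within an existing planted element")
    tsd = scaffold[site:site + tsd_length]
    edited = scaffold[:site + tsd_length] + provirus + scaffold[site:]
    start = site + tsd_length
    return edited, start, start + len(provirus), tsd


def excise(scaffold: str, start: int, end: int, tsd_length: int) -> str:
    """Inverse of :func:`plant`: remove the element plus one TSD copy."""
    return scaffold[:start] + scaffold[end + tsd_length:]


def derive_solo_ltr(build: GenomeBuild, element_id: str) -> PlantedTruth:
    """Recombine a planted provirus down to a solo LTR.

    The internal region and one LTR are removed in place, leaving a single
    LTR flanked by the original TSD; downstream truth coordinates shift."""
    t = build.element(element_id)
    if t.is_solo:
        raise ValueError(f"{element_id} is already a solo LTR")
    seq = build.scaffolds[t.scaffold]
    a, b = t.ltr5
    ltr_seq = seq[a:b]
    delta = len(ltr_seq) - (t.end - t.start)
    build.scaffolds[t.scaffold] = seq[:t.start] + ltr_seq + seq[t.end:]
    for other in build.truth:
        if other.scaffold == t.scaffold and other.start > t.start:
            other.start += delta
            other.end += delta
            if other.ltr5:
                other.ltr5 = (other.ltr5[0] + delta, other.ltr5[1] + delta)
            if other.ltr3:
                other.ltr3 = (other.ltr3[0] + delta, other.ltr3[1] + delta)
            other.domains = {n: (x + delta, y + delta) for n, (x, y) in other.domains.items()}
    t.end = t.start + len(ltr_seq)
    t.ltr5 = (t.start, t.end)
    t.ltr3 = None
    t.domains = {}
    t.is_solo = True
    return t


# --------------------------------------------------------------------------
# whole-genome simulation

def _choose_sites(rng: np.random.Generator, length: int, k: int,
                  min_gap: int, edge: int) -> list[int]:
    avail = length - 2 * edge - (k - 1) * min_gap
    if k == 0:
        return []
    if avail <= k:
        raise ValueError("scaffold too short for the requested inserts")
    u = np.sort(rng.integers(0, avail, size=k))
    return [int(edge + u[i] + i * min_gap) for i in range(k)]


def simulate_genome(config: SimulationConfig, species: str = "sim") -> GenomeBuild:
    """Generate a genome per ``config`` and return it with its truth ledger."""
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 23)))
    factory = ProvirusFactory(config.seed, ltr_len=config.ltr_len,
                              internal_len=config.internal_len)
    scaf_len = config.genome_length // config.n_scaffolds
    per_scaf: list[list[InsertSpec]] = [[] for _ in range(config.n_scaffolds)]
    for i, spec in enumerate(config.insert_specs):
        per_scaf[i % config.n_scaffolds].append(spec)

    scaffolds: dict[str, str] = {}
    truth: list[PlantedTruth] = []
    counter = 0
    for si in range(config.n_scaffolds):
        name = f"scaffold_{si + 1}"
        bg = generate_background(scaf_len, config.gc_content, rng)
        specs = per_scaf[si]
        elements = []
        for spec in specs:
            pv = factory.build(spec, rng)
            elements.append((spec, pv))
        gap = config.min_spacing + max((len(p.seq) for _, p in elements), default=0)
        sites = _choose_sites(rng, scaf_len, len(elements), gap, 700)
        parts: list[str] = []
        pos = cur = 0
        for site, (spec, pv) in zip(sites, elements):
            tlen = CLASS_TABLE[spec.class_label].tsd_length
            tsd = bg[site:site + tlen]
            seg = bg[cur:site + tlen]
            parts.append(seg)
            pos += len(seg)
            start = pos
            if spec.solo:
                a, b = pv.ltr5
                ins = pv.seq[a:b]
                entry = PlantedTruth(
                    element_id=f"{species}_{si + 1}_{counter:03d}", scaffold=name,
                    start=start, end=start + len(ins), class_label=spec.class_label,
                    tsd_sequence=tsd, ltr5=(start, start + len(ins)), ltr3=None,
                    true_divergence=pv.true_divergence, is_solo=True, family=spec.family)
            else:
                ins = pv.seq
                off = start
                entry = PlantedTruth(
                    element_id=f"{species}_{si + 1}_{counter:03d}", scaffold=name,
                    start=start, end=start + len(ins), class_label=spec.class_label,
                    tsd_sequence=tsd,
                    ltr5=(off + pv.ltr5[0], off + pv.ltr5[1]),
                    ltr3=(off + pv.ltr3[0], off + pv.ltr3[1]),
                    true_divergence=pv.true_divergence,
                    capture_mode=pv.capture_mode, family=spec.family,
                    domains={n: (off + a, off + b) for n, (a, b) in pv.domains.items()})
            counter += 1
            parts.append(ins)
            pos += len(ins)
            parts.append(tsd)
            pos += tlen
            cur = site + tlen
            truth.append(entry)
        parts.append(bg[cur:])
        scaffolds[name] = "".join(parts)
    return GenomeBuild(scaffolds=scaffolds, truth=truth, species=species)


# --------------------------------------------------------------------------
# species pairs with orthologous insertions

@dataclass
class SpeciesPairConfig:
    genome_length: int
    shared: list[InsertSpec]
    specific_a: list[InsertSpec]
    specific_b: list[InsertSpec]
    flank_divergence: float = 0.05
    gc_content: float = 0.44
    seed: int = 0
    ltr_len: int = 400
    internal_len: int = 6000

    def __post_init__(self) -> None:
        if self.flank_divergence >= 0.5:
            raise ValueError("flank divergence >= 0.5 is no longer alignable")


def make_species_pair(config: SpeciesPairConfig,
                      names: tuple[str, str] = ("spA", "spB")):
    """Two genomes sharing orthologous insertions at homologous sites.

    Shared inserts are planted on a common ancestral background; each
    species' genome then accumulates single-hit substitutions at half the
    stated flank divergence, and lineage-specific inserts are planted on top.
    Truth ledgers cross-link ortholog partners.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 29)))
    factory = ProvirusFactory(config.seed, ltr_len=config.ltr_len,
                              internal_len=config.internal_len)
    L = config.genome_length
    bg = generate_background(L, config.gc_content, rng)
    shared = [(s, factory.build(s, rng)) for s in config.shared]
    spec_a = [(s, factory.build(s, rng)) for s in config.specific_a]
    spec_b = [(s, factory.build(s, rng)) for s in config.specific_b]

    n_total = len(shared) + len(spec_a) + len(spec_b)
    all_pv = shared + spec_a + spec_b
    gap = 1400 + max((len(p.seq) for _, p in all_pv), default=0)
    sites = _choose_sites(rng, L, n_total, gap, 700)
    rng.shuffle(site_idx := np.arange(n_total))
    site_of = {i: sites[j] for j, i in enumerate(site_idx)}
    shared_sites = [site_of[i] for i in range(len(shared))]
    a_sites = [site_of[len(shared) + i] for i in range(len(spec_a))]
    b_sites = [site_of[len(shared) + len(spec_a) + i] for i in range(len(spec_b))]

    def compose(species: str, extras, extra_sites):
        placements = sorted(
            [(site, spec, pv, True, i) for i, ((spec, pv), site) in enumerate(zip(shared, shared_sites))]
            + [(site, spec, pv, False, i) for i, ((spec, pv), site) in enumerate(zip(extras, extra_sites))])
        parts: list[str] = []
        truth: list[PlantedTruth] = []
        pos = cur = 0
        for k, (site, spec, pv, is_shared, idx) in enumerate(placements):
            tlen = CLASS_TABLE[spec.class_label].tsd_length
            tsd = bg[site:site + tlen]
            seg = bg[cur:site + tlen]
            parts.append(seg)
            pos += len(seg)
            start = pos
            eid = f"{species}_1_{k:03d}"
            oid = f"shared{idx}" if is_shared else None
            if spec.solo:
                a, b = pv.ltr5
                ins = pv.seq[a:b]
                truth.append(PlantedTruth(
                    element_id=eid, scaffold="scaffold_1", start=start,
                    end=start + len(ins), class_label=spec.class_label,
                    tsd_sequence=tsd, ltr5=(start, start + len(ins)), ltr3=None,
                    true_divergence=pv.true_divergence, is_solo=True,
                    ortholog_partner_id=oid, family=spec.family))
            else:
                ins = pv.seq
                truth.append(PlantedTruth(
                    element_id=eid, scaffold="scaffold_1", start=start,
                    end=start + len(ins), class_label=spec.class_label,
                    tsd_sequence=tsd,
                    ltr5=(start + pv.ltr5[0], start + pv.ltr5[1]),
                    ltr3=(start + pv.ltr3[0], start + pv.ltr3[1]),
                    true_divergence=pv.true_divergence + (config.flank_divergence if is_shared else 0.0),
                    capture_mode=pv.capture_mode, ortholog_partner_id=oid,
                    family=spec.family,
                    domains={n: (start + a, start + b) for n, (a, b) in pv.domains.items()}))
            parts.append(ins)
            pos += len(ins)
            parts.append(tsd)
            pos += tlen
            cur = site + tlen
        parts.append(bg[cur:])
        genome = _substitute("".join(parts), config.flank_divergence / 2, rng)
        return GenomeBuild(scaffolds={"scaffold_1": genome}, truth=truth, species=species)

    build_a = compose(names[0], spec_a, a_sites)
    build_b = compose(names[1], spec_b, b_sites)
    # resolve shared markers into partner element ids
    by_marker_b = {t.ortholog_partner_id: t.element_id for t in build_b.truth
                   if t.ortholog_partner_id}
    for t in build_a.truth:
        if t.ortholog_partner_id:
            marker = t.ortholog_partner_id
            t.ortholog_partner_id = by_marker_b[marker]
    by_marker_a = {t.element_id: t.ortholog_partner_id for t in build_a.truth
                   if t.ortholog_partner_id}
    inv = {v: k for k, v in by_marker_a.items()}
    for t in build_b.truth:
        if t.ortholog_partner_id:
            t.ortholog_partner_id = inv[t.element_id]
    return build_a, build_b
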