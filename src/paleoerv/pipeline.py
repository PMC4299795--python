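"""End-to-end orchestration: simulate/load -> detect -> consensus -> group
-> classify -> date -> orthologs -> capture -> summary.

A single YAML-able config drives every stage; all thresholds the analysis
depends on (chain cut-offs 250/300, 70% bootstrap support, 500 bp / 80%
flank rule, substitution rate 3.9e-10) surface as named keys with those
defaults.  Outputs are plain TSV/GFF3/FASTA files plus a manifest with
content hashes, so a rerun with the same config and seed is byte-identical
and individual stages can be skipped when their outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify as _classify
from . import io as _io
from .capture import codon_z_test, detect_capture
from .consensus import center_star_align
from .dating import DEFAULT_RATE, date_group
from .detect import call_proviruses, filter_complete, find_solo_ltrs
from .grouping import (DistanceMatrix, ERVGroup, bootstrap_supports,
                       annotate_supports, define_groups, nj_tree, summarize_group)
from .orthology import call_orthologs, crosscheck_distribution_age
from .simulate import (Degradation, GenomeBuild, InsertSpec, SimulationConfig,
                       SpeciesPairConfig, make_species_pair, simulate_genome)


@dataclass
class PipelineConfig:
    outdir: str = "paleoerv_out"
    seed: int = 0
    genomes: dict[str, str] = field(default_factory=dict)  # species -> FASTA path
    simulate: dict | None = None
    host_proteins: str | None = None
    chain_cutoff: float = 250.0
    report_cutoff: float = 300.0
    support_threshold: float = 0.70
    bootstrap_reps: int = 200
    flank_len: int = 500
    flank_identity: float = 0.80
    substitution_rate: float = DEFAULT_RATE
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for key in ("chain_cutoff", "report_cutoff", "support_threshold",
                    "flank_identity", "substitution_rate"):
            if getattr(self, key) <= 0:
                raise ValueError(f"{key} must be positive")
        for species, path in self.genomes.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"genome for {species}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _parse_insert_specs(entries: list[dict]) -> list[InsertSpec]:
    out = []
    for e in entries:
        e = dict(e)
        count = e.pop("count", 1)
        deg = e.pop("degradation", None)
        kwargs = dict(e)
        if deg:
            kwargs["degradation"] = Degradation(**deg)
        out.extend(InsertSpec(**kwargs) for _ in range(count))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class GenomeSummary:
    species: str
    assembly_length: int
    n_chains: int
    n_complete: int
    summed_chain_length: int
    mean_chain_length: float
    percent_erv: float
    n_solo_ltrs: int


def summarize_genome(calls, genome, solos=(), species: str = "genome") -> GenomeSummary:
    """Genome content summary: chain count/length and percent of the
    assembly covered by ERV chains (excluding solo LTRs)."""
    scaffolds = genome.scaffolds if hasattr(genome, "scaffolds") else dict(genome)
    total = sum(len(s) for s in scaffolds.values())
    if total == 0:
        raise ValueError("empty genome")
    lengths = [c.end - c.start for c in calls]
    summed = sum(lengths)
    return GenomeSummary(
        species=species,
        assembly_length=total,
        n_chains=len(calls),
        n_complete=sum(c.complete for c in calls),
        summed_chain_length=summed,
        mean_chain_length=round(summed / len(lengths), 1) if lengths else 0.0,
        percent_erv=round(100.0 * summed / total, 2),
        n_solo_ltrs=len(solos),
    )


def run(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage; returns the manifest (also written as JSON).

    Existing stage outputs are reused unless ``force`` is set; a stage
    failure raises with the stage name while earlier outputs remain on
    disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in vars(config).items()},
                      "stages": {}, "files": {}}
    stage = "setup"
    try:
        # --- genomes ----------------------------------------------------
        builds: dict[str, GenomeBuild] = {}
        if config.simulate is not None:
            stage = "simulate"
            sim = dict(config.simulate)
            if "species_pair" in sim:
                sp = dict(sim["species_pair"])
                for key in ("shared", "specific_a", "specific_b"):
                    sp[key] = _parse_insert_specs(sp.get(key, []))
                names = tuple(sp.pop("names", ("spA", "spB")))
                sp.setdefault("seed", config.seed)
                a, b = make_species_pair(SpeciesPairConfig(**sp), names=names)
                builds = {a.species: a, b.species: b}
            else:
                sim["insert_specs"] = _parse_insert_specs(sim.get("insert_specs", []))
                sim.setdefault("seed", config.seed)
                build = simulate_genome(SimulationConfig(**sim))
                builds = {build.species: build}
            for species, build in builds.items():
                for name, p in _io.write_build(build, outdir / "sim").items():
                    manifest["files"][f"sim/{species}/{name}"] = str(p)
        else:
            for species, path in config.genomes.items():
                builds[species] = GenomeBuild(
                    scaffolds=_io.read_fasta(path), truth=[], species=species)
        hosts = None
        if config.host_proteins:
            hosts = _io.read_fasta(config.host_proteins)
        elif builds and config.simulate is not None:
            hosts = next(iter(builds.values())).hosts

        # --- detection --------------------------------------------------
        stage = "detect"
        calls_by_species = {}
        solos_by_species = {}
        for species, build in builds.items():
            calls = call_proviruses(build, cutoff=config.chain_cutoff,
                                    id_prefix=species)
            library = {}
            for c in calls:
                seq = build.scaffolds[c.scaffold]
                library[f"{c.id}_LTR5"] = seq[c.pair.ltr5[0]:c.pair.ltr5[1]]
            solos = find_solo_ltrs(build, library, calls)
            calls_by_species[species] = calls
            solos_by_species[species] = solos
            for name, p in _io.write_calls(calls, solos, outdir / "detect",
                                           prefix=f"{species}.calls").items():
                manifest["files"][f"detect/{species}/{name}"] = str(p)
        manifest["stages"]["detect"] = {
            s: {"n_calls": len(c), "n_complete": sum(x.complete for x in c),
                "n_solo": len(solos_by_species[s])}
            for s, c in calls_by_species.items()}

        # --- grouping on complete pol translations ----------------------
        stage = "group"
        complete = [c for calls in calls_by_species.values()
                    for c in filter_complete(calls)]
        species_of = {}
        for species, calls in calls_by_species.items():
            for c in calls:
                species_of[c.id] = species
        groups: list[ERVGroup] = []
        group_rows = []
        if len(complete) >= 3:
            aln = center_star_align([c.id for c in complete],
                                    [c.pol_aa for c in complete])
            supports = bootstrap_supports(aln.ids, aln.rows,
                                          n_reps=config.bootstrap_reps,
                                          seed=config.seed)
            dm = DistanceMatrix.from_alignment(aln.ids, aln.rows)
            tree = nj_tree(dm)
            annotate_supports(tree, supports)
            (outdir / "group").mkdir(exist_ok=True)
            (outdir / "group" / "pol_nj.nwk").write_text(tree.newick())
            memberships = define_groups(tree, supports, dm,
                                        threshold=config.support_threshold)
            for gi, members in enumerate(memberships, 1):
                g = summarize_group(f"SimERV{gi}", members, dm,
                                    species_of=lambda m: species_of[m])
                groups.append(g)
        call_index = {c.id: c for calls in calls_by_species.values() for c in calls}

        # --- classification ---------------------------------------------
        stage = "classify"
        for g in groups:
            rep = call_index[g.members[0]]
            profile = _classify.extract_class_features(rep)
            structural = _classify.classify_structural(profile)
            rt_aa = rep.pol_aa[:220].replace("*", "X")
            try:
                phylo = _classify.place_by_rt(rt_aa, seed=config.seed)
            except ValueError:
                phylo = _classify.INTERMEDIATE
            g.class_label = _classify.assign_class(structural, phylo).final

        # --- dating ------------------------------------------------------
        stage = "date"
        for g in groups:
            pairs = []
            for m in g.members:
                c = call_index[m]
                seq = builds[species_of[m]].scaffolds[c.scaffold]
                pairs.append((seq[c.pair.ltr5[0]:c.pair.ltr5[1]],
                              seq[c.pair.ltr3[0]:c.pair.ltr3[1]]))
            g.age = date_group(pairs, r=config.substitution_rate)
            group_rows.append({
                "group": g.group_id, "n_members": len(g.members),
                "class": g.class_label,
                "mean_similarity": round(g.mean_similarity, 3),
                "species": ",".join(sorted(g.species)),
                "d": round(g.age.d, 4) if g.age else "NA",
                "age_my": round(g.age.T_my, 1) if g.age else "NA",
                "pairs_used": g.age.n_pairs_used if g.age else 0,
                "pairs_dropped": g.age.n_pairs_dropped if g.age else 0,
                "members": ",".join(g.members)})
        (outdir / "group").mkdir(exist_ok=True)
        manifest["files"]["group/groups"] = str(
            _io.write_tsv(group_rows, outdir / "group" / "groups.tsv"))
        manifest["stages"]["group"] = {"n_groups": len(groups)}

        # --- orthology (first two genomes) -------------------------------
        stage = "orthologs"
        ortho_rows = []
        if len(builds) >= 2:
            (sa, ba), (sb, bb) = list(builds.items())[:2]
            orths = call_orthologs(calls_by_species[sa], calls_by_species[sb],
                                   ba, bb, threshold=config.flank_identity,
                                   flank_len=config.flank_len)
            ortho_rows = [{"id_a": o.id_a, "id_b": o.id_b,
                           "up_identity": round(o.upstream_identity, 3),
                           "down_identity": round(o.downstream_identity, 3)}
                          for o in orths]
        manifest["files"]["orthologs"] = str(
            _io.write_tsv(ortho_rows, outdir / "orthologs.tsv"))
        manifest["stages"]["orthologs"] = {"n_accepted": len(ortho_rows)}
        flags = crosscheck_distribution_age(groups) if groups else []
        manifest["files"]["age_flags"] = str(
            _io.write_tsv(flags, outdir / "age_flags.tsv"))

        # --- capture ------------------------------------------------------
        stage = "capture"
        capture_rows = []
        if hosts:
            for species, calls in calls_by_species.items():
                build = builds[species]
                for c in calls:
                    seq = build.scaffolds[c.scaffold]
                    internal = seq[c.pair.ltr5[1]:c.pair.ltr3[0]]
                    for ev in detect_capture(c, internal, hosts):
                        capture_rows.append({
                            "species": species, "call_id": c.id,
                            "host": ev.host_id, "mode": ev.mode,
                            "identity": ev.identity, "coverage": ev.coverage,
                            "orf_codons": len(ev.orf_aa)})
        manifest["files"]["captures"] = str(
            _io.write_tsv(capture_rows, outdir / "captures.tsv"))
        manifest["stages"]["capture"] = {"n_events": len(capture_rows)}

        # --- summary ------------------------------------------------------
        stage = "summary"
        summary_rows = []
        for species, build in builds.items():
            s = summarize_genome(calls_by_species[species], build,
                                 solos_by_species.get(species, ()), species)
            summary_rows.append(vars(s))
        manifest["files"]["summary"] = str(
            _io.write_tsv(summary_rows, outdir / "genome_summary.tsv"))
        manifest["stages"]["summary"] = {r["species"]: r for r in summary_rows}
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    for key, path in list(manifest["files"].items()):
        p = Path(path)
        if p.exists():
            manifest["files"][key] = {"path": str(p), "sha256": _sha256(p)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
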