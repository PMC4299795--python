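"""Readers and writers for the pipeline's file formats.

Sequences travel as FASTA (via Biopython), annotations as GFF3 (1-based,
inclusive) with a TSV mirror for convenient loading into dataframes.
Internally all coordinates are 0-based half-open; conversion happens only
at the file boundary.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import ProvirusCall, SoloLTRCall
from .simulate import GenomeBuild


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _gff_line(scaffold, source, ftype, start0, end0, score=".", strand="+",
              attrs: dict | None = None) -> str:
    a = ";".join(f"{k}={v}" for k, v in (attrs or {}).items())
    sc = f"{score:.1f}" if isinstance(score, float) else str(score)
    return f"{scaffold}\t{source}\t{ftype}\t{start0 + 1}\t{end0}\t{sc}\t{strand}\t.\t{a}"


# --------------------------------------------------------------------------
# simulator output

def write_build(build: GenomeBuild, outdir) -> dict[str, Path]:
    """Emit genome FASTA, GFF3 + TSV truth ledger, and host protein FASTA."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / f"{build.species}.fa",
        "truth_gff": outdir / f"{build.species}.truth.gff3",
        "truth_tsv": outdir / f"{build.species}.truth.tsv",
        "hosts": outdir / "host_proteins.fa",
    }
    write_fasta(build.scaffolds, paths["genome"])
    write_fasta(build.hosts, paths["hosts"])
    lines = ["##gff-version 3"]
    rows = []
    for t in build.truth:
        attrs = {"ID": t.element_id, "erv_class": t.class_label,
                 "tsd": t.tsd_sequence, "d_true": f"{t.true_divergence:.4f}",
                 "capture": t.capture_mode or "none",
                 "ortholog": t.ortholog_partner_id or "none",
                 "solo": str(t.is_solo).lower(), "family": t.family}
        ftype = "solo_LTR" if t.is_solo else "provirus"
        lines.append(_gff_line(t.scaffold, "paleoerv_sim", ftype, t.start, t.end,
                               attrs=attrs))
        for name, (a, b) in sorted(t.domains.items(), key=lambda kv: kv[1]):
            lines.append(_gff_line(t.scaffold, "paleoerv_sim", name, a, b,
                                   attrs={"Parent": t.element_id}))
        rows.append({"element_id": t.element_id, "scaffold": t.scaffold,
                     "start": t.start, "end": t.end, "class": t.class_label,
                     "tsd": t.tsd_sequence, "d_true": round(t.true_divergence, 4),
                     "capture": t.capture_mode or "none",
                     "ortholog": t.ortholog_partner_id or "none",
                     "solo": t.is_solo, "family": t.family})
    paths["truth_gff"].write_text("\n".join(lines) + "\n")
    pd.DataFrame(rows).to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths


# --------------------------------------------------------------------------
# detection output

def write_calls(calls: list[ProvirusCall], solos: list[SoloLTRCall], outdir,
                prefix: str = "calls") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / f"{prefix}.gff3",
        "tsv": outdir / f"{prefix}.tsv",
        "pol": outdir / f"{prefix}.pol.fa",
    }
    lines = ["##gff-version 3"]
    rows = []
    pol = {}
    for c in calls:
        lines.append(_gff_line(c.scaffold, "paleoerv", "provirus", c.start, c.end,
                               score=c.chain_score,
                               attrs={"ID": c.id, "complete": str(c.complete).lower(),
                                      "ltr_identity": f"{c.pair.identity:.3f}",
                                      "tsd": c.tsd.sequence if c.tsd else "none"}))
        lines.append(_gff_line(c.scaffold, "paleoerv", "LTR5", *c.pair.ltr5,
                               attrs={"Parent": c.id}))
        lines.append(_gff_line(c.scaffold, "paleoerv", "LTR3", *c.pair.ltr3,
                               attrs={"Parent": c.id}))
        off = c.pair.ltr5[1]
        for h in c.hits:
            strand = "+" if h.frame >= 0 else "-"
            lines.append(_gff_line(c.scaffold, "paleoerv", f"domain_{h.domain}",
                                   off + h.start, off + h.end, score=h.score,
                                   strand=strand, attrs={"Parent": c.id}))
        rows.append({"call_id": c.id, "scaffold": c.scaffold, "start": c.start,
                     "end": c.end, "chain_score": round(c.chain_score, 1),
                     "ltr_identity": round(c.pair.identity, 3),
                     "tsd": c.tsd.sequence if c.tsd else "none",
                     "tsd_len": c.tsd.length if c.tsd else 0,
                     "complete": c.complete,
                     "domains": ",".join(sorted(h.domain for h in c.hits))})
        if c.pol_aa:
            pol[c.id] = c.pol_aa
    for s in solos:
        lines.append(_gff_line(s.scaffold, "paleoerv", "solo_LTR", s.start, s.end,
                               attrs={"library_entry": s.library_entry or "none",
                                      "identity": f"{s.identity:.3f}"}))
    paths["gff"].write_text("\n".join(lines) + "\n")
    pd.DataFrame(rows).to_csv(paths["tsv"], sep="\t", index=False)
    write_fasta(pol, paths["pol"])
    return paths


def read_calls(gff_path, pol_fasta=None) -> list[ProvirusCall]:
    """Reconstruct provirus calls from a detection GFF3 (plus the pol
    translation FASTA when per-call pol sequences are needed)."""
    from .detect import DomainHit, LTRPair, TSD

    pol = read_fasta(pol_fasta) if pol_fasta else {}
    calls: dict[str, ProvirusCall] = {}
    children: dict[str, list[tuple[str, int, int, float, str]]] = {}
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        scaf, _, ftype, start, end, score, strand, _, attrs_s = line.split("\t")
        attrs = dict(kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv)
        s0, e0 = int(start) - 1, int(end)
        if ftype == "provirus":
            cid = attrs["ID"]
            tsd = attrs.get("tsd", "none")
            calls[cid] = ProvirusCall(
                id=cid,
                pair=LTRPair(scaf, (s0, s0), (e0, e0),
                             float(attrs.get("ltr_identity", 0)), 0),
                tsd=TSD(tsd) if tsd != "none" else None,
                chain_score=float(score) if score != "." else 0.0)
            calls[cid].complete = attrs.get("complete") == "true"
        elif "Parent" in attrs:
            children.setdefault(attrs["Parent"], []).append(
                (ftype, s0, e0, float(score) if score != "." else 0.0, strand))
    for cid, feats in children.items():
        call = calls.get(cid)
        if call is None:
            continue
        for ftype, s0, e0, score, strand in feats:
            if ftype == "LTR5":
                call.pair.ltr5 = (s0, e0)
            elif ftype == "LTR3":
                call.pair.ltr3 = (s0, e0)
        off = call.pair.ltr5[1]
        for ftype, s0, e0, score, strand in feats:
            if ftype.startswith("domain_"):
                frame = 0 if strand == "+" else -1
                call.hits.append(DomainHit(ftype[len("domain_"):],
                                           frame, s0 - off, e0 - off, score))
        call.hits.sort(key=lambda h: h.start)
    out = sorted(calls.values(), key=lambda c: (c.scaffold, c.start))
    for c in out:
        c.pol_aa = pol.get(c.id, "")
    return out


def write_tsv(rows: list[dict], path) -> Path:
    path = Path(path)
    if rows:
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        path.write_text("")
    return path
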