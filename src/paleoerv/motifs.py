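"""Retroviral domain signatures and class feature profiles.

The simulator embeds short amino-acid signature blocks inside otherwise
random ORFs, and the detector searches six-frame translations for the same
blocks.  The blocks paraphrase the field's canonical motifs: the CCHC
zinc-finger cassette of the gag nucleocapsid, the D(T/S)G catalytic triad of
retropepsin, the LPQG and YXDD boxes of reverse transcriptase, the DDE-type
integrase core, the GPY/F module found C-terminal of integrase in class I/II
elements, and a dUTPase cassette.

Class centroid sequences (for the variable regions of each gene, and the RT
placement panel) are generated once from a fixed internal seed so that class
identity is stable across runs and independent of user seeds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

# one fixed internal entropy source for class centroids / panel / host proteins
_MASTER_ENTROPY = 715_517_301

# CCHC zinc finger: C-x2-C-x4-H-x4-C
ZF_BLOCK = "CYNCGKPGHLARQC"
ZF_REGEX = re.compile(r"C.{2}C.{4}H.{4}C")

SIGNATURES: dict[str, str] = {
    # capsid block shared by every class (major-homology-region style); the
    # completeness filter accepts either gag signature as evidence of gag
    "gag_ca": "QGPKEPFQSYVDRFYKTLRAEQA",
    "gag_zf": ZF_BLOCK,
    "pro": "VNLLVDTGADVTVIS",
    # RT core: LPQG box ... YVDD box
    "RT": "GLKKCQSPILLPQGMANSPTICQLYVGQALEPLRKQYVDDLLLA",
    "RNaseH": "IHGEIYRRRGLLTSEGKEIKNK",
    "IN": "GQVDRSHEILKSTLHKLNMQTSPFDEAE",
    "GPY_F": "TWEIWGPYFTQNVKATA",
    "dUTPase": "RLSENAGLDLYSTEDVVLAPGERKLVPT",
    "env": "GIDPSRLFSQWFNLTRDMQTELNLT",
}

# lengths (aa) of the class-specific variable regions of each gene
VAR_LEN = {"gag": 40, "pro": 20, "RT": 156, "pol_tail": 40, "env": 120}


@dataclass(frozen=True)
class ClassFeatures:
    """Structural feature vector distinguishing the four ERV classes."""

    tsd_length: int
    zinc_fingers: int
    gpy_f_present: bool
    dutpase_location: str | None  # None | "within_pro" | "downstream_of_IN"
    env_present: bool


# TSD 4/6/5/5 bp; zinc fingers 1-2 / 2 / absent / absent; GPY/F present only
# in classes I and II; dUTPase within pro (II) or downstream of integrase
# (one class III lineage); class IV keeps a relatively intact env.
CLASS_TABLE: dict[str, ClassFeatures] = {
    "ERV1": ClassFeatures(4, 1, True, None, True),
    "ERV2": ClassFeatures(6, 2, True, "within_pro", True),
    "ERV3": ClassFeatures(5, 0, False, "downstream_of_IN", True),
    "ERV4": ClassFeatures(5, 0, False, None, True),
}

ERV_CLASSES = tuple(CLASS_TABLE)


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((_MASTER_ENTROPY, *key)))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def mutate_protein(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Substitute ``fraction`` of residues with a different random residue."""
    chars = list(seq)
    n = len(chars)
    k = int(round(fraction * n))
    for i in rng.choice(n, size=min(k, n), replace=False):
        alt = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _class_centroids() -> dict[str, dict[str, str]]:
    """Per-class centroid sequences for each variable region."""
    rng = _rng(1)
    ancestors = {k: random_protein(n, rng) for k, n in VAR_LEN.items()}
    out: dict[str, dict[str, str]] = {}
    for ci, cls in enumerate(ERV_CLASSES):
        crng = _rng(2, ci)
        out[cls] = {k: mutate_protein(v, 0.40, crng) for k, v in ancestors.items()}
    return out


CLASS_CENTROIDS = _class_centroids()

# The RT domain used for phylogenetic placement: conserved core + class
# variable region.
RT_CORE = SIGNATURES["RT"]


def class_rt(cls: str) -> str:
    return RT_CORE + CLASS_CENTROIDS[cls]["RT"]


def rt_reference_panel() -> list[tuple[str, str, str]]:
    """Labelled RT panel: (name, class label, amino-acid sequence).

    Three representatives per class (the centroid plus two 4%-diverged
    variants) and two deeply diverged Gypsy-like outgroup sequences.
    """
    panel: list[tuple[str, str, str]] = []
    for ci, cls in enumerate(ERV_CLASSES):
        base = class_rt(cls)
        panel.append((f"{cls}_ref1", cls, base))
        for v in (2, 3):
            rng = _rng(3, ci, v)
            panel.append((f"{cls}_ref{v}", cls, RT_CORE + mutate_protein(base[len(RT_CORE):], 0.04, rng)))
    for v in (1, 2):
        rng = _rng(4, v)
        panel.append((f"gypsy_out{v}", "outgroup", RT_CORE + random_protein(VAR_LEN["RT"], rng)))
    return panel


def host_proteins() -> dict[str, str]:
    """Synthetic host protein set for capture detection.

    Stand-ins for a KIT-ligand-like soluble-form protein and a nectin3-like
    protein, plus two unrelated decoys; all synthetic sequences.
    """
    rng = _rng(5)
    return {
        "kitlg_like": random_protein(170, rng),
        "nectin3_like": random_protein(240, rng),
        "decoy_a": random_protein(150, rng),
        "decoy_b": random_protein(190, rng),
    }


# --- reverse translation -------------------------------------------------

from Bio.Data.CodonTable import standard_dna_table as _SDT

CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in _SDT.forward_table.items():
    CODONS_FOR.setdefault(_aa, []).append(_codon)
for _v in CODONS_FOR.values():
    _v.sort()
STOP_CODONS = tuple(sorted(_SDT.stop_codons))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Encode a protein as DNA, drawing synonymous codons uniformly."""
    parts = []
    for aa in protein:
        codons = CODONS_FOR[aa]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)
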