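"""Thin wrappers around edlib for identity computations."""

from __future__ import annotations

import edlib


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Global (NW) alignment identity and alignment column count."""
    if not a or not b:
        return 0.0, 0
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    cols = len(nice["matched_aligned"])
    matches = nice["matched_aligned"].count("|")
    return matches / cols, cols


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]
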