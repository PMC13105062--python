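"""Sequence Specificity Landscape (SSL) construction.

Sequences are arranged in concentric rings by Hamming distance of their
best motif window from the consensus (ring 0 = perfect match at the
center). Within a ring, entries are ordered by the positions of their
mismatches, then by the substituted bases, giving sections of the ring per
mismatch-position combination; normalized intensity is the landscape
height. The one-mismatch ring can be flattened to an ordered 2D profile
with the section boundaries marked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import (
    MotifMatch,
    best_window,
    canonicalize_mismatch,
    is_palindromic,
    min_window_distance,
    revcomp,
    window_distances,
)

__all__ = ["SSLLayout", "assign_ring", "build_landscape", "layout_rings",
           "flatten_one_mismatch_ring"]


def assign_ring(probe_sequence: str, consensus: str) -> int:
    """Ring index: minimum Hamming distance over all windows and strands."""
    if len(probe_sequence) < len(consensus):
        raise ValueError("sequence shorter than the consensus")
    return min_window_distance(probe_sequence, consensus)


def _variant_of(sequence: str, consensus: str, canonicalize: bool) -> tuple[str, tuple, tuple]:
    """Best-window variant octamer plus its mismatch positions/bases.

    The smallest-offset best window is the representative; with
    ``canonicalize`` (palindromic consensus) strand-equivalent variants
    collapse onto one representative octamer.
    """
    off, dist, strand = best_window(sequence, consensus)
    L = len(consensus)
    window = sequence[off : off + L]
    if strand == "-":
        window = revcomp(window)
    positions = tuple(i + 1 for i in range(L) if window[i] != consensus[i])
    bases = tuple(window[i - 1] for i in positions)
    if canonicalize and is_palindromic(consensus):
        match = canonicalize_mismatch(
            MotifMatch(off, "+", dist, positions, bases), consensus
        )
        positions, bases = match.mismatch_positions, match.mismatch_bases
        seq = list(consensus)
        for p, b in zip(positions, bases):
            seq[p - 1] = b
        window = "".join(seq)
    return window, positions, bases


@dataclass
class SSLLayout:
    """Landscape entries with ring, section, ordinal and planar coordinates."""

    entries: pd.DataFrame  # sequence, ring, section, ordinal, x, y, intensity
    r0: float = 1.0
    consensus: str = "AACCGGTT"

    def ring(self, k: int) -> pd.DataFrame:
        return self.entries[self.entries["ring"] == k]

    def ring_means(self) -> pd.Series:
        return self.entries.groupby("ring")["intensity"].mean()

    def to_tsv(self, path) -> None:
        cols = ["sequence", "ring", "section", "ordinal", "x", "y", "intensity"]
        self.entries[cols].to_csv(path, sep="\t", index=False)


def build_landscape(
    probes: pd.DataFrame,
    consensus: str = "AACCGGTT",
    canonicalize: bool = False,
    r0: float = 1.0,
    sequence_col: str = "sequence",
    intensity_col: str = "intensity",
) -> SSLLayout:
    """Aggregate probes into variant classes and lay them out in rings.

    Each probe contributes its best-matching window octamer; probes sharing
    a variant class are collapsed to the class median intensity (matching
    the pipeline's median-collapse convention).
    """
    records = []
    for seq, inten in zip(probes[sequence_col], probes[intensity_col]):
        variant, positions, bases = _variant_of(seq, consensus, canonicalize)
        records.append({
            "sequence": variant,
            "ring": len(positions),
            "positions": positions,
            "bases": bases,
            "intensity": inten,
        })
    df = pd.DataFrame(records)
    classes = (
        df.groupby(["sequence", "ring", "positions", "bases"], sort=False)["intensity"]
        .median()
        .reset_index()
    )
    return layout_rings(classes, r0=r0, consensus=consensus)


def layout_rings(entries: pd.DataFrame, r0: float = 1.0,
                 consensus: str = "AACCGGTT") -> SSLLayout:
    """Assign ordinals and planar coordinates ring by ring.

    Within ring k entries are sorted by (mismatch-position tuple, substituted
    bases in A<C<G<T order, sequence); ordinal i of n maps to angle 2*pi*i/n.
    Radii grow with ring rank among *populated* rings (empty rings leave no
    gap), the innermost populated ring sitting at r0.
    """
    required = {"sequence", "ring", "positions", "bases", "intensity"}
    missing = required - set(entries.columns)
    if missing:
        raise ValueError(f"entries missing columns: {sorted(missing)}")
    out = []
    populated = sorted(entries["ring"].unique())
    for rank, k in enumerate(populated):
        ring = entries[entries["ring"] == k].copy()
        ring = ring.sort_values(
            by=["positions", "bases", "sequence"],
            key=lambda col: col.map(tuple) if col.name in ("positions", "bases") else col,
            kind="mergesort",
        ).reset_index(drop=True)
        n = len(ring)
        radius = (rank + 1) * r0
        angles = 2.0 * np.pi * np.arange(n) / n
        ring["ordinal"] = np.arange(n)
        ring["section"] = ring["positions"].map(
            lambda p: ",".join(map(str, p)) if p else "consensus"
        )
        ring["x"] = radius * np.cos(angles)
        ring["y"] = radius * np.sin(angles)
        out.append(ring)
    frame = pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=list(required | {"ordinal", "section", "x", "y"})
    )
    return SSLLayout(entries=frame, r0=r0, consensus=consensus)


def flatten_one_mismatch_ring(layout: SSLLayout) -> tuple[pd.DataFrame, list[int]]:
    """Flatten ring 1 to an ordered 2D table plus section boundaries.

    Returns the ordered rows (ordinal, sequence, mismatch position and base,
    x, y, intensity) and the ordinal indices at which the mismatch-position
    section changes (boundaries between sections).
    """
    ring = layout.ring(1)
    if ring.empty:
        raise ValueError("layout has no one-mismatch ring")
    ring = ring.sort_values("ordinal").reset_index(drop=True)
    table = pd.DataFrame({
        "ordinal": ring["ordinal"],
        "sequence": ring["sequence"],
        "mismatch_position": ring["positions"].map(lambda p: p[0]),
        "mismatch_base": ring["bases"].map(lambda b: b[0]),
        "x": ring["x"],
        "y": ring["y"],
        "intensity": ring["intensity"],
    })
    pos = table["mismatch_position"].to_numpy()
    # the ring is circular: a section change from the last entry back to the
    # first counts as a boundary at ordinal 0
    boundaries = [int(i) for i in range(len(pos)) if pos[i] != pos[i - 1]]
    return table, boundaries
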