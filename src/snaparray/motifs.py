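"""Motif scanning and mismatch bookkeeping.

Locates consensus and degenerate (IUPAC) motif matches in probe or region
sequences, counts and localizes mismatches relative to a consensus octamer,
canonicalizes strand-equivalent mismatch descriptions for palindromic
consensi, and ranks probes into intensity bins for motif-discovery export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotifMatch",
    "revcomp",
    "hamming",
    "is_palindromic",
    "scan_motif",
    "canonicalize_mismatch",
    "expand_iupac",
    "scan_iupac",
    "window_distances",
    "min_window_distance",
    "best_window",
    "rank_top_probes",
    "build_pfm",
    "IUPAC_SETS",
]

_COMPLEMENT = str.maketrans("ACGTRYKMWSN", "TGCAYRMKWSN")

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "W": "AT", "S": "CG",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def is_palindromic(seq: str) -> bool:
    """True when the sequence equals its own reverse complement."""
    return seq == revcomp(seq)


def _check_acgt(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValueError(f"non-ACGT character {ch!r} at position {i}")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        pos = int(np.nonzero(out < 0)[0][0])
        raise ValueError(f"non-ACGT character {seq[pos]!r} at position {pos}")
    return out


@dataclass(frozen=True)
class MotifMatch:
    """A placement of the consensus (or a variant of it) in a sequence.

    ``offset`` is 0-based in the scanned sequence; mismatch positions are
    1-based within the motif, read in motif orientation on ``strand``.
    """

    offset: int
    strand: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    mismatch_bases: tuple[str, ...]

    def __post_init__(self):
        if self.mismatch_count != len(self.mismatch_positions):
            raise ValueError("mismatch_count must equal |mismatch_positions|")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


def window_distances(sequence: str, consensus: str) -> np.ndarray:
    """Hamming distance of every window to the consensus, per strand.

    Returns an array of shape (2, n_windows): row 0 compares forward
    windows, row 1 compares the reverse complement of each window (i.e.,
    the motif read on the minus strand at the same offset).
    """
    L = len(consensus)
    seq = _encode(sequence)
    cons = _encode(consensus)
    if len(seq) < L:
        return np.zeros((2, 0), dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(seq, L)
    fwd = (win != cons).sum(axis=1)
    # reverse complement of a window: complement (3 - code), reversed
    rc_cons = _encode(revcomp(consensus))
    rev = (win != rc_cons).sum(axis=1)
    return np.vstack([fwd, rev])


def batch_window_distances(sequences: Sequence[str], consensus: str) -> np.ndarray:
    """Window Hamming distances for many equal-length sequences at once.

    Returns an array of shape (n_sequences, 2, n_windows); axis 1 is
    forward / reverse-complement reading, as in :func:`window_distances`.
    """
    if not sequences:
        return np.zeros((0, 2, 0), dtype=int)
    L = len(consensus)
    n_cols = len(sequences[0])
    if any(len(s) != n_cols for s in sequences):
        raise ValueError("sequences must share one length")
    flat = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    arr = flat.reshape(len(sequences), n_cols)
    cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
    rc_cons = np.frombuffer(revcomp(consensus).encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, L, axis=1)
    fwd = (win != cons).sum(axis=2)
    rev = (win != rc_cons).sum(axis=2)
    return np.stack([fwd, rev], axis=1)


def min_window_distance(sequence: str, consensus: str) -> int:
    """Minimum Hamming distance to the consensus over all windows/strands."""
    d = window_distances(sequence, consensus)
    if d.size == 0:
        return len(consensus)
    return int(d.min())


def best_window(sequence: str, consensus: str) -> tuple[int, int, str]:
    """(offset, distance, strand) of the best-matching window.

    Ties are broken by smallest offset, then by '+' strand, so the choice
    is deterministic.
    """
    d = window_distances(sequence, consensus)
    if d.size == 0:
        raise ValueError("sequence shorter than consensus")
    dist = int(d.min())
    offsets = np.nonzero(d.min(axis=0) == dist)[0]
    off = int(offsets[0])
    strand = "+" if d[0, off] == dist else "-"
    return off, dist, strand


def _match_at(sequence: str, consensus: str, offset: int, strand: str) -> MotifMatch:
    L = len(consensus)
    window = sequence[offset : offset + L]
    if strand == "-":
        window = revcomp(window)
    positions = tuple(i + 1 for i in range(L) if window[i] != consensus[i])
    bases = tuple(window[i - 1] for i in positions)
    return MotifMatch(offset, strand, len(positions), positions, bases)


def scan_motif(
    sequence: str,
    consensus: str,
    max_mismatch: int,
    best_per_window: bool = False,
) -> list[MotifMatch]:
    """All windows within ``max_mismatch`` of the consensus, both strands.

    A window whose forward and reverse-complement readings are equally
    distant (always true for a palindromic consensus) is reported once on
    the '+' strand. With ``best_per_window`` only the lower-mismatch strand
    of each window is reported even when both strands pass the cutoff.
    """
    _check_acgt(consensus)
    if not 0 <= max_mismatch <= len(consensus):
        raise ValueError(f"max_mismatch {max_mismatch} out of range 0..{len(consensus)}")
    d = window_distances(sequence, consensus)
    matches: list[MotifMatch] = []
    for off in range(d.shape[1]):
        dp, dm = int(d[0, off]), int(d[1, off])
        if best_per_window:
            if min(dp, dm) <= max_mismatch:
                strand = "+" if dp <= dm else "-"
                matches.append(_match_at(sequence, consensus, off, strand))
            continue
        if dp <= max_mismatch:
            matches.append(_match_at(sequence, consensus, off, "+"))
        if dm <= max_mismatch and dm != dp:
            # dm == dp is the strand-equivalent reading of the same window;
            # the '+' representative above already covers it
            matches.append(_match_at(sequence, consensus, off, "-"))
    return matches


def canonicalize_mismatch(match: MotifMatch, consensus: str) -> MotifMatch:
    """Canonical representative of a strand-equivalent mismatch pair.

    For a palindromic consensus of length L, a mismatch at position i read
    on one strand is the same molecule as a complemented mismatch at
    position L+1-i on the other strand. The representative with the
    lexicographically smaller position tuple (tie: '+' strand) is returned;
    the operation is idempotent.
    """
    if not is_palindromic(consensus):
        return match
    L = len(consensus)
    alt_pairs = sorted(
        (L + 1 - p, b.translate(_COMPLEMENT))
        for p, b in zip(match.mismatch_positions, match.mismatch_bases)
    )
    alt_positions = tuple(p for p, _ in alt_pairs)
    alt_bases = tuple(b for _, b in alt_pairs)
    alt_strand = "-" if match.strand == "+" else "+"
    this_key = (match.mismatch_positions, match.mismatch_bases, match.strand != "+")
    alt_key = (alt_positions, alt_bases, alt_strand != "+")
    if alt_key < this_key:
        return replace(
            match,
            strand=alt_strand,
            mismatch_positions=alt_positions,
            mismatch_bases=alt_bases,
        )
    return match


def expand_iupac(pattern: str) -> list[str]:
    """All concrete A/C/G/T sequences matching an IUPAC pattern, sorted."""
    try:
        sets = [IUPAC_SETS[ch] for ch in pattern]
    except KeyError as exc:
        raise ValueError(f"unknown IUPAC code {exc.args[0]!r}") from None
    return ["".join(p) for p in sorted(product(*sets))]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern:
        if ch not in IUPAC_SETS:
            raise ValueError(f"unknown IUPAC code {ch!r}")
        bases = IUPAC_SETS[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping matches are all found
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(sequence: str, pattern: str, both_strands: bool = True) -> list[dict]:
    """Every exact occurrence of an IUPAC pattern; strand recorded.

    Minus-strand hits are reported at the forward-strand offset of the
    site (0-based), with the matched sequence in pattern orientation.
    """
    _check_acgt(sequence)
    rx = _iupac_regex(pattern)
    hits = [
        {"offset": m.start(), "strand": "+", "match": m.group(1)}
        for m in rx.finditer(sequence)
    ]
    if both_strands:
        rc = revcomp(sequence)
        n = len(sequence)
        L = len(pattern)
        for m in rx.finditer(rc):
            hits.append(
                {"offset": n - m.start() - L, "strand": "-", "match": m.group(1)}
            )
    hits.sort(key=lambda h: (h["offset"], h["strand"]))
    return hits


def rank_top_probes(
    probes: pd.DataFrame,
    n: int = 1200,
    bin_size: int = 300,
    intensity_col: str = "intensity",
) -> list[pd.DataFrame]:
    """Rank probes by descending intensity and split into fixed-size bins.

    ``probes`` needs ``probe_id``, ``sequence`` and the intensity column.
    Ties at bin boundaries are broken by probe_id lexicographic order.
    Returns as many *full* bins as the data allow (a warning is issued if
    fewer than n probes are available).
    """
    if n % bin_size != 0:
        raise ValueError("n must be divisible by bin_size")
    ordered = probes.sort_values(
        [intensity_col, "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if len(ordered) < n:
        import warnings

        warnings.warn(
            f"only {len(ordered)} probes available for a top-{n} ranking",
            stacklevel=2,
        )
    top = ordered.head(n)
    return [
        top.iloc[i : i + bin_size].reset_index(drop=True)
        for i in range(0, len(top) - len(top) % bin_size, bin_size)
    ]


def build_pfm(sequences: Iterable[str]) -> pd.DataFrame:
    """Position frequency matrix over equal-length aligned sequences."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    counts = np.zeros((4, L))
    for s in seqs:
        if len(s) != L:
            raise ValueError("sequences must be aligned to equal length")
        for i, ch in enumerate(s):
            counts[_BASE_CODE[ch], i] += 1
    freqs = counts / counts.sum(axis=0, keepdims=True)
    return pd.DataFrame(freqs, index=list("ACGT"), columns=range(1, L + 1))
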