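"""Flanking-base preference analysis around the perfect consensus site.

Genomic probes carrying exactly one perfect consensus match (and no second
near-match) are split into highest- and lowest-intensity quartiles; base
frequencies at the five positions on each side of the octamer are compared
between quartiles, against the background composition of all eligible
probes, and tested for association with binding strength.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import batch_window_distances, window_distances

__all__ = [
    "filter_flank_eligible",
    "quartile_enrichment",
    "chisq_vs_background",
    "base_quartile_test",
    "FLANK_POSITIONS",
]

FLANK_POSITIONS = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)
BASES = ("A", "C", "G", "T")


def filter_flank_eligible(
    probes: pd.DataFrame,
    consensus: str = "AACCGGTT",
    min_margin: int = 10,
    sequence_col: str = "sequence",
) -> pd.DataFrame:
    """Probes eligible for flank analysis, with the match offset annotated.

    Retains probes whose variable sequence contains exactly one perfect
    consensus window, no additional window within one mismatch anywhere
    else, and whose match sits at least ``min_margin`` bases from both the
    distal probe end and the primer junction. A ``motif_offset`` column is
    added to the returned copy.
    """
    L = len(consensus)
    seqs = probes[sequence_col].tolist()
    lengths = {len(s) for s in seqs}
    if len(lengths) == 1:
        # fast vectorized path for a fixed-length probe set
        d = batch_window_distances(seqs, consensus).min(axis=1)  # (n, windows)
        n_perfect = (d == 0).sum(axis=1)
        n_near = (d <= 1).sum(axis=1)
        off = d.argmin(axis=1)
        probe_len = lengths.pop()
        keep = (
            (n_perfect == 1)
            & (n_near == 1)
            & (off >= min_margin)
            & (probe_len - (off + L) >= min_margin)
        )
        out = probes.loc[keep].copy()
        out["motif_offset"] = off[keep]
        return out
    keep_idx = []
    offsets = []
    for idx, seq in probes[sequence_col].items():
        d = window_distances(seq, consensus).min(axis=0)
        perfect = np.nonzero(d == 0)[0]
        near = np.nonzero(d <= 1)[0]
        if len(perfect) != 1 or len(near) != 1:
            continue
        off = int(perfect[0])
        if off < min_margin or len(seq) - (off + L) < min_margin:
            continue
        keep_idx.append(idx)
        offsets.append(off)
    out = probes.loc[keep_idx].copy()
    out["motif_offset"] = offsets
    return out


def chisq_vs_background(observed_counts, background_proportions) -> tuple[float, float]:
    """Pearson chi-squared of a 4-base count vector against fixed proportions.

    Expected counts are total * background; 3 degrees of freedom.
    """
    obs = np.asarray(observed_counts, dtype=float)
    bg = np.asarray(background_proportions, dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.isclose(bg.sum(), 1.0):
        raise ValueError("background proportions must sum to 1")
    expected = obs.sum() * bg
    if (expected <= 0).any():
        raise ValueError(
            "zero expected count; pool categories before testing"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(stat, df=len(obs) - 1))
    return stat, p


def base_quartile_test(top_count: int, top_total: int,
                       bottom_count: int, bottom_total: int) -> tuple[float, float]:
    """2x2 association test (quartile x base-is-b), Pearson without correction."""
    table = np.array(
        [[top_count, top_total - top_count],
         [bottom_count, bottom_total - bottom_count]],
        dtype=float,
    )
    if table.min() < 0:
        raise ValueError("counts out of range")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _flank_base_counts(df: pd.DataFrame, positions, sequence_col: str,
                       motif_len: int) -> pd.DataFrame:
    """Counts of each base at each flank position (motif-relative)."""
    counts = pd.DataFrame(0, index=pd.Index(positions, name="position"),
                          columns=list(BASES))
    seqs = df[sequence_col].tolist()
    offs = df["motif_offset"].to_numpy(dtype=int)
    if seqs and len({len(s) for s in seqs}) == 1:
        n_cols = len(seqs[0])
        arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(len(seqs), n_cols)
        rows = np.arange(len(seqs))
        for pos in positions:
            idx = offs + (pos if pos < 0 else motif_len + pos - 1)
            valid = (idx >= 0) & (idx < n_cols)
            chars = arr[rows[valid], idx[valid]]
            for base in BASES:
                counts.loc[pos, base] = int((chars == ord(base)).sum())
        return counts
    for seq, off in zip(seqs, offs):
        for pos in positions:
            i = off + pos if pos < 0 else off + motif_len + pos - 1
            if 0 <= i < len(seq):
                counts.loc[pos, seq[i]] += 1
    return counts


def quartile_enrichment(
    eligible: pd.DataFrame,
    consensus: str = "AACCGGTT",
    quartile: float = 0.25,
    positions=FLANK_POSITIONS,
    intensity_col: str = "intensity",
    sequence_col: str = "sequence",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-(position, base) enrichment table for top vs bottom quartile.

    Quartiles are defined on ranked normalized intensity (ties broken by
    probe index so the split is deterministic). Reported per row:

    - freq_top / freq_bottom and their ratio (top / bottom);
    - freq_background over all eligible probes and ratio_vs_background;
    - p_quartile: per-position chi-squared of the top-quartile 4-base count
      vector against background proportions (3 df), plus the analogous
      bottom-quartile p (same value on all four rows of a position);
    - p_value: per-(position, base) 2x2 quartile-membership x base test
      (1 df), with Benjamini-Hochberg q-values and a significance flag at
      ``alpha`` on the raw p.
    """
    if len(eligible) < 8:
        raise ValueError("need at least 8 eligible probes")
    L = len(consensus)
    m = max(1, int(round(quartile * len(eligible))))
    ordered = eligible.sort_values(
        [intensity_col], ascending=False, kind="mergesort"
    )
    top = ordered.head(m)
    bottom = ordered.tail(m)
    if top.empty or bottom.empty:
        raise ValueError("empty quartile")

    counts_top = _flank_base_counts(top, positions, sequence_col, L)
    counts_bottom = _flank_base_counts(bottom, positions, sequence_col, L)
    counts_all = _flank_base_counts(eligible, positions, sequence_col, L)

    rows = []
    for pos in positions:
        ct, cb, ca = counts_top.loc[pos], counts_bottom.loc[pos], counts_all.loc[pos]
        nt, nb, na = ct.sum(), cb.sum(), ca.sum()
        bg = (ca / na).to_numpy()
        # bases absent from the background have zero expected count: pool
        # them out of the goodness-of-fit test (df shrinks accordingly)
        present = bg > 0
        if present.sum() >= 2:
            stat_top, p_top = chisq_vs_background(ct.to_numpy()[present],
                                                  bg[present] / bg[present].sum())
            stat_bot, p_bot = chisq_vs_background(cb.to_numpy()[present],
                                                  bg[present] / bg[present].sum())
        else:
            stat_top = stat_bot = 0.0
            p_top = p_bot = 1.0
        for base in BASES:
            ft = ct[base] / nt
            fb = cb[base] / nb
            fa = ca[base] / na
            stat, p = base_quartile_test(int(ct[base]), int(nt), int(cb[base]), int(nb))
            rows.append({
                "position": pos,
                "base": base,
                "freq_top": ft,
                "freq_bottom": fb,
                "ratio": _safe_ratio(ft, fb),
                "freq_background": fa,
                "ratio_vs_background": _safe_ratio(ft, fa),
                "chi2_position_top": stat_top,
                "p_position_top": p_top,
                "chi2_position_bottom": stat_bot,
                "p_position_bottom": p_bot,
                "chi2": stat,
                "p_value": p,
            })
    table = pd.DataFrame(rows)
    table["q_value"] = stats.false_discovery_control(table["p_value"], method="bh")
    table["significant"] = table["p_value"] < alpha
    table["stars"] = table["p_value"].map(_stars)
    return table


def _safe_ratio(num: float, den: float) -> float:
    """num/den with 0/0 treated as the neutral ratio 1 (no data, no signal)."""
    if den > 0:
        return num / den
    return 1.0 if num == 0 else np.inf


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
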