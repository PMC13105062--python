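"""Probe-library construction for the SNAP binding array.

Builds the probe classes of the array design: 48-mer genomic probes tiled
at a fixed step across candidate regions, and the combinatorial control
libraries (monomer mismatch permutations, dimer spacing series, dimer
mismatch combinations, and self-folding hairpins). Control probes embed
motifs in a constant scaffold chosen to contain no window within two
mismatches of the consensus on either strand, so planted sites are the only
binding-competent sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

from .motifs import hamming, min_window_distance, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeDesignSpec",
    "Probe",
    "DEFAULT_PRIMER",
    "DEFAULT_SCAFFOLD",
    "enumerate_mismatch_variants",
    "tile_region",
    "build_monomer_mismatch_library",
    "build_dimer_spacing_library",
    "build_dimer_mismatch_library",
    "build_hairpin_probe",
]

# 12-nt constant region at the surface-attached (3') end, used for primer
# extension; excluded from the variable probe sequence and from analysis.
DEFAULT_PRIMER = "AAGTTATCACCT"

# Constant scaffold supplying flank and spacer bases for control probes.
# Chosen (and re-verified at build time) to contain no window within two
# mismatches of the default consensus on either strand, including windows
# straddling motif/flank junctions.
DEFAULT_SCAFFOLD = "AGCGTCTTAAGCCTCGCATGATGGCCATCCTGAGTCTAAGTGACCCAGTGTTGCCCCCATAAAT"

PROBE_CLASSES = (
    "genomic",
    "monomer_mismatch",
    "dimer_spacing",
    "dimer_mismatch",
    "hairpin",
    "background",
)


@dataclass(frozen=True)
class ProbeDesignSpec:
    """Array design geometry: probe length, tiling step, consensus motif."""

    probe_len: int = 48
    primer: str = DEFAULT_PRIMER
    tile_step: int = 6
    consensus: str = "AACCGGTT"
    max_region_len: int = 1000

    def __post_init__(self):
        if self.probe_len <= 0:
            raise ValueError("probe_len must be positive")
        if self.tile_step <= 0:
            raise ValueError("tile_step must be positive")
        if len(self.primer) != 12:
            raise ValueError("primer must be 12 bases")
        if any(ch not in "ACGT" for ch in self.consensus):
            raise ValueError("consensus must contain only A/C/G/T")


@dataclass(frozen=True)
class Probe:
    """One array feature: variable sequence (primer excluded) plus metadata."""

    probe_id: str
    sequence: str
    probe_class: str
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class {self.probe_class!r}")
        if any(ch not in "ACGT" for ch in self.sequence):
            raise ValueError("probe sequence must be A/C/G/T only")

    def to_record(self) -> dict:
        return {
            "probe_id": self.probe_id,
            "probe_class": self.probe_class,
            "sequence": self.sequence,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "metadata": json.dumps(self.metadata, sort_keys=True),
        }


def enumerate_mismatch_variants(consensus: str, k: int) -> list[str]:
    """Every sequence differing from the consensus at exactly k positions.

    Returns C(L, k) * 3^k variants in lexicographic order; k = 0 returns
    the consensus itself.
    """
    L = len(consensus)
    if not 0 <= k <= L:
        raise ValueError(f"k={k} out of range 0..{L}")
    variants = []
    for positions in combinations(range(L), k):
        alt_sets = [[b for b in "ACGT" if b != consensus[p]] for p in positions]
        for subs in product(*alt_sets):
            seq = list(consensus)
            for p, b in zip(positions, subs):
                seq[p] = b
            variants.append("".join(seq))
    return sorted(variants)


def tile_region(
    region_sequence: str,
    region_interval: tuple[str, int, int],
    spec: ProbeDesignSpec | None = None,
) -> list[Probe]:
    """Tile a genomic region with fixed-length probes at a constant step.

    Probes start at offsets 0, step, 2*step, ... while a full window fits.
    Regions shorter than one probe, or longer than the design maximum, are
    skipped with a logged reason. Probe IDs encode region and offset so a
    library rebuild is deterministic.
    """
    spec = spec or ProbeDesignSpec()
    chrom, start, end = region_interval
    L = len(region_sequence)
    if end - start != L:
        raise ValueError("region interval length does not match sequence length")
    region_id = f"{chrom}:{start}-{end}"
    if L > spec.max_region_len:
        logger.warning("region %s (%d bp) exceeds %d bp; excluded",
                       region_id, L, spec.max_region_len)
        return []
    if L < spec.probe_len:
        logger.warning("region %s (%d bp) shorter than probe length %d; skipped",
                       region_id, L, spec.probe_len)
        return []
    probes = []
    for off in range(0, L - spec.probe_len + 1, spec.tile_step):
        seq = region_sequence[off : off + spec.probe_len]
        probes.append(
            Probe(
                probe_id=f"{region_id}|{off:05d}",
                sequence=seq,
                probe_class="genomic",
                chrom=chrom,
                start=start + off,
                end=start + off + spec.probe_len,
                metadata={"region_id": region_id, "offset": off},
            )
        )
    return probes


def _check_scaffold(scaffold: str, consensus: str, min_dist: int = 3) -> None:
    d = min_window_distance(scaffold, consensus)
    if d < min_dist:
        raise ValueError(
            f"scaffold contains a window within {d} mismatches of the "
            f"consensus; need >= {min_dist}"
        )


def _embed(scaffold: str, inserts: Sequence[tuple[int, str]], probe_len: int) -> str:
    """Overwrite scaffold bases with motif inserts; scaffold supplies the rest."""
    if len(scaffold) < probe_len:
        raise ValueError("scaffold shorter than probe length")
    seq = list(scaffold[:probe_len])
    for off, ins in inserts:
        if off < 0 or off + len(ins) > probe_len:
            raise ValueError("insert does not fit in probe")
        seq[off : off + len(ins)] = ins
    return "".join(seq)


def build_monomer_mismatch_library(
    consensus: str = "AACCGGTT",
    k: int = 1,
    probe_len: int = 48,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> list[Probe]:
    """One probe per exact-k-mismatch variant, embedded centrally in the scaffold."""
    _check_scaffold(scaffold, consensus)
    off = (probe_len - len(consensus)) // 2
    probes = []
    for i, var in enumerate(enumerate_mismatch_variants(consensus, k)):
        probes.append(
            Probe(
                probe_id=f"mono_k{k}_{i:05d}",
                sequence=_embed(scaffold, [(off, var)], probe_len),
                probe_class="monomer_mismatch",
                metadata={"variant": var, "mismatches": k, "motif_offset": off},
            )
        )
    return probes


def build_dimer_spacing_library(
    consensus: str = "AACCGGTT",
    spacings: Iterable[int] = range(0, 33),
    orientations: Iterable[str] = ("FF", "RF"),
    probe_len: int = 48,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> list[Probe]:
    """Dimeric probes with two motif copies at defined edge-to-edge spacings.

    FF places consensus-consensus; RF places revcomp(consensus)-consensus.
    Spacer and flank bases come from the constant scaffold. Metadata records
    the edge-to-edge spacing and the center-to-center spacing (s + motif
    length), which is the axis used by the helical-phasing fit.
    """
    _check_scaffold(scaffold, consensus)
    L = len(consensus)
    probes = []
    for orientation in sorted(orientations):
        if orientation not in ("FF", "RF"):
            raise ValueError(f"unknown orientation {orientation!r}")
        left = consensus if orientation == "FF" else revcomp(consensus)
        for s in sorted(spacings):
            block = 2 * L + s
            if block > probe_len:
                raise ValueError(
                    f"spacing {s} needs {block} bases; probe is {probe_len}"
                )
            off = (probe_len - block) // 2
            seq = _embed(scaffold, [(off, left), (off + L + s, consensus)], probe_len)
            probes.append(
                Probe(
                    probe_id=f"dimer_{orientation}_s{s:02d}",
                    sequence=seq,
                    probe_class="dimer_spacing",
                    metadata={
                        "spacing": s,
                        "center_spacing": s + L,
                        "orientation": orientation,
                        "left_offset": off,
                        "right_offset": off + L + s,
                    },
                )
            )
    return probes


def build_dimer_mismatch_library(
    consensus: str = "AACCGGTT",
    left_k: int = 0,
    right_k: int = 0,
    pairing: str = "identical",
    spacer_len: int = 1,
    probe_len: int = 48,
    scaffold: str = DEFAULT_SCAFFOLD,
) -> list[Probe]:
    """Dimeric probes with mismatches in the left and/or right binding site.

    pairing='identical' places the same k-mismatch variant in both sites
    (requires left_k == right_k); 'left_only'/'right_only' mutate one site
    and keep the other at the exact consensus.
    """
    _check_scaffold(scaffold, consensus)
    L = len(consensus)
    block = 2 * L + spacer_len
    if block > probe_len:
        raise ValueError("dimer block does not fit in probe")
    off = (probe_len - block) // 2
    roff = off + L + spacer_len

    if pairing == "identical":
        if left_k != right_k:
            raise ValueError("pairing='identical' requires left_k == right_k")
        combos = [(v, v) for v in enumerate_mismatch_variants(consensus, left_k)]
    elif pairing == "left_only":
        if right_k != 0:
            raise ValueError("pairing='left_only' requires right_k == 0")
        combos = [(v, consensus) for v in enumerate_mismatch_variants(consensus, left_k)]
    elif pairing == "right_only":
        if left_k != 0:
            raise ValueError("pairing='right_only' requires left_k == 0")
        combos = [(consensus, v) for v in enumerate_mismatch_variants(consensus, right_k)]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    probes = []
    for i, (lv, rv) in enumerate(combos):
        probes.append(
            Probe(
                probe_id=f"dimermm_{left_k}_{right_k}_{pairing}_{i:05d}",
                sequence=_embed(scaffold, [(off, lv), (roff, rv)], probe_len),
                probe_class="dimer_mismatch",
                metadata={
                    "left_variant": lv,
                    "right_variant": rv,
                    "left_mismatches": hamming(lv, consensus),
                    "right_mismatches": hamming(rv, consensus),
                    "pairing": pairing,
                    "spacer_len": spacer_len,
                },
            )
        )
    return probes


def build_hairpin_probe(duplex_half: str, loop: str = "TTT", probe_id: str | None = None) -> Probe:
    """Single strand folding into a 25-bp hairpin duplex with a short loop.

    The emitted strand is half + loop + revcomp(half): positions i and
    len-1-i are complementary for i < len(half).
    """
    if len(duplex_half) != 25:
        raise ValueError("duplex half must be 25 bases")
    if any(ch not in "ACGT" for ch in duplex_half + loop):
        raise ValueError("hairpin sequences must be A/C/G/T only")
    seq = duplex_half + loop + revcomp(duplex_half)
    return Probe(
        probe_id=probe_id or f"hairpin_{duplex_half}",
        sequence=seq,
        probe_class="hairpin",
        metadata={"duplex_len": len(duplex_half), "loop_len": len(loop)},
    )
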