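"""Build the probe classes of a binding-array design.

Tiles a genomic region into 48-mer probes at 6-bp steps and constructs the
combinatorial control libraries: all k-mismatch permutations of the
consensus octamer, the dimer spacing series, dimer mismatch combinations,
and a self-folding hairpin probe.
"""

from snaparray.design import (
    ProbeDesignSpec,
    build_dimer_mismatch_library,
    build_dimer_spacing_library,
    build_hairpin_probe,
    build_monomer_mismatch_library,
    enumerate_mismatch_variants,
    tile_region,
)
from snaparray.simulate import SimulatorConfig, simulate_regions
import numpy as np

spec = ProbeDesignSpec()  # 48-mer probes, 6-bp tiling, consensus AACCGGTT

# a small synthetic genomic region to tile
regions, _ = simulate_regions(
    SimulatorConfig(n_regions=1, region_length_range=(300, 300)),
    np.random.default_rng(0),
)
row = regions.iloc[0]
probes = tile_region(row.sequence, (row.chrom, row.start, row.end), spec)
print(f"genomic tiling: {len(probes)} probes over a {row.end - row.start} bp "
      f"region (offsets step {spec.tile_step})")

for k in range(5):
    n = len(enumerate_mismatch_variants(spec.consensus, k))
    print(f"k={k} mismatch permutations of {spec.consensus}: {n} variants")

mono = build_monomer_mismatch_library(spec.consensus, k=1)
spacing = build_dimer_spacing_library(spec.consensus, spacings=range(0, 33),
                                      orientations=["FF", "RF"])
dimer_mm = build_dimer_mismatch_library(spec.consensus, 1, 1, "identical")
hairpin = build_hairpin_probe(spacing[0].sequence[:25])
print(f"monomer 1-mismatch library: {len(mono)} probes")
print(f"dimer spacing series 0-32 bp, FF+RF: {len(spacing)} probes")
print(f"dimer identical-1-mismatch library: {len(dimer_mm)} probes")
print(f"hairpin probe length: {len(hairpin.sequence)} nt "
      f"(25 bp stem + {hairpin.metadata['loop_len']} nt loop)")

# Counts follow C(8,k)*3^k; every control probe embeds its motifs in a
# constant scaffold verified to contain no near-consensus window.
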