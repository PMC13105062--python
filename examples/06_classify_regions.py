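"""Direct versus indirect occupancy classification of genomic regions.

Simulates a tiled array, collapses probes into regions by tiling overlap,
classifies each region by its strongest probe against the 3.0 threshold,
counts distinct binding sites, and tests whether cofactor (FoxA1) sites are
enriched in the indirect class.
"""

from snaparray.normalize import normalize_pipeline
from snaparray.regions import (
    classify_region,
    collapse_to_regions,
    count_distinct_sites,
    differential_association,
    indirect_fraction,
)
from snaparray.simulate import simulate_array

arr = simulate_array(seed=4)
final, _ = normalize_pipeline(arr.raw)
probes = arr.probes.copy()
probes["intensity"] = final.loc[probes["probe_id"]].to_numpy()

regions = collapse_to_regions(probes)
for region in regions:
    classify_region(region, threshold=3.0)
    count_distinct_sites(region, probes, threshold=3.0)

n_direct = sum(r.binding_class == "direct" for r in regions)
print(f"{len(probes)} probes collapsed into {len(regions)} regions: "
      f"{n_direct} direct, {len(regions) - n_direct} indirect "
      f"({indirect_fraction(regions):.1f}% indirect)")
sites = [r.n_sites for r in regions if r.binding_class == "direct"]
print("distinct binding sites per direct region:",
      {k: sites.count(k) for k in sorted(set(sites))})

seq_by_locus = {(r.chrom, r.start): r.sequence
                for r in arr.regions.itertuples(index=False)}
seqs = {r.region_id: seq_by_locus[(r.chrom, r.start)] for r in regions}
direct = [r for r in regions if r.binding_class == "direct"]
indirect = [r for r in regions if r.binding_class == "indirect"]
for name, pattern in (("FoxA1", "AWTRTTKRYT"), ("ERa half-site", "RGGTCA")):
    res = differential_association(direct, indirect, pattern=pattern,
                                   sequences=seqs, feature_name=name)
    print(f"{name}: {res['direct_fraction_with_feature']:.0%} of direct vs "
          f"{res['indirect_fraction_with_feature']:.0%} of indirect regions, "
          f"chi2 = {res['chi2']:.1f}, p = {res['p_value']:.2e}")

# Indirect regions (ChIP-occupied but no naked-DNA binding) are enriched
# for FoxA1 sites, the tethering scenario; the ERa half-site shows no class
# difference.
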