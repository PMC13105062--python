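"""Flanking-base preferences around the perfect consensus.

Simulates probes carrying exactly one perfect consensus site whose binding
is boosted when the immediate 3' flank is C, then recovers that preference
by comparing base frequencies between the top and bottom intensity
quartiles with chi-squared tests.
"""

import numpy as np

from snaparray.flanks import filter_flank_eligible, quartile_enrichment
from snaparray.simulate import SimulatorConfig, simulate_flank_probes

cfg = SimulatorConfig()
probes = simulate_flank_probes(1000, cfg, np.random.default_rng(11),
                               flank_effect=True)
eligible = filter_flank_eligible(probes, cfg.consensus)
print(f"{len(eligible)} of {len(probes)} probes pass the eligibility filter")

table = quartile_enrichment(eligible, cfg.consensus)
hits = table[table.significant].sort_values("p_value")
print("significant (position, base) cells:")
for row in hits.head(5).itertuples(index=False):
    print(f"  position {row.position:+d} base {row.base}: "
          f"top/bottom ratio {row.ratio:.2f}, p = {row.p_value:.2e}")

# The planted +1 C preference dominates: C directly 3' of the octamer is
# strongly enriched in the top quartile; other cells are noise at the 5%
# level.
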