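import numpy as np
import pytest

from snaparray.normalize import normalize_pipeline
from snaparray.simulate import SimulatorConfig, simulate_array

CONSENSUS = "AACCGGTT"


@pytest.fixture(scope="session")
def sim_array():
    """One default synthetic array shared across tests (fixed seed)."""
    return simulate_array(SimulatorConfig(), seed=20240901)


@pytest.fixture(scope="session")
def sim_normalized(sim_array):
    """Probe table of the shared array with final normalized intensities."""
    final, _ = normalize_pipeline(sim_array.raw)
    probes = sim_array.probes.copy()
    probes["intensity"] = final.loc[probes["probe_id"]].to_numpy()
    return probes


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def truth_by_locus(sim):
    """Map (chrom, start) -> ground-truth record for a simulated array."""
    out = {}
    for rec in sim.truth.regions:
        chrom, span = rec["region_id"].split(":")
        out[(chrom, int(span.split("-")[0]))] = rec
    return out
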