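import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plastmut.genomic_io import default_topology
from plastmut.synthetic_data import simulate_dataset


@pytest.fixture(scope="session")
def topology():
    return default_topology()


@pytest.fixture(scope="session")
def sim():
    """One default-condition simulated dataset shared across tests."""
    return simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def sim_analysis(sim):
    """Pipeline products (labels, sites, events) on the shared dataset."""
    from plastmut.genomic_io import build_coordinate_map, project_regions
    from plastmut.snp_analysis import analyze_snps
    from plastmut.structural_analysis import analyze_structural

    aln = sim.alignment
    cmap = build_coordinate_map(aln, aln.reference_taxon)
    labels = project_regions(sim.regions, cmap, aln.length)
    sites = analyze_snps(aln, sim.regions, sim.topology)
    events = analyze_structural(aln, sim.regions, sim.topology, labels)
    return {"cmap": cmap, "labels": labels, "sites": sites, "events": events}
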