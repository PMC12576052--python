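import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from qvmeth import io as qio
from qvmeth.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small simulated dataset with sorted+indexed BAM, shared per session."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = SimulationConfig(
        genome_length=3500, n_cpg=30, coverage=12, seed=11
    )
    data = simulate_dataset(cfg, outdir)
    bam = qio.sam_to_sorted_bam(data.sam, outdir / "reads.bam")
    return data, bam
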