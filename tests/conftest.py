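import numpy as np
import pytest

from hcrkit.pool_plate import (
    assign_wells,
    build_pools,
    channel_map,
    write_platemap,
)
from hcrkit.probe_design import design_panel, load_targets
from hcrkit.simulate import synth_transcriptome, write_fasta


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def panel_fasta(tmp_path_factory):
    """16-target synthetic FASTA panel on disk."""
    path = tmp_path_factory.mktemp("panel") / "targets.fa"
    write_fasta(synth_transcriptome(16, (600, 1500), 0.4, seed=11), path)
    return path


@pytest.fixture(scope="session")
def panel(panel_fasta):
    """Designed, pooled and plated 16-target panel."""
    targets, _ = load_targets(panel_fasta)
    sets = design_panel(targets)
    ok = [s for s in sets if s.status == "ok"]
    pools = build_pools(ok)
    plates = assign_wells(pools)
    return {
        "targets": targets,
        "sets": sets,
        "ok": ok,
        "pools": pools,
        "plates": plates,
        "channels": channel_map(),
    }


@pytest.fixture(scope="session")
def panel_platemap_csv(panel, tmp_path_factory):
    path = tmp_path_factory.mktemp("pm") / "platemap.csv"
    write_platemap(panel["plates"], panel["pools"], path)
    return path
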