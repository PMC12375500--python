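import numpy as np
import pytest

from rbpomics.iolib import CountMatrix, SampleDesign
from rbpomics.synthdata import SimConfig, simulate_eclip


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_genes=120)


@pytest.fixture(scope="session")
def eclip_sim(small_config):
    return simulate_eclip(small_config)


def make_design(n_replicates: int = 2, library_size: int = 1_000_000):
    """A balanced 2x2 design with equal library sizes."""
    design = []
    for assay in ("IP", "input"):
        for treatment in ("treated", "untreated"):
            for rep in range(1, n_replicates + 1):
                design.append(
                    SampleDesign(
                        sample_id=f"{assay}_{treatment}_{rep}",
                        assay=assay,
                        treatment=treatment,
                        replicate=rep,
                        library_size=library_size,
                    )
                )
    return design


def cell_matrix(cells: dict[tuple[str, str], list[float]], row_id: str = "c1"):
    """Build a 1-cluster RPM matrix from per-cell value lists.

    ``cells`` maps (assay, treatment) to replicate values; the design is
    built to match, with library size 1e6 so RPM == count numerically.
    """
    design = []
    cols = []
    values = []
    for (assay, treatment), reps in cells.items():
        for i, v in enumerate(reps, start=1):
            sid = f"{assay}_{treatment}_{i}"
            design.append(
                SampleDesign(sid, assay, treatment, i, 1_000_000)
            )
            cols.append(sid)
            values.append(v)
    cm = CountMatrix([row_id], cols, np.array([values], dtype=float))
    return cm, design
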