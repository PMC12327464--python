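import numpy as np
import pytest
from hypothesis import settings

from splitmark import default_design
from splitmark.pipeline import process_run
from splitmark.simulate import Scenario, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return default_design()


def small_scenario(seed=42, **kw):
    """A light scenario (~35k reads) for fast unit-level end-to-end checks."""
    defaults = dict(
        n_cells=50,
        contigs=(("chr1", 600_000), ("chr2", 400_000)),
        peaks_per_mark_per_type=40,
        peak_width=1500,
        fragments_per_cell={"H3K27me3": (100, 10), "H3K27ac": (100, 10), "IgG": (30, 10)},
        umis_per_cell=(120, 10),
        n_genes=100,
        seed=seed,
    )
    defaults.update(kw)
    return Scenario(**defaults)


@pytest.fixture(scope="session")
def small_run(design):
    return simulate(small_scenario(), design)


@pytest.fixture(scope="session")
def small_result(small_run):
    return process_run(small_run, batch_size=20_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
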