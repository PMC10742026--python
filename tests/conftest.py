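import numpy as np
import pytest

from sindex.fourpl import logistic4
from sindex.simulate import SyntheticConfig, generate_screen
from sindex.types import DoseResponseSeries, PrefittedRecord, ScreenTable

GRID_UM = np.logspace(-3, 2, 11)


def make_series(zero=100.0, inf=0.0, lac50_um=0.0, slope=1.0, noise_sd=0.0,
                rng=None, compound="CPD", cell_line="LINE", grid=GRID_UM):
    """A 4PL-generated series; the generator doubles as the fit oracle."""
    resp = logistic4(np.log10(grid), zero, inf, lac50_um, slope)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        resp = resp + rng.normal(0.0, noise_sd, size=len(grid))
    return DoseResponseSeries(compound, cell_line, tuple(grid), tuple(resp))


def make_prefitted_table(records, reference=None):
    table = ScreenTable(dialect="prefitted", source="inline")
    for rec in records:
        table.add(PrefittedRecord(**rec) if isinstance(rec, dict) else rec)
    if reference:
        table.roles[reference] = "reference"
    return table


@pytest.fixture(scope="session")
def small_screen():
    """A 12-compound synthetic screen shared by integration-style tests."""
    return generate_screen(SyntheticConfig(n_compounds=12, seed=7))


@pytest.fixture(scope="session")
def noiseless_screen():
    return generate_screen(SyntheticConfig(n_compounds=8, noise_sd=0.0, seed=11))
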