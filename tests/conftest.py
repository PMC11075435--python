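import numpy as np
import pandas as pd
import pytest

from dfmflow.synthetic_data import (
    EventTable,
    NoiseModel,
    default_noise,
    default_optics,
    default_panel,
    dfm_strain_specs,
)

SEED = 3841


@pytest.fixture(scope="session")
def optics():
    return default_optics()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def specs():
    return dfm_strain_specs()


@pytest.fixture(scope="session")
def spec_by_id(specs):
    return {s.strain_id: s for s in specs}


@pytest.fixture
def noise():
    return default_noise(seed=SEED)


@pytest.fixture
def quiet_noise():
    """No doublets/debris/autofluorescence and no expression spread."""
    return NoiseModel(
        expr_gsd=1.0,
        autofluor={},
        doublet_rate=0.0,
        debris_rate=0.0,
        seed=SEED,
    )


def make_event_table(rows, optics=None, truth=None):
    """Hand-built EventTable from dicts of raw column values."""
    optics = optics or default_optics()
    df = pd.DataFrame(rows)
    for col in ("fsc", "ssc", "ar_ssc") + tuple(optics.channel_keys):
        if col not in df.columns:
            df[col] = 0.0 if col != "fsc" else 1.0
    if truth is not None:
        df["truth"] = truth
    return EventTable(data=df, channels=optics.channel_keys)


@pytest.fixture
def tiny_table_factory():
    return make_event_table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
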