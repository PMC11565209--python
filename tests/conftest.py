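import dataclasses

import numpy as np
import pytest

from gasxkit.data_model import GasxSeries, Protocol
from gasxkit.synthetic_data import AccessionTruth


@pytest.fixture
def truth() -> AccessionTruth:
    """A representative mid-range accession truth."""
    return AccessionTruth(
        accession="ACC001",
        phi=0.05, Amax=40.0, Rd=2.0,
        coupling_slope=200.0, coupling_intercept=-10.0,
        k_gs=100.0, k_A=150.0, lam=60.0,
        SD_ab=120.0, SD_ad=70.0, gcl=40.0, pore=20.0,
        noise_A=0.3, noise_gs=0.005,
    )


@pytest.fixture
def noiseless_truth(truth) -> AccessionTruth:
    return dataclasses.replace(truth, noise_A=0.0, noise_gs=0.0)


def make_series(t, Q, A, gs, Ci=None, Ca=None, protocol=Protocol.STEP_CHANGE,
                plant_id="P1", accession="ACC"):
    """Hand-built series with sensible defaults for unused channels."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    if Ci is None:
        Ci = np.full(n, 120.0)
    if Ca is None:
        Ca = np.full(n, 400.0)
    return GasxSeries(
        plant_id=plant_id, accession=accession, protocol=protocol,
        t=t, Q=np.asarray(Q, dtype=float), A=np.asarray(A, dtype=float),
        gs=np.asarray(gs, dtype=float), Ci=np.asarray(Ci, dtype=float),
        Ca=np.asarray(Ca, dtype=float),
    )
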