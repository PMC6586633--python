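import numpy as np
import pytest

from prmquant.simulator import (AcquisitionSettings, RawAcquisition, Scan,
                                SimulationTruth, build_upr_panel, default_truth,
                                panel_pairs, simulate_acquisition)


@pytest.fixture(scope="session")
def panel():
    return build_upr_panel(seed=1)


@pytest.fixture(scope="session")
def pair(panel):
    return panel_pairs(panel)[0]


@pytest.fixture(scope="session")
def settings():
    return AcquisitionSettings()


@pytest.fixture(scope="session")
def acquisition(panel, settings):
    truth = default_truth(panel, seed=1)
    return simulate_acquisition(panel, settings, truth)


def make_acquisition(scan_tuples, settings=None):
    """Hand-built acquisition from (rt, sequence, label, mzs, intensities)."""
    scans = [Scan(rt=rt, sequence=seq, label=label,
                  mz=np.asarray(mz, float), intensity=np.asarray(inten, float),
                  signal_total=int(np.sum(inten)))
             for rt, seq, label, mz, inten in scan_tuples]
    return RawAcquisition(scans=scans, settings=settings or AcquisitionSettings(),
                          truth=SimulationTruth(amounts={}), panel=[])
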