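import numpy as np
import pytest

from a1atkit import immunoassay as ia
from a1atkit import synthetic as syn

#: dilution grid dense enough that peak interpolation error is ~1e-4
DENSE_DILUTIONS = np.logspace(0, 4.5, int(4.5 * 96) + 1)
#: realistic plate-format grid (10 points per decade)
COARSE_DILUTIONS = np.logspace(0, 4.5, 46)


@pytest.fixture
def noiseless_cfg():
    return syn.GeneratorConfig(seed=7, noise_cv=0.0)


@pytest.fixture
def dense_dilutions():
    return DENSE_DILUTIONS


@pytest.fixture
def coarse_dilutions():
    return COARSE_DILUTIONS


@pytest.fixture
def polymer_assay():
    return ia.polymer_assay()


@pytest.fixture
def total_assay():
    return ia.total_assay()


def build_calibrations(dilutions, noise_cv=0.0, seed=11):
    """Polymer-assay and total-assay calibrations from synthetic standards."""
    pol = ia.polymer_assay()
    tot = ia.total_assay()
    stocks = [0.25e-6, 0.5e-6, 1e-6, 2e-6, 4e-6, 8e-6, 16e-6]
    cfg = syn.GeneratorConfig(seed=seed, noise_cv=noise_cv)
    cal_pol = ia.calibrate_peaks(
        syn.gen_calibration_standards(pol, stocks[:-1], "polymer", dilutions, cfg),
        background=pol.background,
    )
    cfg2 = syn.GeneratorConfig(seed=seed + 1, noise_cv=noise_cv)
    cal_tot_mono = ia.calibrate_peaks(
        syn.gen_calibration_standards(tot, stocks, "monomer", dilutions, cfg2),
        background=tot.background,
    )
    cfg3 = syn.GeneratorConfig(seed=seed + 2, noise_cv=noise_cv)
    cal_tot_pol = ia.calibrate_peaks(
        syn.gen_calibration_standards(tot, stocks, "polymer", dilutions, cfg3),
        background=tot.background,
    )
    return cal_pol, cal_tot_mono, cal_tot_pol


@pytest.fixture(scope="session")
def dense_cals():
    """(cal_polymer_assay, cal_total_monomer, cal_total_polymer) on the dense grid."""
    return build_calibrations(DENSE_DILUTIONS)
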