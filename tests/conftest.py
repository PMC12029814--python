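import numpy as np
import pytest
from scipy.optimize import brentq

from cdbind import (
    CVGroundTruth,
    ITCGroundTruth,
    default_cv_design,
    default_itc_design,
    generate_cv_table,
)

# study conditions: NMR K (L/mol) and ITC (K, n, dH) as fitted in the source data
NMR_K = 81.97
ITC_K = 1096.0
ITC_N = 1.0
ITC_DH_CAL = -1013.0


def hg_bisection(A, B, K):
    """Independent mass-action oracle: root of K (A-x)(B-x) = x by bisection."""
    if A <= 0 or B <= 0 or K <= 0:
        return 0.0
    return brentq(lambda x: K * (A - x) * (B - x) - x, 0.0, min(A, B),
                  xtol=1e-18, rtol=8.9e-16)


@pytest.fixture
def cv_design():
    return default_cv_design()


@pytest.fixture
def noiseless_cv_table(cv_design):
    return generate_cv_table(CVGroundTruth(K=NMR_K, noise_sd=0.0), cv_design)


@pytest.fixture
def itc_design():
    return default_itc_design()


@pytest.fixture
def noiseless_itc_truth(itc_design):
    return ITCGroundTruth(noise_sd=0.0, design=itc_design)
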