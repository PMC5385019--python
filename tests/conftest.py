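import logging

import numpy as np
import pytest

import iolcalc as ic

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def virgin_cohort():
    """133 virgin eyes at the study marginals, Haigis truth, 0.3 D noise."""
    return ic.generate_cohort(ic.virgin_config(133, seed=7))


@pytest.fixture(scope="session")
def noiseless_virgin_srkt():
    """Noiseless virgin cohort whose truth model is SRK/T with A = 118.4."""
    return ic.generate_cohort(
        ic.virgin_config(133, seed=13, truth_formula="srkt", noise_sd_d=0.0)
    )


@pytest.fixture(scope="session")
def noiseless_virgin_haigis():
    return ic.generate_cohort(ic.virgin_config(133, seed=11, noise_sd_d=0.0))


@pytest.fixture
def sample_eye():
    return ic.EyeRecord(
        eye_id="e1", status="virgin", device="pci",
        al_mm=24.42, k_d=43.93, acd_mm=3.16,
        iol_model="920H", iol_power_d=18.5, postop_se_d=-0.35,
    )


def random_biometry(rng, n):
    """Physiologically plausible random (AL, K, ACD) triples for property tests."""
    al = rng.uniform(20.0, 32.0, n)
    k = rng.uniform(36.0, 48.0, n)
    acd = rng.uniform(2.2, 4.2, n)
    return al, k, acd
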