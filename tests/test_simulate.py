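"""Synthetic cohort generator: determinism, calibration closure, marginals,
the post-refractive bias structure, and the device-offset experiment."""

import warnings

import numpy as np
import pytest

import iolcalc as ic
from iolcalc.exceptions import ClampWarning, DomainError


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = ic.generate_cohort(ic.virgin_config(40, seed=3))
        b = ic.generate_cohort(ic.virgin_config(40, seed=3))
        assert a == b

    def test_different_seed_different_cohort(self):
        a = ic.generate_cohort(ic.virgin_config(40, seed=3))
        b = ic.generate_cohort(ic.virgin_config(40, seed=4))
        assert a != b

    def test_paired_arms_share_outcome(self):
        pci, us = ic.generate_paired_cohort(ic.virgin_config(30, seed=5))
        for p, u in zip(pci, us):
            assert p.iol_power_d == u.iol_power_d
            assert p.postop_se_d == u.postop_se_d
            assert p.k_d == u.k_d and p.acd_mm == u.acd_mm
            assert u.al_mm != p.al_mm


class TestCalibrationClosure:
    """With zero noise the truth formula at the truth constants predicts the
    generated outcomes exactly."""

    def test_haigis_truth(self, noiseless_virgin_haigis):
        const = ic.simulate.DEFAULT_TRUTH_CONSTANTS
        res = ic.prediction_errors(noiseless_virgin_haigis, "haigis", const)
        assert np.max(np.abs(res.errors)) < 1e-9

    def test_srkt_truth(self, noiseless_virgin_srkt):
        const = ic.IOLConstants(iol_model="920H", device="pci", A=118.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            res = ic.prediction_errors(noiseless_virgin_srkt, "srkt", const)
        assert np.max(np.abs(res.errors)) < 1e-9


class TestMarginals:
    def test_virgin_axial_length_mean(self):
        cohort = ic.generate_cohort(ic.virgin_config(10000, seed=21))
        al = np.array([e.al_mm for e in cohort])
        # SE of the mean at n = 10000, sd 2.40 is 0.024; 0.08 is > 3 SE
        assert abs(al.mean() - 24.42) < 0.08

    def test_al_acd_correlation_positive(self):
        cohort = ic.generate_cohort(ic.virgin_config(5000, seed=22))
        al = np.array([e.al_mm for e in cohort])
        acd = np.array([e.acd_mm for e in cohort])
        r = np.corrcoef(al, acd)[0, 1]
        assert 0.3 < r < 0.5

    def test_post_lasik_profile_location(self):
        cohort = ic.generate_cohort(ic.post_lasik_config(5000, seed=23))
        k = np.array([e.k_d for e in cohort])
        al = np.array([e.al_mm for e in cohort])
        assert abs(k.mean() - 36.35) < 0.05
        assert abs(al.mean() - 30.06) < 0.15

    def test_powers_on_step_grid(self):
        cohort = ic.generate_cohort(ic.virgin_config(200, seed=24))
        for e in cohort:
            assert (e.iol_power_d * 2) == round(e.iol_power_d * 2)


@pytest.fixture(scope="module")
def post_lasik_errors():
    cohort = ic.generate_cohort(ic.post_lasik_config(2000, seed=31))
    const = ic.simulate.DEFAULT_TRUTH_CONSTANTS
    out = {}
    methods = {
        "uncorrected": ic.get_method("haigis"),
        "koch_maloney": ic.get_method("koch_maloney_haigis"),
        "shammas_cd": ic.get_method("shammas_cd_haigis"),
        "haigis_l": ic.get_method("haigis_l"),
        "shammas_pl": ic.get_method("shammas_cd_shammas_pl"),
    }
    for name, method in methods.items():
        res = ic.prediction_errors(cohort, method, const)
        out[name] = float(res.errors.mean())
    return out


class TestPostRefractiveBiasStructure:
    def test_uncorrected_k_is_hyperopic(self, post_lasik_errors):
        assert post_lasik_errors["uncorrected"] > 0.5

    def test_every_correction_reduces_the_bias(self, post_lasik_errors):
        me0 = abs(post_lasik_errors["uncorrected"])
        for name in ("koch_maloney", "shammas_cd", "haigis_l", "shammas_pl"):
            assert abs(post_lasik_errors[name]) < me0

    def test_shammas_cd_haigis_is_nearly_unbiased(self, post_lasik_errors):
        # its corneal-power map is the generator's own truth map
        assert abs(post_lasik_errors["shammas_cd"]) < 0.1


class TestDeviceOffset:
    def test_recorded_al_shorter_on_us_arm(self):
        pci, us = ic.generate_paired_cohort(ic.virgin_config(500, seed=41))
        d = np.array([p.al_mm - u.al_mm for p, u in zip(pci, us)])
        assert abs(d.mean() - 0.15) < 0.02

    def test_literal_offset_with_fixed_constants_is_myopic(self):
        """Shortening the recorded axial length with the constants held fixed
        shifts the mean error myopically (negative): the formula sees a shorter
        eye, picks a higher vergence, and the prediction turns hyperopic
        relative to the unchanged outcome."""
        cohort = ic.generate_cohort(ic.virgin_config(2000, seed=42))
        const = ic.simulate.DEFAULT_TRUTH_CONSTANTS
        base = ic.prediction_errors(cohort, "haigis", const).errors.mean()
        shifted = ic.with_device_offset(cohort, 0.15)
        off = ic.prediction_errors(shifted, "haigis", const).errors.mean()
        assert off - base < -0.1

    def test_with_device_offset_relabels_device(self, virgin_cohort):
        out = ic.with_device_offset(virgin_cohort[:5], 0.15)
        assert all(e.device == "us_topo" for e in out)
        assert out[0].al_mm == pytest.approx(virgin_cohort[0].al_mm - 0.15)


@pytest.fixture(scope="module")
def fixture():
    return ic.make_study_fixture(seed=0)


class TestStudyFixture:
    def test_cohort_sizes(self, fixture):
        assert sum(len(v) for v in fixture.virgin.values()) == 2 * 133
        assert sum(len(v) for v in fixture.post_lasik.values()) == 2 * 10

    def test_model_distribution(self, fixture):
        virgin = fixture.virgin["pci"]
        counts = {m: sum(e.iol_model == m for e in virgin) for m, *_ in ic.simulate.STUDY_MODELS}
        assert counts == {"920H": 36, "Adapt-AO": 33, "SN60WF": 33, "ZCB00": 31}

    def test_constants_per_model_and_device(self, fixture):
        keys = {(c.iol_model, c.device) for c in fixture.constants}
        assert len(keys) == 8

    def test_virgin_haigis_nearly_unbiased_after_optimization(self, fixture):
        for device in ("pci", "us_topo"):
            errs = np.concatenate([
                ic.prediction_errors(
                    [e for e in fixture.virgin[device] if e.iol_model == m],
                    "haigis",
                    ic.constants_lookup(fixture.constants, next(
                        e for e in fixture.virgin[device] if e.iol_model == m)),
                ).errors
                for m, *_ in ic.simulate.STUDY_MODELS
            ])
            assert abs(errs.mean()) < 0.05


class TestConfigValidation:
    def test_bad_step(self):
        with pytest.raises(DomainError):
            ic.virgin_config(10, iol_step_d=0.3)

    def test_bad_n(self):
        with pytest.raises(DomainError):
            ic.virgin_config(0)

    def test_impossible_truncation(self):
        cfg = ic.virgin_config(5, al_mean=60.0)
        with pytest.raises(DomainError):
            ic.generate_cohort(cfg)
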