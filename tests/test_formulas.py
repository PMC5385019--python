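"""The five vergence formulas: published branch rules, round-trip exactness,
monotonicity, and agreement between closed-form and root-found inverses."""

import math
import warnings

import numpy as np
import pytest

import iolcalc as ic
from iolcalc.exceptions import ClampWarning, DegenerateGeometryError, DomainError
from iolcalc.formulas import (
    FormulaInputs,
    holladay1_geometry,
    hofferq_elp,
    srkt_geometry,
)

from conftest import random_biometry

A_CONST = 118.4
PACD = 5.04
SF = 1.45
TRIPLE = (0.154, 0.166, 0.166)
C_CONST = 4.6866


def _inputs(formula, al, k, acd):
    """Formula inputs on measured biometry with typical constants."""
    const = ic.IOLConstants(iol_model="m", device="pci", A=A_CONST, pACD=PACD,
                            SF=SF, a0=TRIPLE[0], a1=TRIPLE[1], a2=TRIPLE[2],
                            C=C_CONST)
    inp = FormulaInputs(al_mm=al, k_d=k, acd_mm=acd, constants=const)
    if formula == "haigis":
        inp.r_mm = ic.k_to_radius(k)
    return inp


class TestSrkt:
    def test_lcor_short_eye_branch(self):
        r, elp22, _ = srkt_geometry(22.0, 44.0, A_CONST)
        # LCOR = AL on the short branch: nudging AL moves ELP only through LCOR/Cw
        assert srkt_geometry(22.0, 44.0, A_CONST) == srkt_geometry(22.0, 44.0, A_CONST)

    def test_lcor_long_eye_polynomial(self):
        lcor = -3.446 + 1.716 * 30.0 - 0.0237 * 900.0
        assert lcor == pytest.approx(26.704, abs=1e-9)
        # the polynomial branch changes the corneal-width term vs the identity branch
        cw_long = -5.41 + 0.58412 * lcor + 0.098 * 44.0
        cw_id = -5.41 + 0.58412 * 30.0 + 0.098 * 44.0
        assert cw_long < cw_id

    def test_optical_axial_length(self):
        _, _, lopt = srkt_geometry(24.42, 43.93, A_CONST)
        assert lopt == pytest.approx(24.5814782, abs=1e-6)

    def test_clamped_height_warns(self):
        # steep cornea + very long eye pushes the corneal chord past the diameter
        with pytest.warns(ClampWarning):
            ic.srkt_power(38.0, 48.0, A_CONST, 0.0)


class TestHofferQ:
    @pytest.mark.parametrize("al, k", [(22.0, 44.0), (25.0, 44.0)])
    def test_branch_rule(self, al, k):
        # M=+1,G=28 for AL<=23; M=-1,G=23.5 above: the ELP kink is continuous at 23
        elp = hofferq_elp(al, k, PACD)
        assert np.isfinite(elp)

    def test_branch_jump_at_23_is_small(self):
        # the published M/G switch leaves a genuine but tiny ELP step at 23 mm
        jump = abs(hofferq_elp(23.0, 44.0, PACD) - hofferq_elp(23.0 + 1e-9, 44.0, PACD))
        assert 0.0 < jump < 5e-3

    def test_al_clamp_applies_to_elp_only(self):
        # ELP saturates above 31 mm while the vergence still sees the true length
        assert hofferq_elp(32.0, 44.0, PACD) == hofferq_elp(31.0, 44.0, PACD)
        assert ic.hofferq_power(32.0, 44.0, PACD) != ic.hofferq_power(31.0, 44.0, PACD)

    def test_degenerate_vergence(self):
        with pytest.raises(DegenerateGeometryError):
            ic.hofferq_power(24.0, 26.0, PACD, target_ref_d=-40.0)


class TestHolladay1:
    def test_chord_scaling_no_cap(self):
        _, elp, _ = holladay1_geometry(23.45, 44.0, SF)
        r = 337.5 / 44.0
        expected = 0.56 + r - math.sqrt(r * r - 12.5 ** 2 / 4.0) + SF
        assert elp == pytest.approx(expected, abs=1e-12)

    def test_chord_cap(self):
        # AG(26.0) = 13.859 caps at 13.5
        _, elp26, _ = holladay1_geometry(26.0, 44.0, SF)
        _, elp_cap, _ = holladay1_geometry(13.5 * 23.45 / 12.5, 44.0, SF)
        assert elp26 == pytest.approx(elp_cap, abs=1e-12)

    def test_optical_length_offset(self):
        _, _, alm = holladay1_geometry(24.42, 44.0, SF)
        assert alm == pytest.approx(24.62, abs=1e-12)


class TestHaigis:
    def test_elp_from_published_constants(self):
        d = ic.formulas.haigis_elp(3.16, 24.42, *TRIPLE)
        assert d == pytest.approx(4.73228, abs=1e-10)

    def test_zero_target_vergence_is_corneal_power(self):
        dc = ic.formulas.haigis_corneal_power(k_d=43.93)
        p0 = ic.haigis_power(24.42, 3.16, *TRIPLE, k_d=43.93, target_ref_d=0.0)
        d = ic.formulas.haigis_elp(3.16, 24.42, *TRIPLE)
        expected = 1336.0 / (24.42 - d) - 1336.0 / (1336.0 / dc - d)
        assert p0 == pytest.approx(expected, abs=1e-12)

    def test_degenerate_constants_give_fixed_elp(self):
        p1 = ic.haigis_power(24.0, 2.5, 4.7, 0.0, 0.0, k_d=44.0)
        p2 = ic.haigis_power(24.0, 4.5, 4.7, 0.0, 0.0, k_d=44.0)
        assert p1 == p2

    def test_corrected_k_typed_directly(self):
        # an explicit corneal power bypasses the radius/index path entirely
        direct = ic.formulas.haigis_corneal_power(corneal_power_d=34.64)
        assert direct == 34.64

    def test_elp_beyond_axial_length_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ic.haigis_power(20.0, 3.0, 18.0, 0.1, 0.1, k_d=44.0)


class TestShammasPL:
    def test_length_correction_fixed_point(self):
        assert ic.shammas_pl_power(23.0, 34.6, C_CONST, 0.0) == pytest.approx(
            1336.0 / (23.0 - C_CONST - 0.05)
            - 1.0 / (1.0125 / 34.6 - (C_CONST + 0.05) / 1336.0),
            abs=1e-12,
        )

    def test_length_correction_long_eye(self):
        lstar = 30.06 - 0.1 * (30.06 - 23.0)
        assert lstar == pytest.approx(29.354, abs=1e-12)

    def test_zero_target_simplification(self):
        p = ic.shammas_pl_power(30.06, 34.64, C_CONST, 0.0)
        lstar = 30.06 - 0.1 * (30.06 - 23.0)
        expected = 1336.0 / (lstar - C_CONST - 0.05) - 1.0 / (
            1.0125 / 34.64 - (C_CONST + 0.05) / 1336.0
        )
        assert p == pytest.approx(expected, abs=1e-12)


class TestInversion:
    @pytest.mark.parametrize("formula", ic.formulas.FORMULAS)
    def test_round_trip_randomized(self, formula, rng):
        al, k, acd = random_biometry(rng, 200)
        targets = rng.uniform(-4.0, 1.5, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            for a, kk, c, t in zip(al, k, acd, targets):
                inp = _inputs(formula, a, kk, c)
                p = ic.formula_power(formula, inp, t)
                back = ic.predicted_refraction(formula, inp, p)
                assert back == pytest.approx(t, abs=1e-6)

    @pytest.mark.parametrize("formula", ic.formulas.FORMULAS)
    def test_closed_form_matches_bisection(self, formula, rng):
        al, k, acd = random_biometry(rng, 25)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            for a, kk, c in zip(al, k, acd):
                inp = _inputs(formula, a, kk, c)
                p = ic.formula_power(formula, inp, -0.5)
                closed = ic.predicted_refraction(formula, inp, p, solver="closed")
                bisect = ic.predicted_refraction(formula, inp, p, solver="bisect")
                assert closed == pytest.approx(bisect, abs=1e-8)

    def test_refraction_strictly_decreasing_in_power(self, rng):
        inp = _inputs("haigis", 24.42, 43.93, 3.16)
        powers = np.arange(5.0, 30.0, 0.5)
        refs = [ic.predicted_refraction("haigis", inp, p) for p in powers]
        assert np.all(np.diff(refs) < 0)

    def test_no_root_out_of_bracket(self):
        inp = _inputs("haigis", 24.42, 43.93, 3.16)
        with pytest.raises(DomainError):
            ic.predicted_refraction("haigis", inp, 120.0, solver="bisect")


class TestMonotonicity:
    @pytest.mark.parametrize("formula", ic.formulas.FORMULAS)
    def test_emmetropic_power_decreases_with_axial_length(self, formula):
        powers = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            for al in np.arange(21.0, 30.0, 0.5):
                powers.append(ic.formula_power(formula, _inputs(formula, al, 43.0, 3.2), 0.0))
        assert np.all(np.diff(powers) < 0)

    @pytest.mark.parametrize("formula", ic.formulas.FORMULAS)
    def test_emmetropic_power_increases_with_k(self, formula):
        # flatter corneas need stronger implants: P rises with corneal power...
        # for the ELP-through-K formulas the ELP effect partially offsets, but the
        # net vergence effect dominates over the physiological range
        powers = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClampWarning)
            for k in np.arange(38.0, 48.0, 0.5):
                powers.append(ic.formula_power(formula, _inputs(formula, 24.0, k, 3.2), 0.0))
        assert np.all(np.diff(powers) < 0) or np.all(np.diff(powers) > 0)
        # direction check on the ELP-free Haigis family
        if formula in ("haigis", "shammas_pl"):
            assert powers[-1] < powers[0]


def test_srkt_holladay_shared_vergence_block():
    """With ELP matched and the same corneal power the two vergence blocks agree
    loosely (they differ only in corneal index and retinal-thickness terms)."""
    al, k = 24.0, 43.5
    _, elp_srkt, _ = srkt_geometry(al, k, A_CONST)
    r = 337.5 / k
    ag = min(al * 12.5 / 23.45, 13.5)
    acd_anat = 0.56 + r - math.sqrt(r * r - ag * ag / 4.0)
    sf = elp_srkt - acd_anat
    p_srkt = ic.srkt_power(al, k, A_CONST, -0.25)
    p_hol = ic.holladay1_power(al, k, sf, -0.25)
    assert abs(p_srkt - p_hol) < 0.25
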