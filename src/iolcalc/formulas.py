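"""The five vergence-based IOL power formulas, each invertible.

Every formula is exposed in both directions: the power that achieves a target
spectacle refraction, and the predicted spectacle refraction for an implanted
power.  The inverse direction has an exact closed form for all five formulas
because each power expression is linear-fractional in the (corneal-plane or
embedded) target refraction; a bracketed bisection solver is also provided and
the two must agree — the round-trip contract
``predicted_refraction(power_for_target(R)) == R`` is normative.

Corneal power conventions
-------------------------
SRK/T, Holladay 1 and Hoffer Q consume the displayed K (index 1.3375) as
published.  The Haigis family consumes the corneal radius with its own
fictitious index nc = 1.3315.  When an already-corrected corneal power
(Koch–Maloney or Shammas c.d., a 1.3375-style number) is fed to Haigis it is
used directly as the corneal power without re-indexing — the common clinical
practice of typing the corrected K into the device.

A quirk worth knowing: the published Hoffer Q effective-lens-position formula
takes tangents of *numeric values interpreted as degrees* (the K reading in
diopters and an axial-length expression in mm are both passed to ``tan`` as
degree arguments).  That idiosyncrasy is reproduced faithfully here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .biometry import (
    AQUEOUS_INDEX,
    HAIGIS_CORNEAL_INDEX,
    IOLConstants,
    VERTEX_MM,
    corneal_to_spectacle_plane,
    k_to_radius,
    spectacle_to_corneal_plane,
)
from .exceptions import ClampWarning, DegenerateGeometryError, DomainError

FORMULAS = ("srkt", "hofferq", "holladay1", "haigis", "shammas_pl")

_NA = AQUEOUS_INDEX  # 1.336


def _clamped_sqrt(r: float, half_chord_sq: float, label: str) -> float:
    """sqrt(r^2 - c) with c clamped at r^2 (flat-cornea corner case), warning on clamp."""
    rsq = r * r
    if half_chord_sq > rsq:
        warnings.warn(
            f"{label}: corneal height term clamped (chord exceeds corneal diameter)",
            ClampWarning,
            stacklevel=3,
        )
        return 0.0
    return math.sqrt(rsq - half_chord_sq)


# ---------------------------------------------------------------------------
# Shared thick-lens vergence block (SRK/T and Holladay 1)
# ---------------------------------------------------------------------------

def _vergence_power(r: float, axl: float, elp: float, ncm1: float, ref: float) -> float:
    """IOL power from the retina/cornea vergence balance.

    ``axl`` is the formula's optical axial length (mm), ``elp`` the assumed
    lens plane (mm), ``ncm1`` the formula's (corneal index - 1), ``ref`` the
    target refraction at the spectacle plane (vertex handled internally).
    """
    x = _NA * r - ncm1 * axl
    w = _NA * r - ncm1 * elp
    num = 1000.0 * _NA * (x - 0.001 * ref * (VERTEX_MM * x + axl * r))
    den = (axl - elp) * (w - 0.001 * ref * (VERTEX_MM * w + elp * r))
    if abs(den) < 1e-12:
        raise DegenerateGeometryError("vergence denominator vanished")
    return num / den


def _vergence_refraction(r: float, axl: float, elp: float, ncm1: float, power: float) -> float:
    """Closed-form inverse of :func:`_vergence_power` (linear-fractional in REF)."""
    x = _NA * r - ncm1 * axl
    w = _NA * r - ncm1 * elp
    num = 1000.0 * _NA * x - power * (axl - elp) * w
    den = _NA * (VERTEX_MM * x + axl * r) - 0.001 * power * (axl - elp) * (
        VERTEX_MM * w + elp * r
    )
    if abs(den) < 1e-12:
        raise DegenerateGeometryError("refraction inverse denominator vanished")
    return num / den


# ---------------------------------------------------------------------------
# SRK/T
# ---------------------------------------------------------------------------

def srkt_geometry(al_mm: float, k_d: float, a_const: float) -> tuple[float, float, float]:
    """Return (corneal radius, ELP, optical axial length) of the SRK/T model."""
    r = 337.5 / k_d
    if al_mm <= 24.2:
        lcor = al_mm
    else:
        lcor = -3.446 + 1.716 * al_mm - 0.0237 * al_mm * al_mm
    cw = -5.41 + 0.58412 * lcor + 0.098 * k_d
    h = r - _clamped_sqrt(r, cw * cw / 4.0, "srkt")
    elp = h + (0.62467 * a_const - 68.747) - 3.336
    lopt = al_mm + 0.65696 - 0.02029 * al_mm
    return r, elp, lopt


def srkt_power(al_mm: float, k_d: float, a_const: float, target_ref_d: float = 0.0) -> float:
    """SRK/T IOL power (D) for a target spectacle refraction."""
    r, elp, lopt = srkt_geometry(al_mm, k_d, a_const)
    return _vergence_power(r, lopt, elp, 0.333, target_ref_d)


def srkt_refraction(al_mm: float, k_d: float, a_const: float, iol_power_d: float) -> float:
    """Predicted spectacle refraction (D) for an implanted power under SRK/T."""
    r, elp, lopt = srkt_geometry(al_mm, k_d, a_const)
    return _vergence_refraction(r, lopt, elp, 0.333, iol_power_d)


# ---------------------------------------------------------------------------
# Holladay 1
# ---------------------------------------------------------------------------

def holladay1_geometry(al_mm: float, k_d: float, sf: float) -> tuple[float, float, float]:
    """Return (corneal radius, ELP, optical axial length) of the Holladay 1 model."""
    r = 337.5 / k_d
    ag = min(al_mm * 12.5 / 23.45, 13.5)
    acd_anat = 0.56 + r - _clamped_sqrt(r, ag * ag / 4.0, "holladay1")
    elp = acd_anat + sf
    alm = al_mm + 0.2
    return r, elp, alm


def holladay1_power(al_mm: float, k_d: float, sf: float, target_ref_d: float = 0.0) -> float:
    r, elp, alm = holladay1_geometry(al_mm, k_d, sf)
    return _vergence_power(r, alm, elp, 1.0 / 3.0, target_ref_d)


def holladay1_refraction(al_mm: float, k_d: float, sf: float, iol_power_d: float) -> float:
    r, elp, alm = holladay1_geometry(al_mm, k_d, sf)
    return _vergence_refraction(r, alm, elp, 1.0 / 3.0, iol_power_d)


# ---------------------------------------------------------------------------
# Hoffer Q
# ---------------------------------------------------------------------------

def hofferq_elp(al_mm: float, k_d: float, pacd: float) -> float:
    """Hoffer Q personalized-ACD effective lens position (mm).

    The axial length is clamped to [18.5, 31] mm inside the ELP expression
    only; tangent arguments are numeric values read as degrees, as published.
    """
    al_e = min(max(al_mm, 18.5), 31.0)
    if al_mm <= 23.0:
        m, g = 1.0, 28.0
    else:
        m, g = -1.0, 23.5
    t_k = math.tan(math.radians(k_d))
    t_al = math.tan(math.radians(0.1 * (g - al_e) ** 2))
    return (
        pacd
        + 0.3 * (al_e - 23.5)
        + t_k * t_k
        + 0.1 * m * (23.5 - al_e) ** 2 * t_al
        - 0.99166
    )


def hofferq_power(al_mm: float, k_d: float, pacd: float, target_ref_d: float = 0.0) -> float:
    elp = hofferq_elp(al_mm, k_d, pacd)
    rc = spectacle_to_corneal_plane(target_ref_d)
    if k_d + rc <= 0:
        raise DegenerateGeometryError("corneal vergence non-positive in Hoffer Q")
    return 1336.0 / (al_mm - elp - 0.05) - 1.336 / (
        1.336 / (k_d + rc) - (elp + 0.05) / 1000.0
    )


def hofferq_refraction(al_mm: float, k_d: float, pacd: float, iol_power_d: float) -> float:
    elp = hofferq_elp(al_mm, k_d, pacd)
    t1 = 1336.0 / (al_mm - elp - 0.05)
    if abs(t1 - iol_power_d) < 1e-12:
        raise DegenerateGeometryError("implanted power at the Hoffer Q vergence pole")
    inner = (elp + 0.05) / 1000.0 + 1.336 / (t1 - iol_power_d)
    if inner <= 0:
        raise DegenerateGeometryError("non-positive corneal vergence in Hoffer Q inverse")
    rc = 1.336 / inner - k_d
    return corneal_to_spectacle_plane(rc)


# ---------------------------------------------------------------------------
# Haigis
# ---------------------------------------------------------------------------

def haigis_corneal_power(
    *,
    k_d: float | None = None,
    r_mm: float | None = None,
    corneal_power_d: float | None = None,
    nc: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Corneal power entering the Haigis formula.

    Priority: an explicit ``corneal_power_d`` (e.g. a Koch–Maloney or Shammas
    corrected K typed in directly) is used as-is; otherwise the radius (given
    or derived from the displayed K at 1.3375) is re-indexed with nc.
    """
    if corneal_power_d is not None:
        return corneal_power_d
    if r_mm is None:
        if k_d is None:
            raise DomainError("Haigis needs one of corneal_power_d, r_mm, or k_d")
        r_mm = k_to_radius(k_d)
    if r_mm <= 0:
        raise DomainError(f"corneal radius must be positive, got {r_mm}")
    return (nc - 1.0) * 1000.0 / r_mm


def haigis_elp(acd_mm: float, al_mm: float, a0: float, a1: float, a2: float) -> float:
    """Predicted ELP d = a0 + a1*ACD + a2*AL (mm)."""
    return a0 + a1 * acd_mm + a2 * al_mm


def haigis_power(
    al_mm: float,
    acd_mm: float,
    a0: float,
    a1: float,
    a2: float,
    *,
    r_mm: float | None = None,
    k_d: float | None = None,
    corneal_power_d: float | None = None,
    target_ref_d: float = 0.0,
    nc: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Haigis IOL power (D) for a target spectacle refraction."""
    dc = haigis_corneal_power(k_d=k_d, r_mm=r_mm, corneal_power_d=corneal_power_d, nc=nc)
    d = haigis_elp(acd_mm, al_mm, a0, a1, a2)
    z = dc + spectacle_to_corneal_plane(target_ref_d)
    if al_mm <= d:
        raise DegenerateGeometryError(f"ELP {d:.2f} mm not shorter than AL {al_mm:.2f} mm")
    if z <= 0:
        raise DegenerateGeometryError("non-positive corneal vergence in Haigis")
    return 1336.0 / (al_mm - d) - 1336.0 / (1336.0 / z - d)


def haigis_refraction(
    al_mm: float,
    acd_mm: float,
    a0: float,
    a1: float,
    a2: float,
    iol_power_d: float,
    *,
    r_mm: float | None = None,
    k_d: float | None = None,
    corneal_power_d: float | None = None,
    nc: float = HAIGIS_CORNEAL_INDEX,
) -> float:
    """Closed-form Haigis inverse: z' = 1336/(d + 1336/(1336/(AL-d) - P))."""
    dc = haigis_corneal_power(k_d=k_d, r_mm=r_mm, corneal_power_d=corneal_power_d, nc=nc)
    d = haigis_elp(acd_mm, al_mm, a0, a1, a2)
    if al_mm <= d:
        raise DegenerateGeometryError(f"ELP {d:.2f} mm not shorter than AL {al_mm:.2f} mm")
    t = 1336.0 / (al_mm - d) - iol_power_d
    if abs(t) < 1e-12:
        raise DegenerateGeometryError("implanted power at the Haigis vergence pole")
    z = 1336.0 / (d + 1336.0 / t)
    return corneal_to_spectacle_plane(z - dc)


# ---------------------------------------------------------------------------
# Shammas-PL
# ---------------------------------------------------------------------------

def shammas_pl_power(
    al_mm: float,
    kc_d: float,
    c_const: float,
    target_ref_d: float = 0.0,
    *,
    vertex_correct_target: bool = False,
    vergence_factor: float = 1.0125,
) -> float:
    """Shammas post-LASIK IOL power (D) for an already-corrected corneal power.

    The axial length enters through the corrected length L* = AL - 0.1*(AL - 23).
    The published formula consumes the target refraction directly (no vertex
    transposition); set ``vertex_correct_target`` to transpose it first.
    """
    lstar = al_mm - 0.1 * (al_mm - 23.0)
    r = spectacle_to_corneal_plane(target_ref_d) if vertex_correct_target else target_ref_d
    if kc_d + r <= 0:
        raise DegenerateGeometryError("corneal vergence non-positive in Shammas-PL")
    inner = vergence_factor / (kc_d + r) - (c_const + 0.05) / 1336.0
    if inner <= 0:
        raise DegenerateGeometryError("degenerate second vergence term in Shammas-PL")
    return 1336.0 / (lstar - c_const - 0.05) - 1.0 / inner


def shammas_pl_refraction(
    al_mm: float,
    kc_d: float,
    c_const: float,
    iol_power_d: float,
    *,
    vertex_correct_target: bool = False,
    vergence_factor: float = 1.0125,
) -> float:
    lstar = al_mm - 0.1 * (al_mm - 23.0)
    t1 = 1336.0 / (lstar - c_const - 0.05)
    if abs(t1 - iol_power_d) < 1e-12:
        raise DegenerateGeometryError("implanted power at the Shammas-PL vergence pole")
    inner = (c_const + 0.05) / 1336.0 + 1.0 / (t1 - iol_power_d)
    if inner <= 0:
        raise DegenerateGeometryError("non-positive vergence in Shammas-PL inverse")
    r = vergence_factor / inner - kc_d
    return corneal_to_spectacle_plane(r) if vertex_correct_target else r


# ---------------------------------------------------------------------------
# Generic dispatch
# ---------------------------------------------------------------------------

@dataclass
class FormulaInputs:
    """Biometry and constants for one formula evaluation.

    ``k_d`` is the corneal power the formula should consume (a measured K for
    virgin eyes, an already-corrected Kc for no-history methods); ``r_mm`` or
    ``corneal_power_d`` override the Haigis corneal-power path explicitly.
    """

    al_mm: float
    constants: IOLConstants
    k_d: float | None = None
    r_mm: float | None = None
    corneal_power_d: float | None = None
    acd_mm: float | None = None


def _require(value, formula: str, name: str):
    if value is None:
        raise DomainError(f"formula {formula!r} requires {name}")
    return value


def formula_power(formula: str, inputs: FormulaInputs, target_ref_d: float = 0.0) -> float:
    """IOL power for a target spectacle refraction under any supported formula."""
    c = inputs.constants
    if formula == "srkt":
        return srkt_power(inputs.al_mm, _require(inputs.k_d, formula, "k_d"),
                          _require(c.A, formula, "A constant"), target_ref_d)
    if formula == "hofferq":
        return hofferq_power(inputs.al_mm, _require(inputs.k_d, formula, "k_d"),
                             _require(c.pACD, formula, "pACD constant"), target_ref_d)
    if formula == "holladay1":
        return holladay1_power(inputs.al_mm, _require(inputs.k_d, formula, "k_d"),
                               _require(c.SF, formula, "surgeon factor"), target_ref_d)
    if formula == "haigis":
        a0, a1, a2 = c.haigis_triple
        return haigis_power(
            inputs.al_mm, _require(inputs.acd_mm, formula, "acd_mm"), a0, a1, a2,
            r_mm=inputs.r_mm, k_d=inputs.k_d, corneal_power_d=inputs.corneal_power_d,
            target_ref_d=target_ref_d,
        )
    if formula == "shammas_pl":
        return shammas_pl_power(inputs.al_mm, _require(inputs.k_d, formula, "kc_d"),
                                _require(c.C, formula, "C constant"), target_ref_d)
    raise DomainError(f"unknown formula {formula!r}")


def _closed_form_refraction(formula: str, inputs: FormulaInputs, iol_power_d: float) -> float:
    c = inputs.constants
    if formula == "srkt":
        return srkt_refraction(inputs.al_mm, inputs.k_d, c.A, iol_power_d)
    if formula == "hofferq":
        return hofferq_refraction(inputs.al_mm, inputs.k_d, c.pACD, iol_power_d)
    if formula == "holladay1":
        return holladay1_refraction(inputs.al_mm, inputs.k_d, c.SF, iol_power_d)
    if formula == "haigis":
        a0, a1, a2 = c.haigis_triple
        return haigis_refraction(
            inputs.al_mm, inputs.acd_mm, a0, a1, a2, iol_power_d,
            r_mm=inputs.r_mm, k_d=inputs.k_d, corneal_power_d=inputs.corneal_power_d,
        )
    if formula == "shammas_pl":
        return shammas_pl_refraction(inputs.al_mm, inputs.k_d, c.C, iol_power_d)
    raise DomainError(f"unknown formula {formula!r}")


REFRACTION_BRACKET_D = (-30.0, 30.0)


def predicted_refraction(
    formula: str,
    inputs: FormulaInputs,
    iol_power_d: float,
    solver: str = "closed",
) -> float:
    """Spectacle refraction REF with ``formula_power(..., target=REF) == iol_power_d``.

    ``solver='closed'`` uses the exact algebraic inverse; ``solver='bisect'``
    root-finds on the monotone power-vs-refraction map over [-30, +30] D.
    The two agree to better than 1e-8 D (asserted by the test suite).
    """
    if solver == "closed":
        return _closed_form_refraction(formula, inputs, iol_power_d)
    if solver != "bisect":
        raise DomainError(f"unknown solver {solver!r}")

    def f(ref: float) -> float:
        return formula_power(formula, inputs, ref) - iol_power_d

    lo, hi = REFRACTION_BRACKET_D
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:
        raise DomainError(
            f"no predicted refraction in [{lo}, {hi}] D for power {iol_power_d} D"
        )
    return brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
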