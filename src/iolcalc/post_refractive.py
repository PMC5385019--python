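"""No-history corneal-power corrections for eyes after myopic LASIK.

Myopic LASIK flattens the anterior cornea and breaks the fixed
anterior-to-posterior curvature ratio assumed by the 1.3375 keratometric
index, so the displayed K overestimates the true corneal power.  The three
corrections here map current measurements to a corrected corneal power (Kc)
without needing pre-LASIK data:

* Koch–Maloney:  Kc = 1.114 * K - 6.1   (a 1.3375-style power)
* Shammas c.d.:  Kc = 1.14  * K - 6.8   (a 1.3375-style power)
* Haigis-L:      a regression on the measured radius producing a corrected
  radius for the Haigis formula (nc = 1.3315); composing the corrected radius
  with the Haigis formula *is* the Haigis-L method.

All three are affine in the measurement, and over the post-myopic-LASIK range
(K < 46 D) each yields Kc below the measured K, i.e. they act in the
hyperopic-surprise-mitigating direction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biometry import k_to_radius
from .exceptions import DomainError

CORRECTIONS = ("none", "haigis_l", "koch_maloney", "shammas_cd")


def koch_maloney_k(k_d: float) -> float:
    """Koch–Maloney corrected corneal power, Kc = 1.114*K - 6.1 (D)."""
    if not (25.0 < k_d < 60.0):
        raise DomainError(f"measured K {k_d} D outside (25, 60)")
    return 1.114 * k_d - 6.1


def shammas_cd_k(k_d: float) -> float:
    """Shammas clinically-derived corrected corneal power, Kc = 1.14*K - 6.8 (D)."""
    if not (25.0 < k_d < 60.0):
        raise DomainError(f"measured K {k_d} D outside (25, 60)")
    return 1.14 * k_d - 6.8


def haigis_l_corrected_radius(r_meas_mm: float) -> float:
    """Haigis-L corrected corneal radius (mm) from the measured radius.

    r_corr = 331.5 / (-5.1625*r + 82.2603 - 0.35); feeding this radius to the
    Haigis formula (nc = 1.3315) constitutes the Haigis-L method.
    """
    if not (5.5 < r_meas_mm < 10.0):
        raise DomainError(f"measured radius {r_meas_mm} mm outside (5.5, 10)")
    denom = -5.1625 * r_meas_mm + 82.2603 - 0.35
    if denom <= 0:
        raise DomainError(f"Haigis-L regression non-positive at r = {r_meas_mm} mm")
    return 331.5 / denom


def haigis_l_corrected_power(r_meas_mm: float) -> float:
    """Corrected corneal power (D, nc = 1.3315 scale) implied by Haigis-L."""
    return 331.5 / haigis_l_corrected_radius(r_meas_mm)


@dataclass(frozen=True)
class CorrectionResult:
    """A corneal-power correction applied to one measurement."""

    method: str
    input_k_d: float | None = None
    input_r_mm: float | None = None
    corrected_k_d: float | None = None
    corrected_r_mm: float | None = None


def apply_correction(method: str, *, k_d: float | None = None, r_mm: float | None = None) -> CorrectionResult:
    """Apply a named correction to a measured K (D) or radius (mm).

    When Haigis-L receives only a K-reading, the radius is derived at the
    instrument display index 1.3375.
    """
    if method in ("koch_maloney", "shammas_cd"):
        if k_d is None:
            if r_mm is None:
                raise DomainError(f"correction {method!r} needs k_d or r_mm")
            k_d = 337.5 / r_mm
        fn = koch_maloney_k if method == "koch_maloney" else shammas_cd_k
        return CorrectionResult(method=method, input_k_d=k_d, input_r_mm=r_mm,
                                corrected_k_d=fn(k_d))
    if method == "haigis_l":
        if r_mm is None:
            if k_d is None:
                raise DomainError("correction 'haigis_l' needs r_mm or k_d")
            r_mm = k_to_radius(k_d)
        r_corr = haigis_l_corrected_radius(r_mm)
        return CorrectionResult(method=method, input_k_d=k_d, input_r_mm=r_mm,
                                corrected_r_mm=r_corr)
    if method == "none":
        return CorrectionResult(method="none", input_k_d=k_d, input_r_mm=r_mm,
                                corrected_k_d=k_d, corrected_r_mm=r_mm)
    raise DomainError(f"unknown correction {method!r}")
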