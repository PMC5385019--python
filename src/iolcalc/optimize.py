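"""Lens-constant optimization on virgin-eye cohorts.

The defining property of an optimized constant is a zero mean prediction
error on the optimization cohort.  Scalar constants (SRK/T A, Hoffer Q pACD,
Holladay 1 surgeon factor) are found by bracketed monotone root-finding on
the cohort mean error, which is strictly monotone in the constant because the
assumed lens position is.  The Haigis triple is found by the double-linear-
regression scheme: each eye's *effective* lens position is back-solved from
its implanted power and observed refraction, then ordinary least squares of
the effective ELP on (ACD, AL) with intercept yields (a0, a1, a2).  The
Shammas-PL C constant is converted from the optimized SRK/T A constant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

from .biometry import (
    EyeRecord,
    HAIGIS_CORNEAL_INDEX,
    IOLConstants,
    k_to_radius,
    spectacle_to_corneal_plane,
)
from .exceptions import (
    BackSolveError,
    CollinearityError,
    ConvergenceError,
    DomainError,
)
from .formulas import haigis_refraction
from .prediction import predict_eye_refraction

logger = logging.getLogger(__name__)

#: Physiologically plausible window for a pseudophakic lens plane (mm).
ELP_WINDOW_MM = (1.5, 9.0)

#: Root-search bracket half-width around the nominal constant.
BRACKET_HALFWIDTH = 5.0

NOMINAL_CONSTANTS = {"srkt": 118.5, "hofferq": 5.2, "holladay1": 1.5}

SCALAR_FIELD = {"srkt": "A", "hofferq": "pACD", "holladay1": "SF"}


def _check_cohort(cohort: list[EyeRecord]) -> None:
    if not cohort:
        raise DomainError("optimization cohort is empty")
    models = {e.iol_model for e in cohort}
    devices = {e.device for e in cohort}
    if len(models) > 1 or len(devices) > 1:
        raise DomainError(
            f"optimization cohort must be one IOL model on one device, got "
            f"models={sorted(models)} devices={sorted(devices)}"
        )


def cohort_mean_error(formula: str, cohort: list[EyeRecord], constant: float) -> float:
    """Mean (observed - predicted) refraction over the cohort at a trial constant."""
    base = cohort[0]
    const = IOLConstants(iol_model=base.iol_model, device=base.device,
                         **{SCALAR_FIELD[formula]: constant})
    total = 0.0
    for eye in cohort:
        total += eye.postop_se_d - predict_eye_refraction(eye, formula, const)
    return total / len(cohort)


def optimize_scalar_constant(
    formula: str,
    cohort: list[EyeRecord],
    nominal: float | None = None,
    bracket_halfwidth: float = BRACKET_HALFWIDTH,
) -> float:
    """Constant making the cohort mean prediction error zero (to < 1e-6 D).

    ``formula`` is one of srkt / hofferq / holladay1; ``nominal`` centres the
    search bracket (formula-typical default).
    """
    if formula not in SCALAR_FIELD:
        raise DomainError(f"no scalar constant for formula {formula!r}")
    _check_cohort(cohort)
    center = NOMINAL_CONSTANTS[formula] if nominal is None else nominal
    lo, hi = center - bracket_halfwidth, center + bracket_halfwidth
    f_lo = cohort_mean_error(formula, cohort, lo)
    f_hi = cohort_mean_error(formula, cohort, hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ConvergenceError(
            f"mean error does not change sign over [{lo}, {hi}] "
            f"(ME({lo}) = {f_lo:.4f} D, ME({hi}) = {f_hi:.4f} D)"
        )
    return brentq(lambda c: cohort_mean_error(formula, cohort, c), lo, hi,
                  xtol=1e-10, rtol=8.9e-16)


def back_solve_elp(eye: EyeRecord, corneal_power_d: float) -> float:
    """Effective lens position (mm) explaining an eye's observed outcome.

    Inverts the Haigis vergence expression for the lens plane ``d`` given the
    implanted power and the observed corneal-plane refraction: the quadratic
    ``d^2 - (AL+q)d + AL*q - (1336/P)(q - AL) = 0`` with ``q = 1336/z`` and
    ``z`` the corneal vergence.  Roots outside (1.5, 9) mm are rejected; when
    both roots qualify the smaller (physical) one is returned with a warning.
    """
    if abs(eye.iol_power_d) < 0.25:
        raise BackSolveError(
            f"eye {eye.eye_id!r}: implanted power {eye.iol_power_d} D too close "
            "to zero for ELP back-solving"
        )
    z = corneal_power_d + spectacle_to_corneal_plane(eye.postop_se_d)
    if z <= 0:
        raise BackSolveError(f"eye {eye.eye_id!r}: non-positive corneal vergence")
    q = 1336.0 / z
    al = eye.al_mm
    b = -(al + q)
    c = al * q - (1336.0 / eye.iol_power_d) * (q - al)
    disc = b * b - 4.0 * c
    if disc < 0:
        raise BackSolveError(
            f"eye {eye.eye_id!r}: negative discriminant, no real lens plane"
        )
    sq = math.sqrt(disc)
    roots = sorted(((-b - sq) / 2.0, (-b + sq) / 2.0))
    lo, hi = ELP_WINDOW_MM
    valid = [r for r in roots if lo < r < hi]
    if not valid:
        raise BackSolveError(
            f"eye {eye.eye_id!r}: no lens-plane root in ({lo}, {hi}) mm "
            f"(roots {roots[0]:.3f}, {roots[1]:.3f})"
        )
    if len(valid) == 2:
        warnings.warn(
            f"eye {eye.eye_id!r}: both ELP roots plausible; using the shallower",
            UserWarning,
            stacklevel=2,
        )
    return valid[0]


@dataclass
class HaigisFit:
    """Result of a Haigis double-linear-regression optimization."""

    a0: float
    a1: float
    a2: float
    n_used: int
    mean_error_d: float
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def triple(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)


def optimize_haigis_constants(
    cohort: list[EyeRecord],
    strategy: str = "elp",
    min_eyes: int = 4,
    condition_limit: float = 1e8,
) -> HaigisFit:
    """Optimize (a0, a1, a2) on a virgin cohort.

    ``strategy='elp'`` (default) back-solves each eye's effective lens
    position, then regresses it on (ACD, AL) with intercept — the canonical
    reading of the double linear regression.  ``strategy='refraction'``
    minimizes refraction-scale residuals directly by nonlinear least squares.
    Eyes whose outcome admits no plausible lens plane are excluded (with a
    logged reason) rather than failing the fit.
    """
    _check_cohort(cohort)
    used: list[EyeRecord] = []
    d_eff: list[float] = []
    excluded: list[tuple[str, str]] = []
    for eye in cohort:
        dc = (HAIGIS_CORNEAL_INDEX - 1.0) * 1000.0 / k_to_radius(eye.k_d)
        try:
            d_eff.append(back_solve_elp(eye, dc))
        except BackSolveError as err:
            excluded.append((eye.eye_id, str(err)))
            logger.warning("excluding eye from Haigis optimization: %s", err)
            continue
        used.append(eye)
    if len(used) < min_eyes:
        raise DomainError(
            f"only {len(used)} eyes survive ELP back-solving; need >= {min_eyes}"
        )

    acd = np.array([e.acd_mm for e in used])
    al = np.array([e.al_mm for e in used])
    design = np.column_stack([np.ones(len(used)), acd, al])
    if np.linalg.cond(design) > condition_limit:
        raise CollinearityError(
            "ACD and AL are (numerically) collinear in this cohort; "
            "consider a scalar-constant formula instead"
        )
    coef, *_ = np.linalg.lstsq(design, np.array(d_eff), rcond=None)
    a0, a1, a2 = (float(v) for v in coef)

    if strategy == "refraction":
        def residuals(params):
            p0, p1, p2 = params
            out = np.empty(len(used))
            for i, eye in enumerate(used):
                out[i] = eye.postop_se_d - haigis_refraction(
                    eye.al_mm, eye.acd_mm, p0, p1, p2, eye.iol_power_d,
                    r_mm=k_to_radius(eye.k_d),
                )
            return out

        sol = least_squares(residuals, x0=(a0, a1, a2), method="lm")
        if not sol.success:
            raise ConvergenceError(f"refraction-scale Haigis fit failed: {sol.message}")
        a0, a1, a2 = (float(v) for v in sol.x)
    elif strategy != "elp":
        raise DomainError(f"unknown Haigis optimization strategy {strategy!r}")

    base = used[0]
    const = IOLConstants(iol_model=base.iol_model, device=base.device,
                         a0=a0, a1=a1, a2=a2)
    me = float(np.mean([
        e.postop_se_d - predict_eye_refraction(e, "haigis", const) for e in used
    ]))
    if abs(me) > 0.05:
        warnings.warn(
            f"Haigis fit leaves a residual mean error of {me:.3f} D "
            "(ELP-scale regression only approximately zeroes it at the "
            "refraction scale)",
            UserWarning,
            stacklevel=2,
        )
    return HaigisFit(a0=a0, a1=a1, a2=a2, n_used=len(used), mean_error_d=me,
                     excluded=excluded)


def a_to_shammas_c(a_const: float) -> float:
    """Shammas-PL C constant from an SRK/T A constant: C = 0.5835*A - 64.40 (mm)."""
    if not (110.0 < a_const < 125.0):
        raise DomainError(f"A constant {a_const} outside (110, 125)")
    return 0.5835 * a_const - 64.40


def optimize_constants(
    cohort: list[EyeRecord],
    nominal_a: float | None = None,
    haigis_strategy: str = "elp",
) -> IOLConstants:
    """Full constant set (A, pACD, SF, Haigis triple, C) for one model x device."""
    _check_cohort(cohort)
    base = cohort[0]
    a = optimize_scalar_constant("srkt", cohort, nominal=nominal_a)
    pacd = optimize_scalar_constant("hofferq", cohort)
    sf = optimize_scalar_constant("holladay1", cohort)
    fit = optimize_haigis_constants(cohort, strategy=haigis_strategy)
    return IOLConstants(
        iol_model=base.iol_model, device=base.device,
        A=a, pACD=pacd, SF=sf, a0=fit.a0, a1=fit.a1, a2=fit.a2,
        C=a_to_shammas_c(a),
    )


def optimize_constants_table(
    cohort: list[EyeRecord],
    haigis_strategy: str = "elp",
) -> list[IOLConstants]:
    """Optimize constants for every (iol_model, device) group in a virgin cohort."""
    groups: dict[tuple[str, str], list[EyeRecord]] = {}
    for eye in cohort:
        groups.setdefault((eye.iol_model, eye.device), []).append(eye)
    return [
        optimize_constants(eyes, haigis_strategy=haigis_strategy)
        for _, eyes in sorted(groups.items())
    ]
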