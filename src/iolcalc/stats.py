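"""Prediction-error statistics: the per-method summary battery, SD comparison
F tests, and box-plot summaries.

The prediction error of an eye is the observed stable postoperative spherical
equivalent minus the method's predicted spherical equivalent, so a positive
error is a hyperopic shift.  The summary row per method reports n, mean error
(ME), sample SD, range, mean absolute error (MAE), median absolute error
(MedAE), a 95% confidence interval for the MAE, and the percentage of eyes
within +/-0.5, 1.0 and 1.5 D of prediction (inclusive thresholds).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .biometry import EyeRecord, IOLConstants
from .exceptions import DomainError, IolcalcError
from .prediction import MethodSpec, get_method, predict_eye_refraction

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS_D = (0.5, 1.0, 1.5)


@dataclass
class ErrorSummary:
    """One summary row of prediction-error statistics (all diopters)."""

    n: int
    me_d: float
    sd_d: float | None
    range_d: tuple[float, float]
    mae_d: float
    medae_d: float
    ci95_mae_d: tuple[float, float] | None
    pct_within: dict[float, float]


def summarize_errors(
    errors: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS_D,
    ci_method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> ErrorSummary:
    """Compute the full statistics battery for a vector of prediction errors.

    SD uses the n-1 denominator; MedAE interpolates the two central order
    statistics at even n; the MAE confidence interval is t-based on the
    absolute errors (floored at zero), or percentile-bootstrap with
    ``ci_method='bootstrap'`` (seeded).  n = 1 yields point statistics with
    SD and CI absent.
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise DomainError("cannot summarize an empty error vector")
    n = int(e.size)
    abs_e = np.abs(e)
    mae = float(abs_e.mean())

    if n >= 2:
        sd = float(e.std(ddof=1))
        if ci_method == "t":
            hw = float(sps.t.ppf(0.975, n - 1) * abs_e.std(ddof=1) / np.sqrt(n))
            ci = (max(0.0, mae - hw), mae + hw)
        elif ci_method == "bootstrap":
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, n, size=(n_boot, n))
            boot = abs_e[idx].mean(axis=1)
            ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
        else:
            raise DomainError(f"unknown CI method {ci_method!r}")
    else:
        sd, ci = None, None

    pct = {
        float(th): float(100.0 * np.mean(abs_e <= th)) for th in thresholds
    }
    return ErrorSummary(
        n=n,
        me_d=float(e.mean()),
        sd_d=sd,
        range_d=(float(e.min()), float(e.max())),
        mae_d=mae,
        medae_d=float(np.median(abs_e)),
        ci95_mae_d=ci,
        pct_within=pct,
    )


@dataclass
class FTestResult:
    """Two-sided variance-ratio test between two error vectors."""

    f: float
    df1: int
    df2: int
    p: float

    @property
    def significant(self) -> bool:
        """Significance at the 0.05 level."""
        return self.p < 0.05


def compare_sd_f_test(errors_a: Sequence[float], errors_b: Sequence[float]) -> FTestResult:
    """F test of equal variances: F = s_a^2 / s_b^2 with a two-sided p-value.

    ``p = 2 * min(P(F <= f), P(F >= f))``, capped at 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError("each sample needs n >= 2 for a variance test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        raise DomainError("zero variance in the denominator sample")
    f = float(va / vb)
    df1, df2 = a.size - 1, b.size - 1
    cdf = sps.f.cdf(f, df1, df2)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return FTestResult(f=f, df1=int(df1), df2=int(df2), p=p)


@dataclass
class BoxplotSummary:
    """Five-number box-plot summary with 1.5*IQR whiskers."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)


def boxplot_summary(errors: Sequence[float]) -> BoxplotSummary:
    """Box-plot summary: linear-interpolation quartiles, whiskers at the most
    extreme observations within 1.5*IQR of the quartiles, the rest outliers."""
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise DomainError("cannot summarize an empty error vector")
    q1, med, q3 = (float(v) for v in np.quantile(e, [0.25, 0.5, 0.75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = e[(e >= lo_fence) & (e <= hi_fence)]
    outliers = sorted(float(v) for v in e[(e < lo_fence) | (e > hi_fence)])
    return BoxplotSummary(
        median=med, q1=q1, q3=q3,
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=outliers,
    )


@dataclass
class PredictionErrorResult:
    """Per-eye prediction errors for one method, with flagged exclusions."""

    method: str
    eye_ids: list[str]
    errors: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)


def prediction_errors(
    cohort: Sequence[EyeRecord],
    method: MethodSpec | str,
    constants: IOLConstants | list | dict,
) -> PredictionErrorResult:
    """Observed-minus-predicted SE per eye, in cohort order.

    Eyes for which the formula fails (degenerate geometry, missing constants)
    are excluded with a logged reason instead of aborting the batch.
    """
    method = get_method(method)
    eye_ids: list[str] = []
    errs: list[float] = []
    excluded: list[tuple[str, str]] = []
    for eye in cohort:
        try:
            pred = predict_eye_refraction(eye, method, constants)
        except IolcalcError as err:
            excluded.append((eye.eye_id, str(err)))
            logger.warning("excluding eye %s from method %s: %s",
                           eye.eye_id, method.name, err)
            continue
        eye_ids.append(eye.eye_id)
        errs.append(eye.postop_se_d - pred)
    return PredictionErrorResult(
        method=method.name, eye_ids=eye_ids,
        errors=np.asarray(errs, dtype=float), excluded=excluded,
    )
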