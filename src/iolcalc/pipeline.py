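"""End-to-end study workflow: optimize constants on virgin eyes, predict and
evaluate the no-history methods on post-LASIK eyes, write report tables."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .biometry import (
    EyeRecord,
    IOLConstants,
    read_cohort,
    write_cohort,
    write_constants,
)
from .exceptions import DomainError, IolcalcError
from .optimize import optimize_constants_table
from .prediction import STUDY_METHODS, VIRGIN_METHODS, get_method
from .simulate import make_study_fixture
from .stats import boxplot_summary, compare_sd_f_test, prediction_errors, summarize_errors

logger = logging.getLogger(__name__)

DEFAULT_METHODS = list(STUDY_METHODS)

SUMMARY_COLUMNS = [
    "method", "device", "status", "n", "me", "sd", "range_lo", "range_hi",
    "mae", "medae", "ci_lo", "ci_hi", "within_05", "within_10", "within_15",
]


@dataclass
class StudyReport:
    """Artifacts and diagnostics of one study run."""

    out_dir: Path
    paths: dict[str, Path]
    constants: list[IOLConstants]
    n_warnings: int = 0
    excluded: list[tuple[str, str, str]] = field(default_factory=list)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return json.load(fh)
    return dict(config)


def _summary_row(name: str, device: str, status: str, summary) -> dict:
    return {
        "method": name, "device": device, "status": status, "n": summary.n,
        "me": summary.me_d, "sd": summary.sd_d,
        "range_lo": summary.range_d[0], "range_hi": summary.range_d[1],
        "mae": summary.mae_d, "medae": summary.medae_d,
        "ci_lo": None if summary.ci95_mae_d is None else summary.ci95_mae_d[0],
        "ci_hi": None if summary.ci95_mae_d is None else summary.ci95_mae_d[1],
        "within_05": summary.pct_within[0.5],
        "within_10": summary.pct_within[1.0],
        "within_15": summary.pct_within[1.5],
    }


def run_study(config, out_dir: str | Path | None = None) -> StudyReport:
    """Execute optimize -> predict -> evaluate and write the report tables.

    ``config`` is a JSON file path or dict with keys:

    - ``seed`` (int): drives simulation when no cohort files are given.
    - ``out_dir`` (str): output directory (overridable by the argument).
    - ``virgin_csv`` / ``post_lasik_csv`` (optional): either a single path or
      a ``{device: path}`` mapping; when absent a study-shaped synthetic
      fixture is generated and written alongside the reports.
    - ``methods`` (optional): post-LASIK method names (default: all four).
    - ``virgin_reference_formula`` (optional, default "haigis"): the virgin
      arm method whose errors anchor the SD comparisons.
    """
    cfg = _load_config(config)
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "study_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    method_names = cfg.get("methods", DEFAULT_METHODS)
    ref_formula = cfg.get("virgin_reference_formula", "haigis")
    if ref_formula not in VIRGIN_METHODS:
        raise DomainError(f"unknown virgin reference formula {ref_formula!r}")

    n_warnings = 0
    excluded: list[tuple[str, str, str]] = []
    paths: dict[str, Path] = {}

    def _read_arms(entry, label) -> dict[str, list[EyeRecord]]:
        if isinstance(entry, str):
            records = read_cohort(entry)
            arms: dict[str, list[EyeRecord]] = {}
            for r in records:
                arms.setdefault(r.device, []).append(r)
            return arms
        return {device: read_cohort(path) for device, path in entry.items()}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if cfg.get("virgin_csv") and cfg.get("post_lasik_csv"):
            virgin = _read_arms(cfg["virgin_csv"], "virgin")
            post = _read_arms(cfg["post_lasik_csv"], "post_lasik")
            constants = []
            for device, eyes in sorted(virgin.items()):
                constants.extend(optimize_constants_table(eyes))
        else:
            logger.info("no cohort files configured; simulating a study fixture (seed=%d)", seed)
            fixture = make_study_fixture(seed=seed)
            virgin, post, constants = fixture.virgin, fixture.post_lasik, fixture.constants
            cohort_dir = out / "cohorts"
            cohort_dir.mkdir(exist_ok=True)
            for label, arms in (("virgin", virgin), ("post_lasik", post)):
                for device, recs in arms.items():
                    p = cohort_dir / f"{label}_{device}.csv"
                    write_cohort(recs, p)
                    paths[f"cohort_{label}_{device}"] = p

        paths["constants"] = out / "constants.csv"
        write_constants(constants, paths["constants"])

        error_rows: list[dict] = []
        summary_rows: list[dict] = []
        box_rows: list[dict] = []
        ftest_rows: list[dict] = []
        virgin_ref_errors: dict[str, object] = {}

        for device, eyes in sorted(virgin.items()):
            res = prediction_errors(eyes, ref_formula, constants)
            excluded += [(e, r, f"virgin/{device}/{ref_formula}") for e, r in res.excluded]
            virgin_ref_errors[device] = res.errors
            summary_rows.append(_summary_row(ref_formula, device, "virgin",
                                             summarize_errors(res.errors)))
            for eye_id, err in zip(res.eye_ids, res.errors):
                error_rows.append({"eye_id": eye_id, "device": device,
                                   "status": "virgin", "method": ref_formula,
                                   "error_d": err})

        for device, eyes in sorted(post.items()):
            for name in method_names:
                method = get_method(name)
                res = prediction_errors(eyes, method, constants)
                excluded += [(e, r, f"post_lasik/{device}/{name}") for e, r in res.excluded]
                if res.errors.size == 0:
                    raise DomainError(f"method {name!r} excluded every eye on {device}")
                summary_rows.append(_summary_row(name, device, "post_lasik",
                                                 summarize_errors(res.errors)))
                for eye_id, err in zip(res.eye_ids, res.errors):
                    error_rows.append({"eye_id": eye_id, "device": device,
                                       "status": "post_lasik", "method": name,
                                       "error_d": err})
                box = boxplot_summary(res.errors)
                box_rows.append({
                    "method": name, "device": device,
                    "median": box.median, "q1": box.q1, "q3": box.q3,
                    "whisker_low": box.whisker_low, "whisker_high": box.whisker_high,
                    "n_outliers": len(box.outliers),
                })
                if res.errors.size >= 2 and device in virgin_ref_errors:
                    ft = compare_sd_f_test(res.errors, virgin_ref_errors[device])
                    ftest_rows.append({
                        "method": name, "device": device,
                        "vs": f"virgin {ref_formula}",
                        "f": ft.f, "df1": ft.df1, "df2": ft.df2, "p": ft.p,
                        "significant_05": ft.p < 0.05,
                    })

        n_warnings = len(caught)
        for w in caught:
            logger.warning("%s", w.message)

    paths["errors"] = out / "errors.csv"
    pd.DataFrame(error_rows).to_csv(paths["errors"], index=False)
    paths["summary"] = out / "summary.csv"
    pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS).to_csv(paths["summary"], index=False)
    paths["boxplot"] = out / "boxplot.csv"
    pd.DataFrame(box_rows).to_csv(paths["boxplot"], index=False)
    paths["f_tests"] = out / "f_tests.csv"
    pd.DataFrame(ftest_rows).to_csv(paths["f_tests"], index=False)

    logger.info("study complete: %d warnings, %d excluded eye-method pairs",
                n_warnings, len(excluded))
    return StudyReport(out_dir=out, paths=paths, constants=constants,
                       n_warnings=n_warnings, excluded=excluded)
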