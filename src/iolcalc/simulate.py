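"""Synthetic ocular-biometry cohorts for virgin and post-LASIK eyes.

The generator draws axial length and anterior chamber depth from a bivariate
normal (longer eyes have deeper chambers), keratometry from an independent
normal, all truncated to physiological ranges by resampling, and then plays
the study forward: the implanted power is the truth formula's power for the
surgical target (rounded to commercially available steps), and the observed
stable refraction is the truth model's prediction for that power plus
measurement noise.

Post-LASIK eyes encode the central premise of no-history corneal-power
correction: the *recorded* keratometry is the (overestimating) display
reading, while the truth model runs on a corrected corneal power
(by default the Shammas clinically-derived map of the measured K, plus noise).

Ultrasound-arm records carry an axial length shorter than the true optical
length (applanation contact compresses/intercepts differently than partial
coherence interferometry) with extra measurement noise; the eye's true
anatomy — and hence its outcome — is unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .biometry import (
    ACD_RANGE_MM,
    AL_RANGE_MM,
    EyeRecord,
    IOLConstants,
    IOL_POWER_RANGE_D,
    K_RANGE_D,
    POSTOP_SE_RANGE_D,
    k_to_radius,
)
from .exceptions import DegenerateGeometryError, DomainError
from .formulas import FormulaInputs, formula_power, predicted_refraction
from .optimize import optimize_constants
from .post_refractive import koch_maloney_k, shammas_cd_k
from .prediction import STUDY_METHODS  # noqa: F401  (re-exported convenience)

# Cohort marginals emulating the study populations (mean, SD).
VIRGIN_PROFILE = {"al": (24.42, 2.40), "k": (43.93, 1.72), "acd": (3.16, 0.44)}
POST_LASIK_PROFILE = {"al": (30.06, 2.87), "k": (36.35, 0.77), "acd": (3.34, 0.41)}

#: Default truth constants: a typical one-piece acrylic IOL.
DEFAULT_TRUTH_CONSTANTS = IOLConstants(
    iol_model="920H", device="pci",
    A=118.4, pACD=5.04, SF=1.45,
    a0=0.154, a1=0.166, a2=0.166,
    C=4.6866,
)

_KC_TRUTH_MAPS = {"shammas_cd": shammas_cd_k, "koch_maloney": koch_maloney_k}


@dataclass
class CohortConfig:
    """Distribution parameters, truth model, noise, and seed for one cohort."""

    n: int
    status: str = "virgin"
    device: str = "pci"
    seed: int = 0
    iol_model: str = "920H"
    al_mean: float = 24.42
    al_sd: float = 2.40
    k_mean: float = 43.93
    k_sd: float = 1.72
    acd_mean: float = 3.16
    acd_sd: float = 0.44
    rho_al_acd: float = 0.4
    truth_formula: str = "haigis"
    truth_constants: IOLConstants = field(default_factory=lambda: DEFAULT_TRUTH_CONSTANTS)
    target_ref_d: float = -0.25
    noise_sd_d: float = 0.3
    iol_step_d: float = 0.5
    device_al_offset_mm: float = 0.15
    device_al_extra_sd_mm: float = 0.08
    kc_truth_map: str = "shammas_cd"
    kc_truth_sd_d: float = 0.25

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError(f"cohort size must be >= 1, got {self.n}")
        if min(self.al_sd, self.k_sd, self.acd_sd, self.noise_sd_d,
               self.device_al_extra_sd_mm, self.kc_truth_sd_d) < 0:
            raise DomainError("standard deviations must be non-negative")
        if not abs(self.rho_al_acd) < 1:
            raise DomainError(f"|rho_al_acd| must be < 1, got {self.rho_al_acd}")
        if self.iol_step_d not in (0.25, 0.5):
            raise DomainError(f"iol_step_d must be 0.25 or 0.5, got {self.iol_step_d}")
        if self.status not in ("virgin", "post_lasik"):
            raise DomainError(f"unknown status {self.status!r}")
        if self.kc_truth_map not in _KC_TRUTH_MAPS:
            raise DomainError(f"unknown corneal-power truth map {self.kc_truth_map!r}")


def virgin_config(n: int, seed: int = 0, **overrides) -> CohortConfig:
    """Config with the virgin-population marginals."""
    (al_m, al_s), (k_m, k_s), (acd_m, acd_s) = (
        VIRGIN_PROFILE["al"], VIRGIN_PROFILE["k"], VIRGIN_PROFILE["acd"]
    )
    base = dict(n=n, status="virgin", seed=seed, al_mean=al_m, al_sd=al_s,
                k_mean=k_m, k_sd=k_s, acd_mean=acd_m, acd_sd=acd_s)
    base.update(overrides)
    return CohortConfig(**base)


def post_lasik_config(n: int, seed: int = 0, **overrides) -> CohortConfig:
    """Config with the post-myopic-LASIK marginals (long eyes, flat corneas)."""
    (al_m, al_s), (k_m, k_s), (acd_m, acd_s) = (
        POST_LASIK_PROFILE["al"], POST_LASIK_PROFILE["k"], POST_LASIK_PROFILE["acd"]
    )
    base = dict(n=n, status="post_lasik", seed=seed, al_mean=al_m, al_sd=al_s,
                k_mean=k_m, k_sd=k_s, acd_mean=acd_m, acd_sd=acd_s)
    base.update(overrides)
    return CohortConfig(**base)


# ---------------------------------------------------------------------------
# Truth model
# ---------------------------------------------------------------------------

@dataclass
class _TrueEye:
    """Latent anatomy and outcome of one synthetic eye."""

    al_mm: float          # true optical axial length
    acd_mm: float
    k_meas_d: float       # displayed keratometry
    kc_true_d: float      # corneal power the truth model runs on
    iol_power_d: float = math.nan
    postop_se_d: float = math.nan


_MAX_RESAMPLES = 1000


def _sample_true_eye(cfg: CohortConfig, rng: np.random.Generator) -> _TrueEye:
    rho = cfg.rho_al_acd
    for _ in range(_MAX_RESAMPLES):
        z0, z1 = rng.standard_normal(2)
        al = cfg.al_mean + cfg.al_sd * z0
        acd = cfg.acd_mean + cfg.acd_sd * (rho * z0 + math.sqrt(1 - rho * rho) * z1)
        if AL_RANGE_MM[0] < al < AL_RANGE_MM[1] and ACD_RANGE_MM[0] < acd < ACD_RANGE_MM[1]:
            break
    else:
        raise DomainError("AL/ACD sampling failed truncation after 1000 resamples")
    for _ in range(_MAX_RESAMPLES):
        k = cfg.k_mean + cfg.k_sd * rng.standard_normal()
        if K_RANGE_D[0] < k < K_RANGE_D[1]:
            break
    else:
        raise DomainError("keratometry sampling failed truncation after 1000 resamples")

    if cfg.status == "post_lasik":
        kc = _KC_TRUTH_MAPS[cfg.kc_truth_map](k) + cfg.kc_truth_sd_d * rng.standard_normal()
    else:
        kc = k
    return _TrueEye(al_mm=al, acd_mm=acd, k_meas_d=k, kc_true_d=kc)


def _truth_inputs(cfg: CohortConfig, eye: _TrueEye) -> FormulaInputs:
    inputs = FormulaInputs(al_mm=eye.al_mm, acd_mm=eye.acd_mm,
                           constants=cfg.truth_constants)
    if cfg.status == "post_lasik":
        # Corrected-style corneal power, typed directly for the Haigis family.
        if cfg.truth_formula == "haigis":
            inputs.corneal_power_d = eye.kc_true_d
        else:
            inputs.k_d = eye.kc_true_d
    else:
        inputs.k_d = eye.k_meas_d
        if cfg.truth_formula == "haigis":
            inputs.r_mm = k_to_radius(eye.k_meas_d)
    return inputs


def _realize_outcome(cfg: CohortConfig, eye: _TrueEye, rng: np.random.Generator) -> None:
    """Choose the implanted power for the surgical target and play out the refraction."""
    inputs = _truth_inputs(cfg, eye)
    exact = formula_power(cfg.truth_formula, inputs, cfg.target_ref_d)
    step = cfg.iol_step_d
    power = round(exact / step) * step
    power = min(max(power, IOL_POWER_RANGE_D[0]), IOL_POWER_RANGE_D[1])
    eye.iol_power_d = power
    base = predicted_refraction(cfg.truth_formula, inputs, power)
    for _ in range(_MAX_RESAMPLES):
        se = base + cfg.noise_sd_d * rng.standard_normal()
        if POSTOP_SE_RANGE_D[0] < se < POSTOP_SE_RANGE_D[1]:
            eye.postop_se_d = se
            return
    raise DomainError("refraction noise sampling failed truncation after 1000 resamples")


def _sample_realized_eye(cfg: CohortConfig, rng: np.random.Generator) -> _TrueEye:
    """A true eye together with its surgical outcome.

    Eyes whose required implant power is clipped so hard that no refraction in
    the supported range can result (or whose geometry degenerates in the truth
    formula) are ineligible — the clinical analogue of failing study screening
    — and a fresh eye is drawn.
    """
    for _ in range(_MAX_RESAMPLES):
        eye = _sample_true_eye(cfg, rng)
        try:
            _realize_outcome(cfg, eye, rng)
        except (DomainError, DegenerateGeometryError):
            continue
        return eye
    raise DomainError("no eligible eye after 1000 resamples")


def _record(cfg: CohortConfig, eye: _TrueEye, eye_id: str, device: str,
            rng: np.random.Generator) -> EyeRecord:
    """Materialize the device's measurement of a true eye as a cohort record."""
    if device == "us_topo":
        al_rec = eye.al_mm - cfg.device_al_offset_mm
        if cfg.device_al_extra_sd_mm > 0:
            al_rec += cfg.device_al_extra_sd_mm * rng.standard_normal()
        al_rec = min(max(al_rec, AL_RANGE_MM[0] + 1e-6), AL_RANGE_MM[1] - 1e-6)
    else:
        al_rec = eye.al_mm
    return EyeRecord(
        eye_id=eye_id, status=cfg.status, device=device,
        al_mm=al_rec, k_d=eye.k_meas_d, acd_mm=eye.acd_mm,
        iol_model=cfg.iol_model, iol_power_d=eye.iol_power_d,
        postop_se_d=eye.postop_se_d,
    )


def generate_cohort(config: CohortConfig) -> list[EyeRecord]:
    """Generate one cohort; deterministic for a given config (seed included)."""
    rng = np.random.default_rng(config.seed)
    records = []
    prefix = "v" if config.status == "virgin" else "p"
    for i in range(config.n):
        eye = _sample_realized_eye(config, rng)
        records.append(_record(config, eye, f"{prefix}{i:04d}", config.device, rng))
    return records


def generate_paired_cohort(config: CohortConfig) -> tuple[list[EyeRecord], list[EyeRecord]]:
    """Generate one set of true eyes measured by both devices.

    The implanted power and observed refraction are facts about the eye and
    are shared; only the recorded axial length differs between the arms.
    """
    rng = np.random.default_rng(config.seed)
    prefix = "v" if config.status == "virgin" else "p"
    pci, us = [], []
    for i in range(config.n):
        eye = _sample_realized_eye(config, rng)
        eye_id = f"{config.iol_model}_{prefix}{i:04d}"
        pci.append(_record(config, eye, eye_id, "pci", rng))
        us.append(_record(config, eye, eye_id, "us_topo", rng))
    return pci, us


# ---------------------------------------------------------------------------
# The full study-shaped fixture
# ---------------------------------------------------------------------------

#: (model, virgin n, post-LASIK n, Haigis triple, nominal A) — counts mirror
#: the study's IOL-model distribution; triples are published per-model fits.
STUDY_MODELS = [
    ("920H", 36, 4, (0.154, 0.166, 0.166), 118.3),
    ("Adapt-AO", 33, 2, (-1.418, 0.629, 0.176), 118.1),
    ("SN60WF", 33, 1, (1.948, 0.376, 0.076), 118.7),
    ("ZCB00", 31, 3, (-3.031, 0.331, 0.309), 119.3),
]


@dataclass
class StudyFixture:
    """A complete synthetic study: both cohorts on both device arms, plus
    per-model, per-device optimized constants."""

    virgin: dict[str, list[EyeRecord]]
    post_lasik: dict[str, list[EyeRecord]]
    constants: list[IOLConstants]


def make_study_fixture(seed: int = 0, optimize: bool = True) -> StudyFixture:
    """Emit a study-shaped worked example: 133 virgin and 10 post-LASIK eyes,
    four IOL models distributed 36/33/33/31 and 4/2/1/3, measured on both
    device arms, with constants optimized per IOL model and device."""
    virgin = {"pci": [], "us_topo": []}
    post = {"pci": [], "us_topo": []}
    for idx, (model, n_v, n_p, triple, a_nom) in enumerate(STUDY_MODELS):
        truth = IOLConstants(iol_model=model, device="pci",
                             A=a_nom, a0=triple[0], a1=triple[1], a2=triple[2])
        v_cfg = virgin_config(n_v, seed=seed * 101 + idx, iol_model=model,
                              truth_constants=truth)
        p_cfg = post_lasik_config(n_p, seed=seed * 101 + 50 + idx, iol_model=model,
                                  truth_constants=truth)
        v_pci, v_us = generate_paired_cohort(v_cfg)
        p_pci, p_us = generate_paired_cohort(p_cfg)
        virgin["pci"] += v_pci
        virgin["us_topo"] += v_us
        post["pci"] += p_pci
        post["us_topo"] += p_us

    constants: list[IOLConstants] = []
    if optimize:
        for device in ("pci", "us_topo"):
            groups: dict[str, list[EyeRecord]] = {}
            for eye in virgin[device]:
                groups.setdefault(eye.iol_model, []).append(eye)
            for model, _, _, _, a_nom in STUDY_MODELS:
                constants.append(optimize_constants(groups[model], nominal_a=a_nom))
    return StudyFixture(virgin=virgin, post_lasik=post, constants=constants)


def with_device_offset(records: list[EyeRecord], offset_mm: float) -> list[EyeRecord]:
    """Re-record a cohort with the axial length shifted by -offset_mm.

    Models re-measuring PCI eyes with applanation ultrasound (deterministic
    component only); the eyes' outcomes are untouched.
    """
    out = []
    for eye in records:
        out.append(replace(eye, al_mm=eye.al_mm - offset_mm, device="us_topo"))
    return out
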