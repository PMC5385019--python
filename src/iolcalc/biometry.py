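"""Domain types, unit/plane conversions, and CSV cohort I/O.

Keratometry is stored as the displayed K-reading at the instrument convention
(keratometric index 1.3375); corneal radii are derived on demand.  Anterior
chamber depth is the epithelium-to-lens distance as instruments report it.
Refractions are spectacle-plane spherical equivalents unless stated; the
vertex distance is fixed at 12 mm, the convention embedded in the classic
vergence formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import DomainError, FormatError, ValidationError

#: Keratometric index used by both devices to display K from the anterior radius.
KERATOMETRIC_INDEX = 1.3375
#: Fictitious corneal index of the Haigis formula family.
HAIGIS_CORNEAL_INDEX = 1.3315
#: Refractive index of aqueous/vitreous used in the vergence formulas.
AQUEOUS_INDEX = 1.336
#: Back vertex distance, mm (spectacle plane to cornea).
VERTEX_MM = 12.0

STATUSES = ("virgin", "post_lasik")
DEVICES = ("pci", "us_topo")

AL_RANGE_MM = (15.0, 40.0)
K_RANGE_D = (25.0, 60.0)
ACD_RANGE_MM = (1.5, 5.0)
IOL_POWER_RANGE_D = (-10.0, 40.0)
POSTOP_SE_RANGE_D = (-15.0, 10.0)

COHORT_COLUMNS = [
    "eye_id",
    "status",
    "device",
    "al_mm",
    "k_d",
    "acd_mm",
    "iol_model",
    "iol_power_d",
    "postop_se_d",
]


# ---------------------------------------------------------------------------
# Unit and plane conversions
# ---------------------------------------------------------------------------

def k_to_radius(k_d: float, nk: float = KERATOMETRIC_INDEX) -> float:
    """Convert a displayed keratometry reading (D) to the anterior corneal radius (mm).

    ``r = (nk - 1) * 1000 / K`` — e.g. K = 45 D at the 1.3375 convention
    corresponds to r = 7.5 mm.
    """
    if k_d <= 0:
        raise DomainError(f"keratometry must be positive, got {k_d}")
    if nk <= 1:
        raise DomainError(f"keratometric index must exceed 1, got {nk}")
    return (nk - 1.0) * 1000.0 / k_d


def radius_to_k(r_mm: float, nk: float = KERATOMETRIC_INDEX) -> float:
    """Convert an anterior corneal radius (mm) to the displayed power (D)."""
    if r_mm <= 0:
        raise DomainError(f"corneal radius must be positive, got {r_mm}")
    if nk <= 1:
        raise DomainError(f"keratometric index must exceed 1, got {nk}")
    return (nk - 1.0) * 1000.0 / r_mm


def spectacle_to_corneal_plane(ref_d: float, vertex_mm: float = VERTEX_MM) -> float:
    """Transpose a spectacle-plane refraction to the corneal plane.

    Standard vertex transposition ``Rc = Rs / (1 - v * Rs)`` with the vertex
    distance ``v`` in metres.
    """
    denom = 1.0 - (vertex_mm / 1000.0) * ref_d
    if abs(denom) < 1e-12:
        raise DomainError(f"vertex transposition singular at {ref_d} D")
    return ref_d / denom


def corneal_to_spectacle_plane(ref_d: float, vertex_mm: float = VERTEX_MM) -> float:
    """Inverse of :func:`spectacle_to_corneal_plane`."""
    denom = 1.0 + (vertex_mm / 1000.0) * ref_d
    if abs(denom) < 1e-12:
        raise DomainError(f"vertex transposition singular at {ref_d} D")
    return ref_d / denom


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

def _check_open_range(eye_id: str, field: str, value: float, lo: float, hi: float) -> None:
    if not (lo < value < hi):
        raise ValidationError(
            f"eye {eye_id!r}: {field}={value} outside ({lo}, {hi})"
        )


@dataclass(frozen=True)
class EyeRecord:
    """One eye's biometry, implanted lens, and observed refractive outcome.

    ``postop_se_d`` is the stable postoperative manifest spherical equivalent
    at the spectacle plane; ``k_d`` is the displayed mean keratometry at the
    1.3375 convention; ``acd_mm`` is measured epithelium-to-lens.
    """

    eye_id: str
    status: str
    device: str
    al_mm: float
    k_d: float
    acd_mm: float
    iol_model: str
    iol_power_d: float
    postop_se_d: float

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(
                f"eye {self.eye_id!r}: status={self.status!r} not in {STATUSES}"
            )
        if self.device not in DEVICES:
            raise ValidationError(
                f"eye {self.eye_id!r}: device={self.device!r} not in {DEVICES}"
            )
        _check_open_range(self.eye_id, "al_mm", self.al_mm, *AL_RANGE_MM)
        _check_open_range(self.eye_id, "k_d", self.k_d, *K_RANGE_D)
        _check_open_range(self.eye_id, "acd_mm", self.acd_mm, *ACD_RANGE_MM)
        lo, hi = IOL_POWER_RANGE_D
        if not (lo <= self.iol_power_d <= hi):
            raise ValidationError(
                f"eye {self.eye_id!r}: iol_power_d={self.iol_power_d} outside [{lo}, {hi}]"
            )
        steps = self.iol_power_d / 0.25
        if abs(steps - round(steps)) > 1e-6:
            raise ValidationError(
                f"eye {self.eye_id!r}: iol_power_d={self.iol_power_d} "
                "is not a multiple of 0.25 D"
            )
        _check_open_range(self.eye_id, "postop_se_d", self.postop_se_d, *POSTOP_SE_RANGE_D)

    @property
    def r_mm(self) -> float:
        """Anterior corneal radius implied by the displayed K."""
        return k_to_radius(self.k_d)


@dataclass(frozen=True)
class IOLConstants:
    """Lens constants for one IOL model on one device.

    Any constant may be absent (``None``) when it has not been optimized:
    ``A`` (SRK/T), ``pACD`` (Hoffer Q personalized ACD, mm), ``SF`` (Holladay
    surgeon factor, mm), ``a0/a1/a2`` (Haigis ELP triple) and ``C``
    (Shammas-PL pACD, mm).
    """

    iol_model: str
    device: str
    A: float | None = None
    pACD: float | None = None
    SF: float | None = None
    a0: float | None = None
    a1: float | None = None
    a2: float | None = None
    C: float | None = None

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValidationError(
                f"constants {self.iol_model!r}: device={self.device!r} not in {DEVICES}"
            )
        triple = (self.a0, self.a1, self.a2)
        present = [v is not None for v in triple]
        if any(present) and not all(present):
            raise ValidationError(
                f"constants {self.iol_model!r}: Haigis triple must be complete or absent"
            )
        if all(present):
            elp = self.a0 + self.a1 * 3.2 + self.a2 * 24.0
            if not (2.0 < elp < 8.0):
                raise ValidationError(
                    f"constants {self.iol_model!r}: Haigis triple implies ELP "
                    f"{elp:.3f} mm at a reference eye, outside (2, 8)"
                )
        if self.C is not None and not (2.0 < self.C < 8.0):
            raise ValidationError(
                f"constants {self.iol_model!r}: C={self.C} outside (2, 8)"
            )

    @property
    def haigis_triple(self) -> tuple[float, float, float]:
        if self.a0 is None:
            raise DomainError(f"constants {self.iol_model!r}: Haigis triple not set")
        return (self.a0, self.a1, self.a2)


CONSTANTS_COLUMNS = ["iol_model", "device", "A", "pACD", "SF", "a0", "a1", "a2", "C"]


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(path) -> list[EyeRecord]:
    """Read a cohort CSV (period decimal separator, header row) into records.

    Raises :class:`FormatError` naming any missing column, and
    :class:`ValidationError` (naming eye and field) on invariant violations.
    """
    frame = pd.read_csv(path, dtype={"eye_id": str, "iol_model": str},
                        float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"cohort file {path} missing column(s): {', '.join(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            EyeRecord(
                eye_id=str(row.eye_id),
                status=str(row.status),
                device=str(row.device),
                al_mm=float(row.al_mm),
                k_d=float(row.k_d),
                acd_mm=float(row.acd_mm),
                iol_model=str(row.iol_model),
                iol_power_d=float(row.iol_power_d),
                postop_se_d=float(row.postop_se_d),
            )
        )
    return records


def cohort_frame(records: Iterable[EyeRecord]) -> pd.DataFrame:
    """Represent a record list as a DataFrame with the canonical column order."""
    rows = [{f.name: getattr(r, f.name) for f in fields(EyeRecord)} for r in records]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(records: Sequence[EyeRecord], path) -> None:
    """Write records to CSV; ``read_cohort(write_cohort(x)) == x``."""
    cohort_frame(records).to_csv(path, index=False)


def read_constants(path) -> list[IOLConstants]:
    """Read a lens-constants table CSV (blank cells mean 'not optimized')."""
    frame = pd.read_csv(path, dtype={"iol_model": str},
                        float_precision="round_trip")
    missing = [c for c in CONSTANTS_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"constants file {path} missing column(s): {', '.join(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        def _opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out.append(
            IOLConstants(
                iol_model=str(row.iol_model),
                device=str(row.device),
                A=_opt(row.A),
                pACD=_opt(row.pACD),
                SF=_opt(row.SF),
                a0=_opt(row.a0),
                a1=_opt(row.a1),
                a2=_opt(row.a2),
                C=_opt(row.C),
            )
        )
    return out


def write_constants(constants: Sequence[IOLConstants], path) -> None:
    rows = [
        {c: getattr(k, c) for c in CONSTANTS_COLUMNS}
        for k in constants
    ]
    pd.DataFrame(rows, columns=CONSTANTS_COLUMNS).to_csv(path, index=False)


def constants_lookup(
    constants: IOLConstants | Sequence[IOLConstants] | dict,
    eye: EyeRecord,
) -> IOLConstants:
    """Resolve the constant set applying to one eye.

    Accepts a single :class:`IOLConstants`, a ``(iol_model, device) -> IOLConstants``
    mapping, or a sequence searched by the eye's model and device.
    """
    if isinstance(constants, IOLConstants):
        return constants
    key = (eye.iol_model, eye.device)
    if isinstance(constants, dict):
        try:
            return constants[key]
        except KeyError:
            raise DomainError(f"no constants for IOL model/device {key}") from None
    for k in constants:
        if (k.iol_model, k.device) == key:
            return k
    raise DomainError(f"no constants for IOL model/device {key}")
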