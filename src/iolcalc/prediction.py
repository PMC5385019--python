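"""Named calculation recipes: formula x corneal-power correction.

A :class:`MethodSpec` names one way to compute a predicted refraction for an
eye — which vergence formula to run and which no-history corneal-power
correction (if any) to apply first.  The four post-LASIK study methods are
pre-registered in :data:`STUDY_METHODS`, the plain virgin-eye formulas in
:data:`VIRGIN_METHODS`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .biometry import EyeRecord, IOLConstants, constants_lookup, k_to_radius
from .exceptions import DomainError, ValidationError
from .formulas import FORMULAS, FormulaInputs, formula_power, predicted_refraction
from .post_refractive import (
    CORRECTIONS,
    haigis_l_corrected_radius,
    koch_maloney_k,
    shammas_cd_k,
)


@dataclass(frozen=True)
class MethodSpec:
    """A named calculation recipe: formula x correction (x optional device tag)."""

    name: str
    formula: str
    correction: str = "none"
    device: str | None = None

    def __post_init__(self) -> None:
        if self.formula not in FORMULAS:
            raise ValidationError(f"method {self.name!r}: unknown formula {self.formula!r}")
        if self.correction not in CORRECTIONS:
            raise ValidationError(
                f"method {self.name!r}: unknown correction {self.correction!r}"
            )
        if self.correction == "haigis_l" and self.formula != "haigis":
            raise ValidationError(
                f"method {self.name!r}: the Haigis-L correction is only defined "
                "with the Haigis formula"
            )


#: The four post-LASIK no-history methods evaluated in the study.
STUDY_METHODS: dict[str, MethodSpec] = {
    "haigis_l": MethodSpec("haigis_l", "haigis", "haigis_l"),
    "koch_maloney_haigis": MethodSpec("koch_maloney_haigis", "haigis", "koch_maloney"),
    "shammas_cd_haigis": MethodSpec("shammas_cd_haigis", "haigis", "shammas_cd"),
    "shammas_cd_shammas_pl": MethodSpec("shammas_cd_shammas_pl", "shammas_pl", "shammas_cd"),
}

#: Plain formulas on measured K, for virgin eyes (constant optimization arm).
VIRGIN_METHODS: dict[str, MethodSpec] = {
    "srkt": MethodSpec("srkt", "srkt"),
    "hofferq": MethodSpec("hofferq", "hofferq"),
    "holladay1": MethodSpec("holladay1", "holladay1"),
    "haigis": MethodSpec("haigis", "haigis"),
}

ALL_METHODS: dict[str, MethodSpec] = {**STUDY_METHODS, **VIRGIN_METHODS}


def get_method(name: str | MethodSpec) -> MethodSpec:
    if isinstance(name, MethodSpec):
        return name
    try:
        return ALL_METHODS[name]
    except KeyError:
        raise DomainError(
            f"unknown method {name!r}; known: {', '.join(sorted(ALL_METHODS))}"
        ) from None


def formula_inputs_for(eye: EyeRecord, method: MethodSpec | str,
                       constants: IOLConstants) -> FormulaInputs:
    """Assemble formula inputs for one eye under a method's correction.

    Corrected K-values (Koch–Maloney, Shammas c.d.) are fed to the Haigis
    formula directly as its corneal power (no re-indexing); Haigis-L supplies
    a corrected radius; with no correction the Haigis corneal power comes from
    the measured radius at the formula's own index.
    """
    method = get_method(method)
    inputs = FormulaInputs(al_mm=eye.al_mm, acd_mm=eye.acd_mm, constants=constants)
    if method.correction == "none":
        inputs.k_d = eye.k_d
        if method.formula == "haigis":
            inputs.r_mm = k_to_radius(eye.k_d)
    elif method.correction == "haigis_l":
        inputs.r_mm = haigis_l_corrected_radius(k_to_radius(eye.k_d))
    else:
        kc = koch_maloney_k(eye.k_d) if method.correction == "koch_maloney" else shammas_cd_k(eye.k_d)
        if method.formula == "haigis":
            inputs.corneal_power_d = kc
        else:
            inputs.k_d = kc
    return inputs


def predict_eye_refraction(
    eye: EyeRecord,
    method: MethodSpec | str,
    constants: IOLConstants | list | dict,
    solver: str = "closed",
) -> float:
    """Predicted spectacle SE (D) for the eye's implanted power under a method."""
    method = get_method(method)
    const = constants_lookup(constants, eye)
    inputs = formula_inputs_for(eye, method, const)
    return predicted_refraction(method.formula, inputs, eye.iol_power_d, solver=solver)


def eye_power_for_target(
    eye: EyeRecord,
    method: MethodSpec | str,
    constants: IOLConstants | list | dict,
    target_ref_d: float = 0.0,
) -> float:
    """IOL power (D) the method would recommend for a target refraction."""
    method = get_method(method)
    const = constants_lookup(constants, eye)
    inputs = formula_inputs_for(eye, method, const)
    return formula_power(method.formula, inputs, target_ref_d)
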