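"""Five IOL power formulas on a single eye.

Computes the implant power each formula recommends for a typical cataract eye
with a -0.25 D target, then inverts the calculation: given the implanted
power, what refraction does each formula predict?
"""

import iolcalc as ic

# A typical virgin (never-operated) eye.
AL, K, ACD = 24.42, 43.93, 3.16

constants = ic.IOLConstants(
    iol_model="demo", device="pci",
    A=118.4,            # SRK/T
    pACD=5.04,          # Hoffer Q
    SF=1.45,            # Holladay 1
    a0=0.154, a1=0.166, a2=0.166,  # Haigis
    C=4.6866,           # Shammas-PL (from A via C = 0.5835*A - 64.40)
)

inputs = ic.FormulaInputs(al_mm=AL, k_d=K, acd_mm=ACD,
                          r_mm=ic.k_to_radius(K), constants=constants)

print(f"Eye: AL {AL} mm, K {K} D, ACD {ACD} mm, target -0.25 D\n")
print(f"{'formula':<12}{'power for target':>18}{'refr. at that power':>22}")
for formula in ic.formulas.FORMULAS:
    p = ic.formula_power(formula, inputs, target_ref_d=-0.25)
    # Round to the half-diopter grid a surgeon can actually implant.
    p_implanted = round(p * 2) / 2
    ref = ic.predicted_refraction(formula, inputs, p_implanted)
    print(f"{formula:<12}{p:>15.2f} D {p_implanted:>12.1f} D -> {ref:>6.2f} D")

# The closed-form inverse agrees with numerical root-finding:
p = ic.formula_power("haigis", inputs, -0.25)
closed = ic.predicted_refraction("haigis", inputs, p, solver="closed")
bisect = ic.predicted_refraction("haigis", inputs, p, solver="bisect")
print(f"\nHaigis inverse, closed vs bisection: {closed:.10f} vs {bisect:.10f}")
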