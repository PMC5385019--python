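"""Lens-constant optimization: make the mean prediction error zero.

Simulates a virgin-eye cohort with known outcomes, then optimizes each
formula's constant so that the cohort's mean prediction error vanishes —
the standard way surgeons personalize constants to their own biometer and
technique.
"""

import logging
import warnings

import iolcalc as ic

logging.disable(logging.WARNING)   # per-eye exclusion notices
warnings.simplefilter("ignore")    # square-root clamp notices on extreme eyes

cohort = ic.generate_cohort(ic.virgin_config(133, seed=7))
print(f"Simulated {len(cohort)} virgin eyes (seed 7).\n")

# Prediction errors at nominal, un-personalized constants:
nominal = ic.IOLConstants(iol_model="920H", device="pci",
                          A=118.0, pACD=5.2, SF=1.2,
                          a0=0.4, a1=0.1, a2=0.1, C=4.453)
print(f"{'formula':<12}{'ME nominal':>12}{'ME optimized':>15}")
optimized = ic.optimize_constants(cohort)
for formula in ("srkt", "hofferq", "holladay1", "haigis"):
    me_nom = ic.prediction_errors(cohort, formula, nominal).errors.mean()
    me_opt = ic.prediction_errors(cohort, formula, optimized).errors.mean()
    print(f"{formula:<12}{me_nom:>10.3f} D {me_opt:>12.2e} D")

print(f"\nOptimized constants: A={optimized.A:.3f}  pACD={optimized.pACD:.3f}  "
      f"SF={optimized.SF:.3f}")
print(f"Haigis triple: a0={optimized.a0:.4f}  a1={optimized.a1:.4f}  "
      f"a2={optimized.a2:.4f}")
print(f"Shammas C (from A): {optimized.C:.4f}")
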