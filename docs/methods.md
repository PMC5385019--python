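# Methods

This note records the optical model, the parameter defaults and their
rationale, what the synthetic-cohort generator does and does not emulate, the
numerical choices, and the known limitations. Quantitative claims below are
computed by the test suite (`tests/`) or by `scripts/acceptance.py`; nothing
here is asserted from outside the package.

## 1. Optical model

All five formulas treat the pseudophakic eye as a thin-lens vergence system:
corneal power `Dc`, an intraocular lens of power `P` at the effective lens
position (ELP) `d` behind the cornea, aqueous/vitreous index 1.336, and the
retina at the (formula-specific) optical axial length. Each formula is the
same algebra with different recipes for `Dc`, `d`, and the length:

- **SRK/T** — corneal height geometry from AL and K; ELP from the A constant
  via `ACD_const = 0.62467·A − 68.747`; retinal-thickness-corrected optical
  length `LOPT = AL + 0.65696 − 0.02029·AL`; corneal index term 0.333. Long
  eyes (AL > 24.2 mm) use the cubic `LCOR` polynomial.
- **Hoffer Q** — ELP is `pACD + 0.3(AL−23.5) + tan²K + 0.1·M·(23.5−AL)²·
  tan(0.1(G−AL_e)²) − 0.99166` with the published M/G branch switch at
  AL = 23 mm and AL clamped to [18.5, 31] mm **inside the ELP only**; tangent
  arguments are degrees. The branch switch leaves a genuine ~0.001 mm ELP
  discontinuity at 23 mm; it is kept as published.
- **Holladay 1** — anatomical ACD from the corneal chord (capped at 13.5 mm)
  plus the surgeon factor SF; optical length AL + 0.2 mm.
- **Haigis** — ELP is the regression `d = a0 + a1·ACD + a2·AL`; corneal power
  is computed from the radius with index 1.3315 (`Dc = 331.5/r`), not the
  display index.
- **Shammas-PL** — fixed ELP (the C constant), post-LASIK length correction
  `L* = AL − 0.1(AL − 23)`, and a corneal-plane target refraction used
  directly as published (a `vertex_correct_target` switch exposes the
  transposed variant; the 1.0125 vergence factor is likewise exposed).

Spectacle-plane refractions convert to the corneal plane with a 12 mm vertex:
`Rc = R / (1 − 0.012·R)`.

Every formula is linear-fractional in the target refraction, so the inverse —
predicted refraction for a given implanted power — is closed-form and exact.
A bisection solver over [−30, 30] D provides an independent cross-check; the
test suite verifies closed-form/bisection agreement to 1e−8 D and round-trip
exactness to 1e−6 D on a thousand random inputs per formula (observed ~1e−14).

### No-history corrections

- Koch–Maloney: `Kc = 1.114·K − 6.1`
- Shammas clinically derived: `Kc = 1.14·K − 6.8`
- Haigis-L: corrected radius `r_corr = 331.5 / (−5.1625·r + 82.2603 − 0.35)`,
  consumed by the Haigis formula's radius input.

The corrected `Kc` from the K-based maps is typed into the Haigis formula as a
corneal power directly (no re-conversion through any index) — the standard
clinical usage this package models. Shammas-PL consumes the Shammas `Kc`.

## 2. Constant optimization

Scalar constants (A, pACD, SF) are found by root-finding the cohort mean
prediction error, which is continuous and monotone in the constant: Brent's
method on a ±5 bracket around the nominal value, `xtol = 1e−10`, leaving
|ME| below 1e−6 D.

The Haigis triple uses the double linear regression: each eye's effective
lens position is back-solved from the quadratic
`d² − (AL+q)d + AL·q − (1336/P)(q − AL) = 0`, `q = 1336/z`, `z` the corneal
vergence at the observed refraction; roots outside the physiological window
(1.5, 9) mm exclude the eye with a logged reason (typically ~1% of eyes —
very long eyes with near-zero implanted powers), and the surviving ELPs are
regressed on (1, ACD, AL) by least squares. A condition-number guard
(> 1e8) rejects degenerate cohorts (e.g., constant ACD). A refraction-scale
nonlinear least-squares fit is available as `strategy="refraction"`.

**Estimator properties (measured by `scripts/acceptance.py`):** with
noiseless outcomes both strategies recover the generator's triple exactly
(≤ 1e−4). Under realistic refraction noise the ELP-scale regression is a
*biased* estimator of the generator's triple — outcome noise maps
nonlinearly into the back-solved ELP and the excluded eyes are
outcome-correlated — while the refraction-scale fit is unbiased at the
Monte-Carlo resolution of 200 replicates. Both sets of biases and their
Monte-Carlo standard errors are reported by the acceptance script. This does
not affect clinical utility: the ELP regression still nearly zeroes the mean
*refraction* error (|ME| ≤ 0.05 D is asserted by the tests), which is the
quantity constants exist to control.

The Shammas C constant is derived from the optimized A:
`C = 0.5835·A − 64.40`.

## 3. Synthetic-cohort generator

The generator emulates the *shape* of a two-biometer clinical comparison, not
any real dataset.

**Sampling.** AL and ACD are bivariate normal with correlation 0.4 (long eyes
have deeper chambers); K is independent normal. Out-of-range draws are
rejected and resampled. Defaults:

| parameter | virgin | post-LASIK | why |
|---|---|---|---|
| AL mm (mean ± SD) | 24.42 ± 2.40 | 30.06 ± 2.87 | typical cataract vs. long myopic-LASIK eyes |
| K D | 43.93 ± 1.72 | 36.35 ± 0.77 | LASIK-flattened corneas cluster tightly |
| ACD mm | 3.16 ± 0.44 | 3.34 ± 0.41 | myopic eyes: deeper chambers |
| target refraction | −0.25 D | −0.25 D | common surgical aim |
| refraction noise SD | 0.3 D | 0.3 D | repeatability of subjective refraction |
| IOL power grid | 0.5 D steps, [−10, 40] D | same | manufactured powers |
| truth formula | Haigis | Haigis | the most flexible ELP model here |

**Outcome realization.** The implant power is the truth formula's power for
the target, rounded to the grid and clipped to the manufactured range; the
observed refraction is the truth prediction at that power plus noise
(truncated to the supported range). Eyes whose clipped power leaves no
representable outcome are ineligible and redrawn — the analogue of failing
study screening.

**Post-LASIK truth.** The eye's *true* corneal power is
`shammas_cd_k(K) + N(0, 0.25)` — the Shammas clinically-derived map plus
cornea-specific scatter — typed into the truth formula directly, while the
records carry the measured K. This builds the keratometric over-reading into
the cohort: the uncorrected formula is hyperopically biased by construction,
and each correction recovers to the extent its map matches the truth map.
Consequences (all reported by the acceptance script): the Shammas-corrected
Haigis is nearly unbiased; Koch–Maloney carries a residual offset equal to the
difference of the two affine maps at the cohort's K; Haigis-L differs more
(different functional form and index convention); Shammas-PL additionally
carries its fixed-ELP structure, which extrapolates poorly to 30 mm eyes under
a Haigis-ELP truth. The generator therefore reproduces the *direction* of the
clinical finding (uncorrected ≫ corrected, all corrections shrink |ME|), not
a ranking of the corrections — that ranking is an artifact of choosing one
map as truth.

**Two biometer arms.** Paired cohorts share the true eyes, implanted powers,
and outcomes; the ultrasound/topography arm records AL 0.15 mm shorter with
0.08 mm extra noise (applanation compresses the cornea). Two readings of the
resulting contrast are computed: (a) the clinical workflow — constants
optimized per device on virgin eyes and transferred, never re-optimized, to
post-LASIK eyes — where the ultrasound arm's mean error is shifted
*hyperopically* (the virgin optimization absorbs the offset at ~24.4 mm where
diopters-per-millimeter is high, and that compensation overshoots at ~30 mm
where it is low); and (b) the literal substitution of shortened ALs under
unchanged constants, which shifts the error *myopically*. Both quantities are
reported by the acceptance script; the signs are asserted by the tests.

**Study-shaped fixture.** `make_study_fixture` emits 133 virgin and 10
post-LASIK eyes per device across four IOL models (36/33/33/31 and 4/2/1/3
eyes respectively), with per-model Haigis triples and nominal A constants,
and optimizes constants per model × device on the virgin eyes.

**Not emulated:** corneal astigmatism and posterior-surface tomography,
formula-specific measurement error in K, axial-length-dependent refraction
noise, surgeon-specific effects, bilateral correlation, and any real
patient data.

## 4. Numerical choices

- Closed-form formula inverses; Brent root-finding (`xtol = 1e−10`) only for
  constant optimization and the optional bisection cross-check.
- SRK/T's corneal-height square root is clamped at zero with a logged
  `ClampWarning` when the chord exceeds the corneal diameter (extreme
  long/steep eyes), as implementations conventionally do.
- CSV I/O uses pandas with `float_precision="round_trip"`, making
  write→read→write byte-identical; all tables are written with deterministic
  row order so pipeline outputs are reproducible byte-for-byte.
- All randomness flows from `numpy.random.default_rng` seeds; derived seeds
  come from `SeedSequence` and stay below 2³¹.

## 5. Limitations

- Thin-lens vergence only: no ray tracing, no pupil-size or asphericity
  effects, and the classic formulas' known AL-dependent biases are inherited
  by design.
- The generator's truth model is itself a Haigis-family eye; conclusions about
  *which* correction wins are circular to that choice and should not be read
  clinically.
- The Haigis-L regression domain is restricted to measured radii in
  (5.5, 10) mm; inputs outside any published domain raise rather than
  extrapolate.
- Constants optimized on cohorts under ~30 eyes are statistically fragile;
  the Haigis fit refuses cohorts with fewer than 4 surviving eyes and warns
  when the residual mean error exceeds 0.05 D.
- The ELP-scale Haigis optimization is biased as an estimator of generator
  parameters under outcome noise (see §2); use `strategy="refraction"` for
  simulation studies that need unbiased parameter recovery.
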