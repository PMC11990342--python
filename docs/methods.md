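# Methods

`seedshield` implements the complete quantitative analysis behind an
insecticidal seed-protection biofilm: a collagen–chitosan film loaded with
calothrixin A (a marine cyanobacterial alkaloid) whose release kinetics,
insecticidal dose–response, formulation optimisation, and docking-derived
mode of action are each reduced to a small, well-defined computation. The
wet-lab inputs are five small printed tables shipped as fixtures; seeded
generators reproduce the statistical structure of each assay so every stage
is testable without laboratory data.

## Desorption model (`fick_release`)

The film is a thin slab of thickness `e` (default 0.12 mm) with the active
compound initially uniform and released through one face held at zero
concentration. Under Fick's second law with constant diffusivity `D`
(mm²/day) the retained mass fraction is a sum of decaying exponentials; the
analysis uses the first-term law

    Mt/M0 = exp(-D π² t / e²) = exp(-K t),   K = π² D / e²,

so `D` comes from an ordinary least-squares line through `(t, ln Mt/M0)`
(free intercept, window `fraction ∈ (0.01, 0.99]`), `K` is always recomputed
from `D` and `e` rather than stored, and the initial areal flux is
`F = (M0/S)·K`. Choices worth noting:

- **Series mode.** The diagnostic multi-term mode keeps the decay exponents
  `D(2m+1)²π²t/e²` of the single-face model and scales the expansion so its
  leading term coincides exactly with the first-term law. The truncated sum
  therefore slightly exceeds 1 near `t = 0` (the odd-sine expansion of a
  uniform profile is not an orthonormal mass decomposition); it exists to
  quantify where the single-term approximation is trustworthy, not to
  replace it. The classical one-face-sealed textbook solution (prefactor
  8/π², exponent with 4e²) is available as `mode="textbook"` for comparison
  only. The fitter raises a `first-term-regime` flag whenever fitted points
  have retained fraction above 0.5, where dropped higher terms matter most.
- **Failure semantics.** A flat log-fraction series is flagged
  "no desorption detected", a rising one "rising curve"; both return
  `D = None` rather than a silent non-physical value.
- **Flux.** The printed per-film flux column is *not* reproducible from `D`
  and `K` alone — it implies a different `M0/S` per film that is not
  printed — so `F` is computed only when the caller supplies `M0` and `S`.
- **Concentration profile.** `concentration_profile` expands the uniform
  initial condition over the odd sine modes `sin((2m+1)πy/e)` (Fourier
  coefficients `4/((2m+1)π)`, amplitude scaled by `C0 − C*`), which satisfies
  the zero-concentration boundary at the desorbing face exactly and converges
  on the uniform initial profile as terms are added. Truncation is a fixed
  `n_terms` (default 200), not adaptive — simpler and directly testable.

Units are fixed package-wide: mm, day, g, cm² for flux. The printed
desorption table stores display-scaled values (×10⁶, ×10³, ×10⁵); scaling is
undone at load time so all in-memory values are base units.

## Bioassay reduction (`bioassay`)

Treated mortality is Abbott-corrected against pooled control mortality,
`CM% = (MOI − MOC)/(100 − MOC)·100`, clamped to [0, 100] with a
"negative-corrected" flag when controls out-die the treatment; a fully dead
control invalidates the assay. The median lethal dose is read by
piecewise-linear interpolation of mean CM% against `ln(dose)`:
`pLD50 = ln(LD50)` at the *first upward* crossing of 50%, with an exact 50%
hit resolved to the lower dose, and no extrapolation outside the tested
range. Replicates are pooled by correcting each replicate against the pooled
control rate and averaging CM per dose. No probit/logit model is fitted —
interpolation *is* the method being reproduced; the logistic tolerance curve
lives only in the simulator.

## Factorial formulation model (`factorial_doe`)

The 2³ design codes collagen (1/2 % w/v), chitosan (1/2 %) and calothrixin A
(0.1/0.5 %) as ±1. The full third-order model
`y = μ0 + Σμi Xi + ΣΣμij XiXj + μABC XAXBXC` is estimated by orthogonal
contrasts (`X'y/n`, identical to least squares since `X'X = nI`).
Coefficients are reported at full precision plus a 2-decimal
half-away-from-zero rounding for table display. With 8 runs and a single
replicate the model is saturated: fitted values equal observations and the
error-based diagnostics (SD as root-MSE, CV%, model F/p, adequate precision,
PRESS-based predicted R²) are reported as explicit
`"undefined (saturated model)"` flags. They become numbers only for
replicated input, where PRESS is computed by explicit leave-one-out refits
and adequate precision follows the signal-to-noise definition
`(max ŷ − min ŷ)/√(p·MSE/n)`. Contour grids fix the third factor at −1 by
default — the level of the observed optimum formulation (low collagen, low
chitosan, high calothrixin A).

## Association analyses (`association`)

- **Correlation matrix.** Pearson correlations of the five per-film
  variables (D, K, F, and pLD50 for *Sitona lineatus* and *Bruchus
  pisorum*) across the eight formulations. Because printed K values are
  rounded, `r(K, ·)` differs from `r(D, ·)` only in the third decimal even
  though K ∝ D exactly.
- **PCA.** Eigendecomposition of that correlation matrix (sample n−1
  standardisation); eigenvalues descend and sum to the number of variables;
  each loading vector is oriented so its largest-magnitude entry is positive.
- **Contingency battery.** For the 2×2 species × sex mortality table:
  Pearson χ² (expected counts `row·col/N`), the Yates-corrected variant
  (`(|O−E|−0.5)₊²/E` — exactly zero here because `|O−E| = 0.5` in every
  cell, hence the p-value of 1.0), Phi, contingency coefficient, Cramér's V,
  Tschuprow's T (all coinciding for 2×2), Goodman–Kruskal lambda, Cohen's
  kappa (treating the square table as an agreement table — descriptive
  only), and Yule's Q and Y. The headline lambda is the asymmetric variant
  predicting sex from species, which is the quantity that is exactly zero on
  this table; both asymmetric forms and the symmetric form are reported. A
  zero marginal makes the χ²-based battery degenerate and raises an error
  rather than returning conventions.

## Docking post-processing (`docking_post`)

Printed binding affinities convert to `pKi = −ΔG/(ln 10 · R · T)` with
`R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹` and `T = 298.15 K`, and to ligand
efficiency `LE = |ΔG|/N_heavy` with the calothrixin A heavy-atom count of 24
(C₁₉H₁₀N₂O₃). These constants are the unique standard convention consistent
with both printed pKi values at 2 d.p.; they are defaults, not hard-coded
assumptions. Docking itself (grids, poses) is out of scope.

## Synthetic data (`synthetic_data`)

Each generator is a pure function of its spec, whose seed feeds a dedicated
`numpy` Generator; one master seed can be fanned out into per-stage
substreams (`derive_seed`). Defaults mirror the bench protocol:

- **Desorption**: first-term law on a 20-point grid over 50–2000 days,
  multiplicative Gaussian noise σ = 0.02 (relative error of a gravimetric
  series is roughly constant while fractions span orders of magnitude);
  noisy values are clipped back into (0, 1] with clip events counted.
- **Bioassay**: logistic tolerance in `ln(dose)` (location `ln LD50_true`,
  slope 3 by default; `slope = inf` gives a step), 10 insects per dose in
  triplicate, 2% control mortality. The generating law is a modelling choice
  — the study specifies only the interpolation readout, not the tolerance
  distribution.
- **Factorial**: corner responses = coded-model value + N(0, σ²), σ = 0.02
  (matching the magnitude of the reported model SD for the better-fitting
  species).
- **Contingency**: the sex split of each species' cohort is deterministic
  (`round(total × male_proportion)`, emulating the designed 50/50 release);
  deaths per sex are binomial. Defaults: 100 insects per species, mortality
  0.5 (males) / 0.45 (females).

What the generators deliberately do not emulate: time-structured mortality,
between-replicate overdispersion, film-to-film manufacturing variation, and
any dependence of desorption noise on the balance used. Passing recovery
tests therefore show the estimators are correct under the stated sampling
models, not that real assays satisfy those models.

## Numerical and testing notes

- Recovery experiments in the test suite use 200 seeded desorption curves
  (2% noise; median relative error of D̂ under 5%), 200 factorial designs,
  and 500 simulated assays (mean pLD50 within 3 s.e. of truth); the whole
  suite runs in a few seconds.
- Dual routes are kept separate throughout: contrasts vs. the solved normal
  equations, PRESS vs. brute-force leave-one-out, χ² vs.
  `scipy.stats.chi2_contingency`, PCA vs. scikit-learn on standardised data,
  quadrature of the concentration profile vs. the series mass law.
- Reports are deterministic: same inputs and seed give byte-identical JSON;
  the seed and the units policy are echoed in every artifact.

## Known limitations

- The raw mortality-vs-dose data behind the printed pLD50 responses are not
  published, so those endpoints are consumed as data and the bioassay stage
  is validated on synthetic assays only.
- The printed model F/p values and the SD/CV/R²-family diagnostics of the
  factorial tables presuppose an error structure (replication or term
  pooling) that is not stated; the package computes them only when the input
  actually provides residual degrees of freedom.
- pLD50 = ln(LD50) is implemented exactly as defined; note that a *larger*
  pLD50 means a larger lethal dose (weaker activity), whatever
  interpretation is attached to it downstream.
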