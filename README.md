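# seedshield

Quantitative analysis pipeline for insecticidal seed-protection biofilms:
collagen–chitosan films loaded with the marine alkaloid calothrixin A and
used to protect stored pea seeds against the weevils *Sitona lineatus* and
*Bruchus pisorum*. The package is aimed at formulation and biocontrol
researchers who need the full desk analysis of such a system — release
kinetics, bioassay reduction, design-of-experiments modelling, association
statistics and docking post-processing — as tested, scriptable code.

## What it computes

- **Fickian desorption** (`fick_release`): the retained mass fraction of a
  slab film follows `Mt/M0 = exp(−Dπ²t/e²) = exp(−Kt)`; diffusivity `D`
  (mm²/day) is the slope of `ln(Mt/M0)` vs `t`, the release constant is
  `K = π²D/e²`, and the initial flux is `F = (M0/S)·K`.
- **Bioassay reduction** (`bioassay`): Abbott-corrected mortality
  `CM% = (MOI − MOC)/(100 − MOC)·100` and `pLD50 = ln(LD50)` by linear
  interpolation of CM% against `ln(dose)` at the first 50% crossing.
- **2³ full-factorial model** (`factorial_doe`): coded collagen, chitosan
  and calothrixin A levels; coefficients of
  `y = μ0 + Σμᵢxᵢ + ΣΣμᵢⱼxᵢxⱼ + μABCxAxBxC` by orthogonal contrasts, with
  Design-Expert-style diagnostics (R² family, PRESS, adequate precision)
  and contour grids.
- **Association analyses** (`association`): Pearson correlation matrix of
  (D, K, F, pLD50) across formulations, PCA of the correlation matrix, and
  the full 2×2 contingency battery (χ² plain/Yates, Phi, Cramér's V,
  Tschuprow's T, contingency coefficient, Goodman–Kruskal lambda, Cohen's
  kappa, Yule's Q/Y) for species × sex mortality.
- **Docking post-processing** (`docking_post`):
  `pKi = −ΔG/(ln10·R·T)` at 298.15 K and ligand efficiency `|ΔG|/N_heavy`
  (24 heavy atoms for calothrixin A).
- **Synthetic data** (`synthetic_data`): seeded generators for all four
  input kinds, so every stage runs and is validated without wet-lab data.

The printed study tables (design + responses, desorption parameters, film
constants, contingency counts, docking affinities) ship as fixtures and load
with `seedshield.load_fixtures()`.

## Worked example

Simulate a mass-loss curve at the optimal film's diffusivity and fit it
back:

```sh
$ seedshield simulate desorption --seed 7 --out demo
$ seedshield fit-desorption --curve demo/sim_desorption_curve.csv --out demo
{
  "D_mm2_per_day": 3.821159424807542e-06,
  "K_per_day": 0.002618981380301708,
  ...
  "r_squared": 0.9998954238874651,
  "n_points": 17
}
```

The fitted diffusivity recovers the generating value 3.82×10⁻⁶ mm²/day to
three figures despite 2% multiplicative noise, and the derived release
constant K = 2.62×10⁻³ /day matches the printed value for the optimal film
(CB3C-5). The association battery on the bundled species × sex mortality
counts:

```sh
$ seedshield assoc chi2 --out demo
{
  "chi2": 0.022,
  "p_value": 0.883,
  "chi2_yates": 0.0,
  "p_value_yates": 1.0,
  "phi": 0.011,
  "cramers_v": 0.011,
  "goodman_kruskal_lambda": 0.0,
  "cohen_kappa": 0.011,
  "yule_q": 0.022,
  ...
}
```

Every coefficient is near zero and the Yates-corrected χ² is exactly zero
(|O−E| = 0.5 in all four cells): mortality is independent of species and
sex. Other stages: `seedshield doe` (factorial coefficients and contour
grids), `seedshield assoc corr|pca`, `seedshield dockpost`, and
`seedshield simulate bioassay|doe|contingency`; all subcommands accept
`--seed` and `--out`, and the library API in `seedshield.*` exposes the same
operations programmatically.

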