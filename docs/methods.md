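# Methods

## The model family and its assumptions

All four candidate laws share the turnover system

```
dXm/dt = km − dm·Xm − δ(Xm, Xs)
dXp/dt = kT·Xm − dp·Xp
```

with the target transcribed constitutively at rate `km` (a.u.·min⁻¹) and
degraded basally at `dm` (min⁻¹). Three assumptions shape everything
downstream:

1. **Constant dose.** The siRNA-RISC complex is long-lived relative to
   the experiment, so `Xs` (pmol per well) is treated as constant; RISC
   loading is assumed fast and is not modeled as a separate step.
2. **Steady state at readout.** Measurements taken ~48 h after
   transfection are treated as equilibria. At `dm = ln2/40 ≈ 0.0173 min⁻¹`
   that is ~72 transcript half-lives; the `dynamics` module verifies the
   closed forms against direct integration rather than assuming them.
3. **Ratio observable.** Data are treated/control ratios. Dividing the
   steady state by the control level `km/dm` cancels `km` for the
   mass-action, cooperative and Hill laws. For the enzymatic law the
   cancellation is only partial: the ratio depends on `km` solely through
   the cluster `c3/km`, which is why the enzymatic model is parameterized
   by `(k3h3, c3_over_km)` and never by `k3`, `h3`, `c3` individually.
   Its ratio is the positive root of a quadratic,
   `r = (−b + √(b² + 4·a·kh·dm)) / (2·kh)` with `a = c3/km`,
   `kh = k3h3`, `b = a·dm + a·kh·Xs − kh`, evaluated on the
   cancellation-free branch and pinned to exactly 1 at `Xs = 0`.

Protein-level ratios equal mRNA-level ratios because the translation gain
`kT/dp` cancels; protein data are therefore fitted with the same ratio
formulas but yield their own parameter set.

## Parameters, units, defaults

| symbol | meaning | unit | default |
|---|---|---|---|
| `dm` | basal mRNA degradation | min⁻¹ | 0.0173 (= ln2/40); fixed, never fitted |
| `km` | transcription rate | a.u.·min⁻¹ | 1 (cancels from ratios) |
| `kT`, `dp` | translation, protein degradation | min⁻¹ | 1 (cancel from ratios) |
| `k1` | mass-action rate | (pmol·min)⁻¹ | fitted |
| `k2`, `h2` | cooperative rate, exponent | (pmol^h2·min)⁻¹, – | fitted |
| `k3h3`, `c3_over_km` | enzymatic clusters | (pmol·min)⁻¹, a.u. | fitted |
| `d4`, `theta4`, `h4` | Hill max rate, half-max dose, steepness | min⁻¹, pmol, – | fitted |

Doses are pmol per 2 mL transfection well throughout; `pmol_to_molar`
converts when molar units are needed (200 pmol ↔ 100 nM). Reference
fitted values used in tests and examples — e.g. `k1 = 1.38e-4`,
`(d4, theta4, h4) = (8.1e-3, 0.105, 4.47)` for mRNA and
`theta4 = 12.9` for protein, and `c3_over_km = 1.33e3` — come from a
published EGFP silencing titration and serve as generating truths for
recovery tests, not as universal constants.

## Fitting

The objective is the SE-weighted sum of squared ratio residuals,
`Σ((r_model − r_data)/SE)²`, with an unweighted fallback for datasets
whose SEs are unreliable or absent. A standard error below 1e-6 in
weighted mode is an error, not a silent clip: the caller must either fit
unweighted or floor the SEs deliberately.

Minimization contract: seeded global stochastic search. Concretely,
scipy's differential evolution runs in a transformed space — rate-like
parameters on log10 scale over [1e-8, 1e2], `theta4` over [1e-4, 1e3]
pmol, Hill exponents linear over [0.05, 10] — with `restarts`
independently seeded runs (default 10) and a final Nelder–Mead polish of
the best candidate. `c3_over_km` is searched over [1e-4, 1e8]: it is a
concentration-like ratio, not a rate, and its physically meaningful
near-mass-action regime lives at large values, so the rate range would
truncate it. The optional `constrain_h_ge_1` mode restricts `h2` to
[1, 10], where data favoring `h2 < 1` drive the fit onto the boundary
`h2 = 1` and the cooperative model collapses onto mass action.

Zero-dose points are included in fitting; the model predicts exactly 1
there, so they contribute only when noise displaces the measured ratio.
Normalized errors divide each model's error by the largest across the
four, so the worst model scores exactly 1 and the comparison is invariant
to whether raw sums or per-point averages are used.

## Leave-one-out prediction error

Each of the N dose points is held out in turn, the model is refitted on
the remaining N−1 (fold i reuses the base seed + i), and the held-out
prediction is scored by its (weighted) squared error; the PE is the mean
over folds, and PEs are normalized across models like fit errors. The
zero-dose point is held out like any other. A failing fold is excluded
with a warning rather than aborting the whole analysis. In tests and the
acceptance script LOO folds use fewer restarts (3–4) than full fits: the
fold problems are 13-point, 1–3-parameter fits for which that is ample,
and it keeps a 56-fit LOO pass to well under a minute.

## Synthetic data

`generate_dataset` emulates the design of a well-plate titration: the
14-dose grid {0, 0.001, 0.01, 0.05, 0.1, 0.5, 1, 10, 20, 40, 60, 80,
100, 200} pmol, three biological replicates per dose, and ratio-valued
readouts. Replicate noise is multiplicative lognormal with mean 1 and
coefficient of variation `cv` (default 0.1 — ratios are positive,
fold-change-like quantities whose scatter scales with their magnitude;
0.1 gives error bars of the size typical of triplicate qPCR series). The
reported mean is the replicate mean and the SE the sample SD over √n.

What the generator does *not* emulate: qPCR amplification mechanics
(ΔΔCt), FACS fluorescence distributions, transfection-efficiency
variation between wells, dose-dependent noise structure, or any
between-dose correlation. Passing recovery and model-selection tests on
this generator therefore shows the pipeline is correct and
well-conditioned under the stated noise model — not that real
measurements obey it.

## Numerical choices

- Steady states are closed-form; the enzymatic quadratic uses the
  cancellation-stable branch (`2·a·dm/(b + √·)` when `b ≥ 0`). Every
  returned equilibrium satisfies the balance residual
  `km − dm·X − δ(X, Xs) = 0` to 1e-9 relative, and a bracketing root
  finder provides a second, independent route in the tests.
- Time courses use LSODA with rtol 1e-8 / atol 1e-11; stiffness arises
  because rate constants span ~1e-4 to 1e3.
- Degenerate inputs: zero dose or zero mRNA gives zero RNAi flux exactly;
  a zero-dose ratio is pinned to exactly 1; nonpositive rates, negative
  doses/levels, and mismatched model/parameter pairings raise immediately.
- All randomness (noise generation, optimizer restarts, LOO folds) flows
  from explicit integer seeds; identical seeds give byte-identical
  reports.

## Design choices that were genuinely open

- **Optimizer.** Any seeded global stochastic minimizer satisfies the
  contract; differential evolution was chosen over a genetic algorithm
  because scipy ships it with reproducible seeding, and restart + polish
  covers its occasional basin misses. Population ~18×dim, ≤250
  generations, tolerance 1e-8 pass every recovery test with large margin.
- **Dose units.** Ratios are fitted against pmol per well, not molar
  concentration; the two differ only by a fixed volume factor, and
  conversion helpers are provided rather than mixing units internally.
- **Problem sizes.** Recovery tests use the full 14-dose grid; the
  ODE-vs-closed-form sweep uses 100 random parameter sets (25 per model);
  the model-comparison study uses one 14-dose, cv = 0.1 triplicate
  dataset. These sizes make every headline check exact or
  comfortably converged while keeping a full run in minutes.

## Known limitations

- Deterministic, population-average models: no stochastic single-cell
  effects, no delay terms, no siRNA decay or dilution by cell division.
- The enzymatic and mass-action models are near-degenerate on saturating
  data (`c3_over_km` runs to its upper bound); the fitted value of
  `c3_over_km` is then a bound artifact, only its order of magnitude is
  meaningful.
- Under strong noise the Hill steepness `h4` is weakly identified and can
  hit its upper bound; `theta4` and `d4` remain stable.
- LOO refits the same bounded global search per fold; with very few dose
  points (< 5) fold fits can sit on bounds and the PE becomes noisy.
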