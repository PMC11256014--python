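# Methods

## Detection and linear range

A dilution level counts as *detected* when at least `min_replicates`
(default 2 of 3) replicate peak areas reach `min_area` (default 10 000
counts, a typical peak-picking floor for Orbitrap-class instruments). A
missing cell and a zero area both mean "not detected": detection in this
workflow is presence/absence per replicate. An optional blank filter
requires the mean area at the lowest detected level to exceed
`blank_ratio` (default 5) times the blank area.

Calibration lines are ordinary least squares of **per-level mean areas**
(mean over detected replicates) on concentration, with intercept.
Replicate scatter is consumed separately by the SD-based estimator, so
fitting level means keeps one curve per compound without double-using the
triplicate information. The linear range is found by iterative bottom
trimming: while any absolute relative residual exceeds `rel_tol` (default
5%), drop the lowest remaining level and refit. Relative residuals are
computed against the *fitted* value so the criterion stays defined when an
observation is zero. Trimming never removes a top level; top-end
saturation therefore surfaces as an R² failure rather than being repaired.
The loop keeps at least `min_levels` = 4 levels ("more than three"), while
*acceptance* of the final fit requires ≥ `min_points` = 3 points and
R² > `r2_min` (default 0.90; 0.98 is the conventional choice for manually
integrated data). Both thresholds are configurable because the two roles
are genuinely distinct: one guards the loop, the other judges the result.

The **response factor** is the slope of the accepted line (M⁻¹): the
method's sensitivity toward the compound, dominated in ESI by ionization
efficiency.

## The four LoD estimators

With `c₁` the lowest detected concentration, `s` the accepted slope and
SD the sample (n−1) standard deviation:

| approach | formula | notes |
|---|---|---|
| cut-off | `LoD = c₁` | flagged if outside the dynamic range (level mean not below the next level's, or above the linear range) |
| S/N extrapolation | `LoD = c₁ᵣ · sn_target / (S/N at c₁ᵣ)` | `c₁ᵣ` = lowest detected level *inside* the linear range; assumes signal linearity below the measured range; `sn_target` defaults to 3 |
| SD-based | `LoD = k_sd · SD(areas at c₁) / s` | `k_sd` defaults to 3.3, the usual 3.3·σ/slope convention |
| residuals | `LoD = k_resid · SD(resid of n lowest in-range levels) / s` | `n_resid_levels` defaults to 3; 4 is available, as both conventions exist |

S/N values are never synthesized from peak areas: noise estimation is
instrument-specific, so when no S/N column is supplied the S/N estimator
reports itself unavailable instead of guessing. Estimators whose
preconditions fail always report a reason; they never return 0 or NaN in
place of an estimate. A zero SD (noise-free data) yields LoD = 0 with a
`flag_degenerate` diagnostic. Residual SDs below 1e−12 of the local signal
scale are snapped to zero, since an exact line leaves only rounding dust
in OLS residuals. The residuals approach is deliberately not clipped when
it exceeds the top calibration level — it is known to produce
unrealistically conservative values — only flagged.

## Transfer model: log IE → log₁₀ LoD

LoD spans 5+ orders of magnitude, so the transfer line is fitted on
log₁₀ LoD. "Robust regression" is implemented as a Huber M-estimate via
iteratively reweighted least squares: tuning constant 1.345 (95% Gaussian
efficiency), scale re-estimated each iteration as the normalized MAD of
residuals, convergence when the largest coefficient change falls below
1e−8, at most 100 iterations; Theil–Sen is available as an alternative.
On outlier-free collinear data the estimate equals the exact line; a zero
MAD short-circuits the reweighting. Standard errors come from the final
weighted normal equations with the robust scale.

Predicted log IE is optionally corrected for the monoisotopic-peak
fraction (`log IE + log₁₀ fraction`, a no-op at the default fraction 1):
peak areas are integrated for the main isotopic peak only, so the
predicted whole-compound ionization efficiency slightly overstates the
observed signal for heavier compounds. Models carry a `label`
(e.g. structure-based vs fingerprint-based log IE) and appliers refuse a
mismatched source unless forced, because the two prediction routes are
calibrated differently. Coefficients are always re-fitted from data,
never hard-coded.

By default the transfer model is fitted on the **cut-off** LoDs: the
cut-off approach is available for every detected compound (the other
three need an accepted linear range) and makes the fewest assumptions.
Any of the four can be configured instead.

## Rank statistics

Spearman ρ is the Pearson correlation of tie-averaged ranks. For
n ≤ 7 the two-sided p-value is exact (all n! permutations enumerated);
otherwise the t-approximation with n−2 degrees of freedom is used.
Correlations are two-sided by default. The Wilcoxon rank-sum comparison is
the Mann–Whitney U with exact enumeration when n·m ≤ 400 and no ties, and
a continuity-corrected normal approximation otherwise; it is one-sided
where the scientific question is directional (better-ionizing compounds
should have *lower* LoDs). No multiple-testing correction is applied —
the handful of reported correlations are individually motivated, not a
screen.

## Chemical space

Suspect lists are pre-filtered on composition — carbon present, nitrogen
or oxygen present, neutral monoisotopic mass ≥ 100 Da (computed from the
formula with standard atomic masses; no adduct is assumed) — since
compounds failing these are unlikely to be retained and ionized in
reversed-phase LC/ESI(+). Unparseable formulas are rejected per record
with a reason, not fatally.

PCA standardizes columns to zero mean and unit sample SD (constant
columns dropped and recorded), decomposes by SVD, and fixes signs so each
component's largest-magnitude loading is positive — making repeated fits
bit-identical. Projection applies the stored standardization and loadings
with name-based column alignment; projecting the training set reproduces
the training scores exactly because the training scores are computed
through the same code path. Representative selection is greedy
farthest-point (maximin Euclidean) sampling in the PC1–PC2 plane, seeded
at the point farthest from the centroid, ties broken by lowest compound
id. The original studies curate such selections manually; the
deterministic maximin rule replaces that step because automation and
reproducibility are the point of this package.

## Synthetic data generator

The generator emulates a standards-based calibration study:

- **Grid**: 16 dilution levels in triplicate, relative factors
  1, 0.2, 0.1, … 2e−8 of a top concentration (default 1.67e−6 M,
  ≈ 500 µg/L at MW 300 g/mol) — spanning ~7.7 orders of magnitude.
- **Signal**: `area = sat(RF·c) · (1 + ε_m) + ε_a` with proportional
  noise ε_m ~ N(0, cv = 0.05), additive noise ε_a ~ N(0, σ), negative
  draws floored at 0, and optional saturation
  `sat(u) = A·(1 − e^(−u/A))` (off by default — the trimming loop only
  handles bottom-end nonlinearity). The S/N column is area/σ.
- **Truth**: the true LoD is *defined* as `sn_target·σ/RF`, so the S/N
  extrapolation's assumption holds exactly in expectation and estimator
  deviations are attributable to the estimators, not simulator mismatch.
- **Link**: log IE is drawn uniformly (range derived from the configured
  response-factor span, default implying RF ≈ 10^12.5–10^16.5 M⁻¹), then
  `log₁₀ LoD = a + b·log IE + N(0, σ_link)` with defaults
  (a, b, σ_link) = (−5, −1, 0.5), and RF follows as `sn_target·σ/LoD`.
  The link is generative in this direction deliberately: solving log IE
  *from* a noisy LoD would make the regression of LoD on log IE
  attenuated (errors-in-variables), and the package's recovery guarantees
  would be unattainable by construction rather than informative.
- **Noise floor**: σ is log-uniform over (1500, 3000) counts by default,
  chosen so that with the 10 000-count detection floor the true LoD sits
  within about one dilution step of the lowest detectable level — the
  regime a well-designed calibration ladder aims for — while spurious
  sub-LoD detections stay negligible (P(ε_a ≥ 10⁴) ≤ 4e−4 per replicate).

All simulators are pure functions of (config, seed); the study spawns
per-compound child seeds from a `SeedSequence`, so compound i's series
does not depend on how many compounds are simulated after it.

What the generator does **not** emulate: chromatographic peak shapes,
m/z-dependent noise, matrix effects beyond a response-factor multiplier,
correlated replicate drift, day-to-day sensitivity shifts, and real
descriptor→log IE prediction error. Passing tests therefore demonstrate
the estimators' and the transfer fit's correctness and calibration *under
the stated noise model*, not the field performance of any particular
instrument or prediction model.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script use 221 compounds
(16 levels × 3 replicates) and 200 features with 20-deep priority tables;
property tests use 100–500 seeded replicates and n = 300 for transfer
recovery. These sizes give stable rank statistics and tight recovery
checks while keeping every run comfortably fast on one CPU.

Other numerics: OLS via `numpy.polyfit`; R² = 1 − SS_res/SS_tot with the
convention R² = 1 for an exact fit of constant data; sample SDs
throughout (triplicates); CSV floats written with 17 significant digits
so read–write round trips are lossless and reruns are byte-identical;
manifests contain configuration, seed and package version but no
timestamps, for reproducibility.

## Known limitations

- The cut-off LoD is grid-quantized: it can never be more precise than
  the dilution ladder, and with a detection floor well above the true LoD
  it overestimates systematically (the S/N extrapolation is the intended
  complement below the measured range).
- The linear-range loop only ever trims the bottom, so a single noisy
  mid-range level can fail an otherwise usable series; with 5%
  proportional noise against the 5% residual tolerance, roughly a fifth
  to a third of simulated series gain an accepted range — conservative by
  design.
- Huber IRLS has a breakdown point well below 50%; Theil–Sen is provided
  for heavier contamination.
- The suspect-list mass filter uses the neutral monoisotopic mass, a
  deliberate simplification where an m/z threshold would need an adduct
  assumption.
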