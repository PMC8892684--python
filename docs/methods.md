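# Methods

## The data model

The experimental unit is the treatment mean: the average of all animals on
one dietary treatment within one respiration-calorimetry study (chamber or
headbox). Energy concentrations (GE, DE, ME) are Mcal per kg of dry matter;
diet composition (CP, NDF, EE, starch, TDN) is % of DM; methane and urinary
energy are stored as % of DE. Missing cells are explicit missing values and
are never imputed; a loader hook (`column_map`) adapts arbitrary spreadsheet
headers to the canonical schema.

The packaged database (`load_table1`) holds the 47 treatment means from the
11 studies added to an earlier 87-mean development compilation. The combined
134-mean spreadsheet is distributed with the original publication and is not
redistributed here; every analysis in the test suite and the acceptance
script therefore runs on the 47-mean subset (or on synthetic data), and
checks against published full-database statistics are phrased either through
values that are derivable for the subset (e.g. the subset mean DE implied by
the published 3.15 → 3.05 Mcal/kg shift) or through the statistical
consistency of the subset estimate with the published value. Two pairs of
treatments in the source table share a diet label within study; the
transcription disambiguates them (period/series suffixes) so that
(citation, diet) is a unique key.

Validation flags, rather than raises: ME > DE, DE > GE, non-positive
BW/DMI/n, percentages outside [0, 100], and a printed ME:DE ratio differing
from ME/DE by more than `ratio_tol` (default 0.005, which covers two-decimal
rounding of the printed energy columns).

## The DE→ME mixed model

    ME_ij = (β0 + u_i) + (β1 + v_i)·DE_ij + ε_ij,
    (u_i, v_i) ~ N(0, Σ),  ε_ij ~ N(0, σ²)

* Estimation is REML via `statsmodels` `MixedLM`. Fixed-effect inference
  uses t statistics with between-study degrees of freedom
  (`n_studies − rank`), a conservative stand-in for the between-within
  approximation; only significance-level claims (p < 0.05, p < 0.01) are
  made, not exact p-values.
* DE is not centred: the intercept at DE = 0 is the interpretable quantity
  in this literature (the constant energy loss per kg of DMI).
* Fallback ladder for singular random structures: correlated
  intercept+slope → uncorrelated → intercept-only → OLS. Each step is
  recorded in `notes`, and `converged` is honest. A single study, or an
  exactly linear response, short-circuits to OLS with zero variance
  components (nothing else is identifiable). A variance component estimated
  on the zero boundary makes the BLUP covariance singular; the BLUPs are
  then exactly zero and are set so.
* Citation adjustment subtracts the BLUPs from the response only
  (`y − û_i − v̂_i·x`); x is left untouched. The adjusted-data OLS then
  reproduces the fixed effects to within sampling error (property-tested at
  2·SE).
* RMSPE of the adjusted fit uses the n denominator (prediction-error
  framing), so it is the root mean squared residual of the displayed line.

The citation-adjusted mean of methane energy per kg of DMI is the fixed
intercept of the intercept-only variant of the same model.

## The net-energy chain and the methane equations

* Dietary NEm and NEg are cubic polynomials in ME. The coefficient values of
  the companion recalibration are not printed in the source text, so the
  shipped default is the classic NRC-lineage pair
  (NEm = 1.37·ME − 0.138·ME² + 0.0105·ME³ − 1.12;
  NEg = 1.42·ME − 0.174·ME² + 0.0122·ME³ − 1.65), clearly labelled a
  stand-in and overridable through `EnergyConfig` (YAML). Every statistic
  downstream of the NEm chain (multiple of maintenance, the intake-adjusted
  methane refit) is conditional on this choice, which is why the refit is
  checked directionally (negative slope, p < 0.05) rather than against the
  published coefficients.
* Multiple of maintenance = DMI × NEm(diet) / (0.077 × BW^0.75). When the
  chain starts from DE, ME is predicted with the updated linear regression
  (`eq1`) by default; `eq2` or the observed ME column can be selected.
* The intake-adjusted methane equation returns a per-kg-DMI rate
  (`eq4_rate`); the daily dispatcher multiplies by DMI. Negative predictions
  (multiple of maintenance > 5.93, far outside the development range) are
  returned flagged, not clamped — the caller decides.
* Unit conventions. Equations developed on calorimetry energy data (`eq3`,
  `eq4`) convert Mcal → L → g with 9.45 kcal/L and 0.716 g/L (0.05522 MJ/g
  end to end). Inventory-style equations printed in g/d or built with
  ÷0.05565 use the flat 0.05565 MJ/g. The two routes differ by ~0.8%;
  `MethanePrediction` records which route filled its secondary scales, and
  `convert_methane` never mixes them within one call. The MJ→g route for the
  DMI-based MJ/d equation is not stated in the source text; the tier
  convention is the default and is configurable.

## Equation evaluation

All evaluation moments use the population (n) denominator. This makes the
three MSPE components — mean bias (p̄ − ō)², slope bias (s_p − r·s_o)², and
random error (1 − r²)·s_o² — sum to the MSPE exactly, so the reported
percentages sum to 100 (report headers in this literature sometimes say
"% of RMSPE", but only percentages of the squared quantity can do that).
RMSPE in the observed-vs-predicted regression is sqrt(MSPE) on the same
vectors by construction. CCC follows Lin's precision × accuracy form with
population moments; two constant, equal vectors are perfectly concordant by
convention, and a constant prediction gets CCC 0 through the formula.
Confidence limits for the observed-vs-predicted line use t quantiles with
n − 2 degrees of freedom. Observed daily methane in g/d is derived from the
% of DE column via the calorimetric chain, and the convention is recorded.

Rows missing the inputs of a given equation are dropped for that equation
only, with the per-equation count carried into the report.

## The synthetic-data generator

`GeneratorParams` defaults are the development-database conditions: 34
studies with 2–6 treatment means each (~130 rows), β0 = −0.3926,
β1 = 1.0001, residual SD 0.04 Mcal/kg (the scale of the adjusted-fit RMSPE),
DE uniform on 1.8–3.9 Mcal/kg, intake 0.77–2.44 % of BW, BW 130–560 kg, and
DE/GE digestibility uniform on 0.46–0.80 (the span of the packaged rows).
Random-effect SDs (0.15 for intercepts, 0.05 for slopes, correlation −0.9)
were chosen once to give ≈ 0.07 Mcal/kg between-study spread in ME at
DE = 3 — typical of calorimetry compilations; the strong negative
correlation is the usual intercept/slope trade-off of an uncentred
covariate. Methane energy per kg of DMI follows either a study-shifted
constant (0.2433, study SD 0.03, residual SD 0.015) or the declining
intake-adjusted line (0.3344 − 0.05639 × multiple of maintenance).

Draws come from a single seeded generator in a documented order (study
effects, then per-observation covariates, then noise), so identical seeds
give byte-identical CSVs. Infeasible draws (ME outside (0, DE)) are
resampled and counted; urinary energy closes the DE − ME balance after
methane and is floored at zero (floor events counted) — the generator treats
methane + urine as the DE − ME gap, which is exactly the assumption behind
the constant-offset ME equation.

What the generator does not emulate: correlated diet-composition structure
(CP/NDF/starch are not linked to DE), repeated animals across treatments
within a study, measurement error in the covariate, and the heavier tails of
real between-study variation. Passing recovery tests therefore show that the
estimation machinery is correct under the stated model, not that the model
is correct for any particular real database.

## Problem sizes and numerical choices

* Parameter-recovery checks run 100–200 synthetic replicates at the
  34-study/134-observation scale; slope CI coverage ≥ 90/100 and mean slope
  bias < 0.01 are the acceptance properties.
* Mixed-model fits use `lbfgs` with a `powell` fallback, up to 2000
  iterations; identities are asserted at 1e-9 relative, estimator agreement
  at 2·SE.
* Median splits rank descending with a stable sort (input order breaks
  ties); with even n the groups are exactly n/2, with odd n the high group
  takes the extra row.

## Known limitations

* The intake-adjusted methane coefficients cannot be reproduced exactly
  without the recalibrated NEm cubic; the directional refit is the supported
  check.
* The published full-database regression constants are reproduced only in
  the consistency sense described above while the 134-mean spreadsheet is
  loaded externally.
* The evaluation module reproduces the report structure of a six-equation
  comparison, but the independent 129-point evaluation database behind the
  published comparison is not deposited anywhere machine-readable, so those
  printed statistics are not targets.
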