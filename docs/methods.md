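# Methods

## Data model and conventions

All months are 1-based calendar integers. A forecast issued in month `m`
(on the 1st) at lead `lt ∈ 0..6` verifies month `m_v = m + lt`, circular
over 12 — lead 0 verifies the issue month itself, whose anomaly is only
known once the month ends. The growing season of winter cereals runs
October (year `y−1`) through June (harvest year `y`); season order
(Oct < Nov < … < Jun) decides whether a predictor month is "past" for a
given issue month. The first usable season of a record starting in year
`Y0` is harvest year `Y0+1` (the default 1993–2019 record gives 26
seasons, 1994–2019).

Standardization is always "interannual": detrend against year by OLS, then
divide the residuals by their **population** SD (divide by n). The
convention is recorded in every provenance block; it cancels in all
correlation-based metrics and only rescales MAE/RMSE consistently across
systems. For climate it is applied per (region, variable, calendar month)
across years; for yields, once per regional annual series (provinces are
averaged first — unweighted, since no weighting basis is modelled — and
the per-province-vs-after-averaging order is recorded in provenance).
Constant series and exact linear ramps are degenerate and raise; missing
cells always raise (a 26-point record cannot absorb silent gaps).

## Synthetic study system

The generator produces the statistical structure the analysis assumes, not
weather realism:

* **Climate.** Per (region, variable), monthly value =
  climatology mean(m) + SD(m) · z, where z follows a stationary AR(1)
  chain across the continuous month sequence (Dec→Jan linked),
  `z_t = φ z_{t−1} + √(1−φ²) ε`. Default φ = 0.35 (a realistic
  month-to-month anomaly persistence; without it the persistence baseline
  would be vacuous). Precipitation is floored at 0 after adding the
  anomaly. The default climatology is Mediterranean-flavoured (wet
  Oct–Apr, dry summer; TX−TN ≥ 6 K so the physical ordering never binds).
  The unfloored chain is carried as generator truth (`z_true`).
* **Hindcasts.** Member value at (m, lt, year) =
  clim(m_v) + d(lt)·SD(m_v)·z_true + s(lt)·SD(m_v)·ε, ε i.i.d. standard
  normal per member, then flooring (PR) and the imposed bias (additive K
  for TX/TN, multiplicative for PR; flooring precedes the bias so the
  multiplicative correction stays well-posed). Default damping
  d = (0.9, 0.5, 0.3, 0.2, 0.15, 0.1, 0.1) and noise scale
  s = (0.6, 0.8, 0.95, 1.0, …, 1.0) emulate how operational systems lose
  most anomaly signal beyond lead ~2. Noise is white across members and
  years; no spread-error calibration is attempted (only ensemble means and
  CRPS are consumed downstream).
* **Yields.** Latent standardized anomaly a(y) = planted sparse linear
  combination of z_true (Oct–Dec read from year y−1) + N(0, 0.45²) noise;
  regional yield = 2.9 ton/ha + 0.03 ton/ha/yr technological trend +
  0.4 ton/ha · a(y); provinces deviate by N(0, 0.05²) ton/ha and share one
  climate series (regional aggregation is upstream of the analysis).
  With the default planted coefficients (Σc² ≈ 0.53) the population R² of
  the true model is ≈ 0.70, the regime of published regional cereal
  models. Production = yield × fixed per-province area.

All randomness derives from one seed through three independent
`numpy` substreams (climate / hindcasts / yields); identical configurations
are bitwise-reproducible.

What the generator does **not** emulate: spatial fields and their
covariance, non-Gaussian precipitation tails, ENSO/NAO-type low-frequency
modes, spread-error relationships, yield responses beyond a linear model
(frost kill, heat spikes), reporting errors in production records. Passing
tests therefore certify the pipeline's correctness and its behaviour under
the stated statistical assumptions — not skill on real data.

## Bias correction

Per (region, variable, issue month, lead): α_PR = ratio of observed to
forecast climatological means (obs taken at the verification month over
exactly the verification years the cell covers), α_TX/TN = their
difference; members are corrected multiplicatively (PR) or additively
(TX/TN). Consequences asserted in tests: corrected climatology matches the
observed one exactly over the calibration years; additive correction
preserves ensemble spread while ratio correction scales it by α;
re-deriving factors from corrected data yields the identity. The
calibration period defaults to the full record (configurable); the
correction is not cross-validated (no left-out verification year). A ratio
denominator below 1e-6 mm (arid-month degeneracy) raises rather than
producing unbounded factors.

## Regression and cross-validation

The candidate pool is exactly 27 standardized anomalies (PR/TX/TN ×
Oct–Jun). Selection is pure forward: each step tentatively adds every
remaining candidate to the OLS fit and takes the one with the smallest
coefficient t-test p-value if it is below 0.05; ties break by larger |t|,
then pool order (determinism); candidates collinear with the selected set
are skipped; no removal step (a term is never dropped when later additions
degrade it). The intercept is fitted but ≈ 0 by construction since both
sides are standardized. An empty selection is a valid null model, not an
error.

Leave-one-year-out CV has two modes, both implemented because the
published setup reports CV metrics for a single printed term set without
saying whether selection was redone per fold:

* **A (default)** — the full-data term set is fixed; each fold refits only
  the coefficients. Fold predictions depend on the held-out year only
  through the original selection.
* **B** — the entire stepwise selection reruns inside each fold (fully
  leakage-free; an empty fold selection predicts 0, the anomaly mean).

Measured behaviour worth knowing (frozen as regression bounds in the test
suite): greedy forward selection at n = 26 over 27 candidates recovers all
three planted terms in only ~50–70 % of seeds at population R² ≈ 0.7 —
masked terms lose out to adjacent-month AR(1) proxies, and the per-step
min-p rule admits a noise term in most seeds (with 24 null candidates,
P(min p < 0.05) is large). This is a property of the method at this sample
size, not an implementation artifact; a pure-numpy oracle with independent
candidates reproduces it (no-miss ≈ 0.69, exact recovery ≈ 0.26).

## Forecast assembly and verification

For issue months January–June: past-month terms (season order) come from
observed anomalies; future terms come from the dynamical system at
lead = season-position difference, or from the observed anomaly of
issue−1 for persistence; the BENCHMARK system uses observations for every
term (the regression's ceiling; panels for issue months after a model's
last predictor month coincide with it). Dynamical predictors are
standardized against the corrected forecast's own per-(issue month, lead)
ensemble-mean trend/SD (so residual biases cannot leak into anomalies); a
flag switches to the observational climatology instead. Both the
ensemble-mean and the 25-member propagation through the (linear) model are
available; deterministic verification uses the mean, CRPS uses members.

Scores: FAR is the false alarm **ratio** b/(a+b) (POFD b/(b+d) is provided
separately), H = a/(a+c), HSS in the standard 2×2 form; the loss event is
anomaly **strictly** below zero. Undefined scores (zero denominators) are
NaN with an explicit reason, never silent zeros. CRPS uses the standard
ensemble estimator `mean|x−y| − ½ mean|x−x'|` (a fair n/(n−1) variant by
flag); a single member reduces it to absolute error. The RMSE percent
difference is reported in two sign conventions because the source
formulation is internally contradictory: the headline `pdiff` is
(RMSE_dyn/RMSE_per − 1)×100, negative when the dynamical system wins,
matching how the added value is described in words; the literal algebraic
alternative (1 − RMSE_dyn/RMSE_per)×100 is emitted as `pdiff_alt`. Pooled
Pdiff concatenates all issue months; per-month values are also written.

## Pipeline

Stages communicate only via CSV/JSON files in the run directory, making
each stage independently re-runnable and testable; the manifest echoes the
fully-defaulted configuration, its hash, the seed and library versions.
Reruns with the same configuration are byte-identical on every CSV. The
problem sizes used by the test suite and the acceptance script (shortened
records, thinned ensembles where the property under test is
size-independent, e.g. exact mean-matching) are deliberate: every
structural identity asserted is exact and does not depend on scale, while
sampling-based checks state their n explicitly.

## Known limitations

* Only the two CV modes above; no information criteria or regularized
  alternatives to stepwise selection.
* No quantile mapping or variance inflation in the correction; mean
  matching only.
* Contingency verification at a fixed threshold (0); no ROC/reliability
  analysis.
* Issue months outside January–June and leads beyond 6 months are out of
  scope by design.
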