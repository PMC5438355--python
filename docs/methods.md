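# Methods

`flowattrib` attributes the change in mean growing-season streamflow of a
headwater catchment between a pre-restoration era and a post-restoration
era to two drivers: climate (precipitation and atmospheric demand) and
vegetation recovery. This note records the models, the conventions and the
genuinely open design choices, and what the synthetic tests do and do not
demonstrate.

## Water balance and notation

All quantities are growing-season depths in mm per season: precipitation
`P`, potential evapotranspiration `ETp`, actual evapotranspiration `ET`,
streamflow `Q`, storage change `dS = P - ET - Q`. Overbars denote long-term
means over the full analysis record (both eras pooled); deltas are
post-era mean minus pre-era mean. The aridity index is `AI = ETp_bar /
P_bar`.

## Water yield coefficient

The WYC is the OLS slope of yearly `Q` on yearly `P` — the marginal
fraction of an extra mm of precipitation leaving as river flow. Variants:

* *partial* WYC — the coefficient on `P` in the two-regressor OLS of `Q`
  on `(P, T)`, which removes temperature-confounded covariation;
* *detrended* WYC — both series have their linear time trend removed
  (mean preserved) before the fit, so a shared secular trend cannot
  masquerade as hydrological sensitivity. Detrending is applied **within
  each analysis period**; with two short eras this is the conservative
  choice, since a single full-record trend line would leak the era shift
  itself into the "trend".

Equality of the pre and post slopes is tested with the pooled regression
`Q ~ P + era + P:era`: the interaction coefficient equals the slope
difference exactly and its two-sided t-test (pooled error variance) is the
standard equality-of-slopes test. Two-sided p-values are used throughout.

## Elasticity partition of the streamflow change

The total change is split as `dQ_tot = dQ_clim + dQ_veg` with the
first-order expansion

    dQ_clim = (eps_P * dP / P_bar + eps_ETp * dETp / ETp_bar) * Q_bar,
    eps_P + eps_ETp = 1,

and `dQ_veg` the residual. The precipitation elasticity comes from a
Budyko-type evaporative-fraction curve `f(AI)`:

* **standard** convention: `eps_P = 1 + AI f'(AI) / (1 - f(AI))`. This is
  what differentiating `Q = P (1 - f(ETp/P))` with respect to `P` yields.
* **as_printed** convention: `eps_P = 1 + AI f'(AI) / (1 - f'(AI))`. This
  variant circulates in parts of the applied literature; for the Schreiber
  curve the two coincide (`f' = 1 - f` there), which is probably why the
  discrepancy goes unnoticed.

Both are implemented behind `PipelineConfig.convention`; the package
default is `as_printed` for continuity with that literature, but the
recovery tests run the `standard` convention because it is the one
consistent with the water balance the synthetic generator obeys — under
`as_printed`, non-Schreiber forms systematically understate `eps_P` (about
1.4 versus 2.4 at `AI ~ 1.3`) and the partition degrades accordingly. Users
analysing real catchments should prefer `standard` unless matching a
specific published chain.

Six classical curves ship in the registry (Schreiber, Ol'dekop, Budyko,
Turc–Pike, Fu with shape `w = 2.6`, Zhang); the ensemble summary is the
unweighted mean ± sample s.d. across forms, a structural-uncertainty band,
not a sampling error. The registry is a plain dict and user-replaceable.
`dQ_veg` and `dQ_clim` share one ensemble s.d. since they differ from
`dQ_tot` by a sign and a constant.

## Budyko decomposition of the ET change

The generalized one-parameter curve

    ET = P [1 + (ETp/P)^(-omega)]^(-1/omega)

is evaluated in log space (exact up to rounding even for omega ~ 1e4,
where ET tends to min(P, ETp)). The catchment parameter omega is
calibrated on the pre era by least squares on yearly ET with Nelder-Mead
from omega0 = 2.0, searching (0.1, 20) through a logistic
reparameterization; a fit pushed to a bound (e.g. observed ET exceeding
min(P, ETp), unreachable by the curve) is flagged non-converged.
Uncertainty comes from refitting on without-replacement subsamples of the
calibration years (default 5000 draws of 12; "random selection of k from n
years" reads as subsampling, not resampling with replacement); the
bootstrap mean is the value carried forward.

Holding omega at its pre-era value, the post-era prediction is the ET the
*unrestored* catchment would have produced under the new climate. Then

    dET_veg  = mean(ET_obs, post) - mean(Budyko ET, post; omega_pre),
    dET_clim = dET_tot - dET_veg           (additive by construction).

The counterfactual uses the mean of yearly predictions rather than the
prediction at mean climate (default `yearly_budyko=True`): it uses all
years and avoids the Jensen gap of a concave curve; the period-mean
variant remains available.

## Recycling feedback

Extra vegetation-driven ET partly returns as local precipitation at the
regional evaporation recycling ratio `eps_r` (an external input from a
moisture-tracking analysis, default 0.152; computing it is out of scope),
and thence to streamflow at the observed runoff ratio `Q/P` of the post
era: `dP_recycled = eps_r * dET_veg`, `dQ_recycled = runoff_ratio *
dP_recycled`. The chain is deliberately linear and diagnostic; no
atmospheric-dynamics feedback is modelled.

## Grazing-exclusion summaries

Paired fencing/grazing site tables yield percent treatment effects,
`100 (fenced - grazed)/grazed`, per site and variable, and layered
soil-water storage `sum(thickness_mm * content)`. Contents are volumetric
by default; because field protocols that weigh oven-dried cores produce
gravimetric contents, a gravimetric variant (`content * bulk_density *
thickness`) is available behind a flag. Published site tables typically
carry no replicate-level dispersion, so the report is descriptive — no
inferential statistics are attempted.

## Synthetic generator

`GeneratorParams` defaults define the study conditions: 18 + 13 years, a
+73.5 mm precipitation shift, a +5 mm demand shift, omega 2.0 -> 2.6 and 2%
multiplicative ET noise. Climate levels not fixed by that setting were
chosen once as realistic for a semi-arid alpine headwater — `P ~ 265 mm`,
`ETp ~ 370 mm` per season with interannual s.d. 40 and 20 mm, storage noise
5 mm — giving a post-era runoff ratio near 0.20 and mean streamflow near
55–60 mm. Temperature is an affine function of ETp plus noise; it exists
only to exercise the partial regression and feeds nothing back into ET.
Draws are truncated (P, ETp at 1 mm) or clipped (ET into (0, min(P,
ETp)), Q at 0) defensively; clip events are counted and are absent at the
defaults.

What the generator does **not** emulate: serial correlation and regime
persistence, covariance between P and ETp, non-Gaussian precipitation
tails, gradual (rather than step) vegetation change, permafrost or glacier
storage trends, and measurement error in Q. Passing recovery tests
therefore show the estimators are consistent with their own assumptions at
realistic noise, not that those assumptions hold for any particular real
catchment.

## Numerical and testing choices

* Budyko curve via `log-sum-exp`; elasticity denominators within 1e-12 of
  zero raise rather than return infinities.
* Nelder-Mead termination at `xatol = 1e-10` on the transformed parameter
  (~2e-10 in omega mid-range); the grid-search oracle used in tests is a
  two-stage (1e-2 then 1e-5) search, independent of the optimizer.
* Regression fits go through statsmodels OLS with an explicit rank check,
  so degenerate designs raise `SingularDesignError` instead of silently
  returning a reduced model.
* Recovery checks use 60–100 independent seeds and median relative errors:
  omega to within 5% at 2% ET noise, vegetation-driven ET exactly
  (noise-free) and the ensemble `dQ_veg` to within ~30% — the latter
  tolerance is dominated by the first-order elasticity approximation
  itself, not by estimation noise.
* CSV round-trips are exact (`%.17g` on write, `round_trip` float parsing
  on read); JSON reports embed the full configuration and seed.

## Known limitations

The elasticity partition is first-order in era-mean changes; for large
climate shifts the curvature of `f` biases `dQ_clim` low (visible in the
synthetic recovery as a median ~15–20% shortfall of `|dQ_veg|`). The
Budyko omega conflates every non-climate control (seasonality, snow,
storage carryover) into one parameter, so "vegetation" components are
really "catchment-characteristics" components. One omega per record is
assumed; drifting omega within an era violates the counterfactual.
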