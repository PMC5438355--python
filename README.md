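# flowattrib

Attribution of growing-season streamflow change in headwater catchments to
**climate** versus **vegetation restoration**, built around the Budyko
water–energy framework and streamflow elasticity.

Large grassland-restoration programs (grazing exclusion, reseeding) change
how much water a catchment evaporates, and therefore how much reaches the
river — but restoration decades also see climate change, so the observed
streamflow trend mixes both signals. `flowattrib` implements the standard
separation used in catchment ecohydrology:

* **Water yield coefficient (WYC)** — the OLS slope of yearly streamflow
  `Q` on precipitation `P` (simple, temperature-adjusted partial, and
  detrended variants), with an interaction-term test for a slope change
  between a pre- and post-restoration era.
* **Elasticity partition** — `dQ_tot = dQ_clim + dQ_veg` with
  `dQ_clim = (eps_P dP/P̄ + eps_ETp dETp/ETp̄) Q̄`, `eps_P + eps_ETp = 1`,
  and `eps_P = 1 + AI f'(AI)/(1 − f(AI))` from a Budyko-type curve at the
  aridity index `AI = ETp̄/P̄`; an ensemble of six classical `f(AI)` forms
  (Schreiber, Ol'dekop, Budyko, Turc–Pike, Fu, Zhang) gives a mean ± sd
  band. (An alternative denominator convention `1 − f'(AI)` is available;
  see `docs/methods.md`.)
* **Budyko ET decomposition** — `ET = P[1 + (ETp/P)^(−ω)]^(−1/ω)`; the
  catchment parameter ω is calibrated on the pre era (Nelder-Mead least
  squares, bootstrap over 12-year subsamples) and held fixed to predict
  post-era ET under climate alone: `dET_veg = ET_obs,post − ET_Budyko,post`,
  `dET_clim = dET_tot − dET_veg`.
* **Water-balance residuals** `dS = P − ET − Q`, and a **moisture-recycling
  feedback**: `dP_recycled = eps_r · dET_veg`, `dQ_recycled = runoff_ratio ·
  dP_recycled`.
* **Grazing-exclusion summaries** — percent fencing effects and layered
  soil-water storage for paired fencing/grazing site tables.
* A **synthetic two-era catchment generator** with Budyko-consistent ET, a
  closed water balance and known ground truth (`omega_pre`, `omega_post`,
  true vegetation-driven streamflow change) for end-to-end recovery tests.

It is a library, used from Python; `examples/` holds one short script per
capability.

## Worked example

```bash
python examples/attribution_example.py
```

generates the default synthetic catchment (18 pre + 13 post years, +73.5 mm
precipitation shift, ω 2.0 → 2.6, 2% ET noise) and runs the full pipeline:

```
dQ_tot  = +12.46 mm (observed post - pre)
dQ_clim = +28.83 +/- 1.39 mm (elasticity ensemble of 6 forms)
dQ_veg  = -16.37 +/- 1.39 mm (generator truth -19.94)
dET_veg = +21.30 mm; omega used = 1.980
recycling feedback: dP = +3.238 mm, dQ = +0.644 mm
full report written to attribution_report.json
```

Reading: streamflow rose 12.5 mm between eras, but that is the net of a
~29 mm climate-driven gain (wetter post era) and a ~16 mm loss because the
restored grassland evaporates more; the ensemble recovers the generator's
true vegetation signal (−19.9 mm) in sign and magnitude. The extra ET
returns only ~0.6 mm to the river via local moisture recycling — far too
little to offset the loss. `examples/grazing_example.py` shows the other
side of the ledger: fencing raises biomass (+30.5% steppe, +70.5% meadow)
and soil-water retention, so restoration trades downstream yield for local
soil-water storage.

Typical catchment analysis on real data:

```python
import flowattrib as fa

series = fa.read_catchment_table("catchment.csv")   # year,P,T,ETp,ET,Q
config = fa.PipelineConfig(
    periods=fa.PeriodDefinition(1982, 1999, 2000, 2012),
    convention="standard", n_draws=5000, subsample_size=12,
    seed=1, eps_r=0.152,
)
report = fa.attribute(series, config=config)
fa.write_report(report.to_dict(), "report.json")
```

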