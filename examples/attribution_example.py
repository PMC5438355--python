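"""Run the full attribution pipeline and write a structured JSON report.

Streamflow change is partitioned per elasticity form (six Budyko-type
curves), the ET change decomposed through the calibrated Budyko curve, and
the vegetation-driven ET gain translated into a recycled-precipitation
streamflow feedback.
"""

from flowattrib import (
    GeneratorParams,
    PipelineConfig,
    attribute,
    generate_catchment,
    write_report,
)

series, truth = generate_catchment(GeneratorParams(seed=1))
config = PipelineConfig(convention="standard", n_draws=1000, seed=1, eps_r=0.152)
report = attribute(series, config=config)

print(f"dQ_tot  = {report.dQ_tot:+.2f} mm (observed post - pre)")
print(
    f"dQ_clim = {report.dQ_clim_mean:+.2f} +/- {report.dQ_clim_sd:.2f} mm "
    f"(elasticity ensemble of {len(report.per_form)} forms)"
)
print(
    f"dQ_veg  = {report.dQ_veg_mean:+.2f} +/- {report.dQ_veg_sd:.2f} mm "
    f"(generator truth {truth.true_dQ_veg:+.2f})"
)
print(f"dET_veg = {report.dET_veg:+.2f} mm; omega used = {report.budyko_fit['omega_used']:.3f}")
print(
    "recycling feedback: dP = {dP_recycled:+.3f} mm, dQ = {dQ_recycled:+.3f} mm".format(
        **report.recycling
    )
)
write_report(report.to_dict(), "attribution_report.json")
print("full report written to attribution_report.json")
# dQ_veg is the restoration signal: negative because the recovered grassland
# evaporates more, partly offsetting the climate-driven streamflow gain.
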