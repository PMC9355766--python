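"""Run the whole pipeline: simulate, measure, aggregate, regress on age.

A small noiseless cohort is generated with ground truth exactly on the
published regression lines, then every region is measured (INAG, width,
SD, rho) and each specimen-mean metric regressed against age.  The
recovered slopes should match the configured lines.
"""

from dentinemp import CohortConfig, RunConfig, relative_change, run_pipeline

cohort = CohortConfig(ages_years=(20.0, 35.0, 50.0, 65.0, 80.0),
                      regions_per_specimen=2, n_px=256, field_um=90.0,
                      residual_sds={"width": 0.0, "inag": 0.0, "rho": 0.0},
                      photon_gain=0.0, read_noise_sd=0.0, jitter_deg=2.0)
result = run_pipeline(RunConfig(cohort=cohort, output_dir="scratch_pipeline",
                                seed=1))

print("metric        slope      intercept   R        p")
for name, reg in result.regressions.items():
    print(f"{name:12s} {reg.slope:+9.5f}  {reg.intercept:+9.4f}  "
          f"{reg.pearson_r:+.4f}  {reg.p_value:.2e}")

inag_chg = relative_change(result.regressions["inag"], 20, 80)
print()
print(f"INAG magnitude change, age 20 -> 80: {inag_chg['percent']:.1f}%")
print()
print("Configured truth: width 0.03*age+3.47, INAG -0.003*age-0.25,")
print("rho -0.02*age-1.03.  The fitted slopes recover these lines; the INAG")
print("line implies the index magnitude is ~58% larger at 80 than at 20.")
print("Full outputs (regions.csv, specimens.csv, report.json) are in")
print("scratch_pipeline/.")
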