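# Calibrated generator set-points (see alcsofa.synthetic.GeneratorParams).
# At large n these give ~21.3% 28-day mortality and a lymphocyte count with
# mean ~1.07 and SD ~0.68 x10^9/L, lower in nonsurvivors.
beta_severity: 0.15
beta_immune: 0.25
baseline_hazard: 0.00313
alc_logmean: -0.1021
alc_logsd: 0.3702
immune_alc_loading: 0.45
severity_immune_corr: 0.2
censor_day: 90.0
missing_rates: {}
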