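# Demo pipeline run: study-emulation simulation at full cohort size,
# a small candidate model set, and the default fixed terminal detection
# probability with its sensitivity bounds.
seed: 1
out_dir: scratch/demo-run
simulation:
  n_scale: 1.0
models:
  - "phi ~ segment * SkokH + rd; p ~ segment + RM:line; fix p[JDF]=0.685"
  - "phi ~ segment * SkokH + rd; p ~ segment + RM:line + rd; fix p[JDF]=0.685"
  - "phi ~ segment * reartype + rd; p ~ segment + RM:line; fix p[JDF]=0.685"
  - "phi ~ segment * SkokH + year + rd; p ~ segment + RM:line; fix p[JDF]=0.685"
  - "phi ~ segment; p ~ segment; fix p[JDF]=0.685"
mortality_model: "phi ~ segment * population + year; p ~ segment + RM:line; fix p[JDF]=0.685"
fixed_p_terminal: 0.685
sensitivity_bounds: [0.428, 0.863]
log_level: INFO
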