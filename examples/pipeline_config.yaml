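# Full-pipeline configuration: the master seed fans out to the cohort,
# microsimulation and bootstrap substreams.  Any omitted field keeps the
# package default (the study conditions for the cohort block, illustrative
# values for the microsimulation block).
seed: 20230901

cohort: {}          # study defaults: n=148, 92/56 arms, GMFCS 24/35/29/21/39

microsim:
  n_individuals: 20000     # 100000 reproduces the full-size run
  horizon_cycles: 30
  discount_rate: 0.03
  baseline: from_cohort    # GMFCS mix of the generated cohort

psa:
  wtp_max: 100000
  wtp_step: 1000
  ellipse_levels: [0.50, 0.75, 0.95]
  plots: false
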