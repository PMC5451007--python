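# Demo configuration: three synthetic populations ("early" and "late"
# seasonal flights plus an allopatric sample) through both analysis arms.
seed: 2025
outdir: flightdiff_out

genetic:
  synthetic:
    loci: 300
    populations: [early, late, allopatric]
    F: 0.08
    n_per_pop: 10
  mcmc: {err: 0.005, steps: 2000, burnin: 500, thin: 5}
  admixture: {k_min: 1, k_max: 4, replicates: 3, steps: 800, burnin: 400}
  # paper_scale: true   # switches to 100,000/10,000 and 100,000/50,000 chains

morpho:
  synthetic:
    groups: {early: 15, late: 15, allopatric: 15}
    effect_norm: 0.04
    noise_sd: 0.008
  permutations: 999

melanization:
  synthetic:
    groups: {early: 20, late: 20, allopatric: 20}
    group_offsets: {late: -4.0, allopatric: -2.0}
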