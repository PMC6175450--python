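# Demo configuration: a small synthetic cohort analysed end to end.
# All keys are fields of homeodiv.pipeline.RunConfig; CLI flags override.
seed: 1
outdir: demo_run
tissues: [apex, leaf]
n_per_pattern: 5        # families per divergence pattern, per tissue
noise_sd: 0.2           # per-observation FPKM noise (also the uncertainty column)
expression_threshold: 2.0
M: 5                    # ensemble maps (scaled down from the default 100)
B: 100                  # resampling draws per gene per map (default 500)
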