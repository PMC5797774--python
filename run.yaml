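# Example pipeline configuration for `lfpdyn run --config run.yaml`.
# Omitted keys keep their defaults; CLI flags override file values.

n_trials: 100          # per condition (synthetic presets when no paths given)
speedup: 3.0           # treated-condition time-scale factor
discard: 0.5           # seconds of stimulus transient to drop

n_surrogates: 100
significance: 0.05
statistic: timerev     # or: fnn
n_nonlinearity_trials: 20

reference_policy: first
linkage: single
ks: [6, 12]

lag_method: autocorr
f: 10.0
theiler: 500
fnn_threshold: 1.0
d_max: 6
n_embed_trials: 10

frechet_downsample: 25
n_frechet_trials: 10

seed: 1
outdir: results/pipeline_run
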