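# gluim

Analysis toolkit for fluorescence glutamate-indicator imaging experiments,
with a synthetic-data generator that emulates the imaging physics so every
stage can be validated by parameter recovery — no real recordings needed.

## What's inside

| module | purpose |
| --- | --- |
| `gluim.synthgen` | synthetic movies (Poisson shot noise, Gaussian point-source footprints, rise/decay indicator kernel, bleaching), release trains, grating sessions, 5-Hz sparse-noise stimuli, photometry traces, mutagenesis screens — all with embedded ground truth |
| `gluim.kinetics` | ΔF/F (10,001-frame moving-median or baseline-mean F₀), spike-triggered averages with 500-ms isolation, nonlinear rise/decay transient fits, windowed autocorrelation decay estimation with robust log-linear fits, branch-level minimum decay, modified z-score event detection |
| `gluim.minis` | pixelwise activity statistic (highpass skewness in shot-noise units; expectation 1 for Poisson data), seeded nonnegative-factorization site detection, per-site SNR (third-largest peak over spectral noise) and peak-triggered decay, well/variant aggregation |
| `gluim.tuning` | time-resolved and eight-point tuning curves, vector-sum preferred orientation and OSI (normalized and raw variants), HSV tuning maps, cross-validated pixel-pair covariance with 1/e and 1/e² spread distances and bootstrap CIs |
| `gluim.strf` | spatiotemporal receptive fields from sparse noise: lagged ON/OFF Toeplitz design (0–1.4 s), spatial-Laplacian ridge regression, 3-fold CV λ selection, explained variance, 1,000-shift circular permutation test, responsiveness (EV > 0.1 and p < 0.005), 2D-Gaussian subfield fits |
| `gluim.mutglm` | categorical GLM over 9 mutation sites (1,728 genotypes; Poisson/log for F₀ and ΔF/F₀, Gaussian/log for T_on/T_off), pairwise epistatic interactions, case-resampling bootstrap CIs, genotype-stratified CV variance explained, interaction-vs-structural-distance correlation |
| `gluim.photometry` | Gaussian low-cut detrending with 4th-order polynomial bleach correction, peri-event time histograms with 2-s pre-event baselines |
| `gluim.cli` | `gluim` command: simulate/analyze stages, YAML configs, fixtures, markdown reports |

## CLI

```sh
# simulate a spontaneous-release movie, then detect and score sites
gluim simulate minis --out runs/sim --seed 1
gluim analyze minis --out runs/ana -i movie=runs/sim

# other stages
gluim simulate tuned|sparse-noise|photometry|screen --out DIR --seed N [-p key=value]
gluim analyze kinetics|tuning|strf|glm|photometry --out DIR -i key=path [-p key=value]

# config-driven runs, fixtures, reports
gluim run --config stage.yaml
gluim make-fixtures --out fixtures --seed 0
gluim report --summary runs/ana/summary.json --out report.md
```

Each stage writes its artifacts plus a `summary.json` (seed, parameters, key
metrics, versions); reruns with the same seed are byte-identical.

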