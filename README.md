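# decispeed

Reusable pipeline linking single-trial EEG decision signals — the
centroparietal build-to-threshold positivity (CPP), the contralateral N2c,
and left-hemisphere beta (LHB) desynchronization — to response speed,
lifetime environmental enrichment, and trial-count reliability, with a
G²-fitted one-boundary drift-diffusion model of the same behavior. Because
the motivating dataset cannot be shared, the package ships a first-class
synthetic cohort generator that plants every quantity the analysis
extracts, so the whole chain is testable end to end offline.

## Modules

| Module | What it does |
| --- | --- |
| `decispeed.synthetic_cohort` | Draws subject parameters (diffusion a/v/t0, planted CPP/N2c/LHB shapes, enrichment scores), simulates behavior from the shifted-Wald first-passage law (or Euler–Maruyama in oracle mode), and synthesizes epochs with the planted components plus white/pink noise. Subject mean RT follows the moderation equation `RT = i1 + b1·slope + b2·EE + b3·slope·EE + ε`. |
| `decispeed.preprocess` | Hamming windowed-sinc FIR chain (detrend → 50/100/150 Hz notch → 0.1 Hz high-pass → 35 Hz low-pass, zero-phase), epoching (−200..1500 ms, baseline −100..0 ms), response-locked re-slicing, trial exclusion (RT ≤ 150 ms, ≥ 1800 ms, \|amplitude\| > 100 µV in [−100, RT+100] ms), 3×IQR outlier flags. |
| `decispeed.erp_metrics` | N2c waveform contralateral at P7/P8, latency (most negative 150–400 ms), amplitude (100 ms window on the grand-average peak); CPP onset via running 25 ms-window t tests (90 consecutive significant samples), build-up rate (OLS −150..+50 ms response-locked), amplitude (±50 ms). |
| `decispeed.lhb_metrics` | Temporal spectral evolution: 20–35 Hz band-pass → rectify → trim 200 ms → 100 ms moving average at 50 ms steps; latency (argmin 0–1000 ms at C3), slope (−300..−50 ms), amplitude (±50 ms around response). |
| `decispeed.ddm_gsquare` | Shifted-Wald pdf/cdf, RT quantile bins ({0.1,0.3,0.5,0.7,0.9} plus miss bin), `G² = 2ΣO·ln(O/E)`, modified-Powell multi-start fit, and both samplers. |
| `decispeed.cohort_stats` | Hierarchical regression with R²-change F tests, raw-scale moderation with conditional effects at moderator mean ± SD, percentile-bootstrap mediation, one-way ANOVA with partial η², JZS Bayes-factor t tests (Cauchy scale 0.707), leisure life-percentage formula. |
| `decispeed.trial_reliability` | Trial-subsampling analysis (bins 20–120 from a 129-trial pool, SNR = mean/SD over permutations, cross-subject r per permutation, BF vs a −0.55 threshold), adjacent-bin KS tests, the task-time budget calculator, and trial-type enumeration. |
| `decispeed.pipeline` / `decispeed.cli` | YAML-configured stage graph (`simulate → preprocess → metrics → ddm → stats`) over TSV/HDF5/JSON artifacts, deterministic under fixed seeds, with every output carrying the config hash. |

## CLI

```bash
# synthetic cohort -> HDF5 epochs + TSV tables
decispeed simulate --out runs/demo --seed 1 --n-older 12 --n-younger 12 --trials 120 --noise-sd 2

# individual stages (operate on the run directory)
decispeed preprocess --out runs/demo
decispeed metrics --out runs/demo
decispeed ddm --out runs/demo
decispeed stats --out runs/demo --seed 1

# or everything from a YAML config
decispeed run --config config.yaml

# reliability tools
decispeed reliability subsample --run-dir runs/demo --perms 1000 --seed 1 --out snr.tsv
decispeed reliability task-time --accuracy 0.71 --reject 0.44
```

A minimal `config.yaml`:

```yaml
stages: [simulate, preprocess, metrics, ddm, stats]
out_dir: runs/demo
bootstrap_seed: 1
cohort:
  n_older: 12
  n_younger: 12
  trials_per_subject: 120
  noise_sd: 2.0
  seed: 1
```

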