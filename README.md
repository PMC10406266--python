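# mreeg

EEG recorded during fMRI is buried under three families of MR-induced
artifacts: the gradient (imaging) artifact — a TR-periodic comb reaching
tens of millivolts, three orders of magnitude above the physiology — the
heartbeat-locked ballistocardiogram (BCG, > 50 µV with power below 25 Hz,
squarely overlapping the alpha band), and helium-pump vibration harmonics
(≥ 30 Hz). `mreeg` is a toolkit for evaluating how well the standard
correction toolchain recovers neural signal from under those artifacts,
aimed at methods researchers and EEG–fMRI practitioners choosing a
correction pipeline.

It provides, as importable library modules plus a thin `mreeg` command:

* **a synthetic EEG–fMRI session generator** with exact ground truth:
  scalp channels, six carbon-wire loops (CWL), ECG, TR and task markers;
  the assembled recording decomposes bitwise into
  `neural + imaging + BCG + pump + motion + noise`;
* **the correction algorithms** as evaluated in practice: average artifact
  subtraction (AAS, 25-window sliding template on volume markers for
  imaging artifacts; 21 windows on R-peaks for BCG), the optimal basis set
  (OBS, per-channel epoch mean + 3 principal components fitted per beat),
  and CWL regression (per 4-s Hann window, least squares on the six loops
  and their ±21 ms lagged copies), plus R-peak detection, composed into
  the variants NC / IAR / AAS / OBS / CWL;
* **feature extraction**: Welch band power (2¹²-sample Hamming segments)
  with dB-domain summary-channel averaging and z-score channel selection,
  VEP contra/ipsilateral difference waves, sliding-RMS evoked SNR, RMSD;
* **hierarchical Bayesian comparison**: a two-level varying-intercept /
  varying-slope normal regression,

  y_i ~ Normal(x_i · β_participant(i), σ_method(i)),
  β_j ~ MultiNormal(β, Σ), Σ = diag(τ) Ω diag(τ),

  with Normal(0, 10) priors on coefficients, half-Cauchy(2.5) on SDs and
  LKJ(2) on Ω, sampled by a built-in No-U-Turn sampler in non-centered
  form; an effect-size variant with partially pooled per-participant ×
  method residual SDs; single-level regression; and a robust (bivariate
  Student-t) correlation model. Convergence is checked with rank-normalized
  split R̂, bulk/tail ESS and MCSE.

`docs/methods.md` describes the models, defaults and numerical choices.

## Worked example

Simulate one resting-state session, correct it with each variant, and
measure the RMS error against the known clean signal:

```python
import numpy as np
from mreeg import SessionConfig, assemble_session, run_variant

cfg = SessionConfig(fs_hz=250.0, duration_s=44.0, task="resting", seed=7,
                    n_scalp=8, neural={"block_s": 10.0, "n_blocks": 4})
rec, markers, gt = assemble_session(cfg)

clean = gt.neural[:8]
trim = slice(int(3 * rec.fs), int(41 * rec.fs))
for variant in ("NC", "IAR", "AAS", "OBS", "CWL"):
    out = run_variant(rec, markers, variant, rpeaks=gt.rpeak_samples)
    err = np.sqrt(np.mean((out.data[:8, trim] - clean[:, trim]) ** 2))
    print(f"{variant:>3}: RMS error {err:8.2f} uV")
```

```
 NC: RMS error  2079.09 uV
IAR: RMS error    53.41 uV
AAS: RMS error    14.14 uV
OBS: RMS error     9.27 uV
CWL: RMS error     1.97 uV
```

Uncorrected data are dominated by the ~20 mV imaging artifact; removing it
(IAR) leaves the ~250 µV BCG; the beat-template methods remove most of
that (OBS slightly ahead of AAS here); CWL regression, which also absorbs
the pump artifact captured by the loops, approaches the 1.5 µV sensor-noise
floor of the clean reference.

A full simulated study — a cohort of participants, all six data variants,
feature extraction and the hierarchical model — runs from the shell:

```sh
mreeg run-all --seed 1 --participants 8 --tasks resting --out study/
mreeg report --report study/report.json
```

The report contains, per variant, the posterior median and 66 %/95 %
intervals of the eyes-closed minus eyes-open alpha-band ΔPSD, the
probability that each method outperforms its neighbour, convergence
diagnostics, and ground-truth RMS errors. On default settings the
recovered ordering reproduces the expected pattern: REF > CWL >
{AAS, OBS} > IAR > NC, with a decisive P(ΔPSD > 0) only for the
BCG-corrected variants.

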