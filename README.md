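# earoddball

Analysis pipeline for studying **auditory attention across a workday with
around-the-ear EEG** (cEEGrid), built around a dual-variant auditory oddball:
a classical *rapid* block (160 double tones in ~5 minutes, ~9 targets/min)
and a *sporadic* block that spreads the same 160 trials over ~160 minutes
(one target per ~3.3 min) so the task runs in the background of normal
office work.  Rare target tones elicit the P3, a positive event-related
potential (ERP) ~250–500 ms post-stimulus that indexes target detection;
comparing reaction times, miss rates and P3 amplitudes between variants
quantifies how attention is shared with everyday activities.

The package is aimed at mobile-EEG researchers who need the full chain —
paradigm generation, artifact-robust cleaning of long noisy recordings, P3
scoring, gyroscope-based movement quantification, and mixed-model
inference — as tested, scriptable Python.  Because no day-long ear-EEG
datasets are public, the package includes a first-class synthetic-session
generator (EEG + gyroscope + events + behavior, with ground-truth artifact
logs) whose defaults are the published fitted estimates, so every stage is
verifiable end to end.

## Models

Behavior is modeled with generalized linear mixed models over oddball
variant x ∈ {0 = rapid, 1 = sporadic}, with by-participant random
intercepts and slopes:

* reaction time: inverse-Gaussian family, inverse link —
  η = β₀ + β₁x + b₀ᵢ + b₁ᵢx, RT ~ IG(μ = 1/η, λ);
* accuracy: binomial family, logit link — P(miss) = logit⁻¹(η);
* P3 amplitude (per condition, role r ∈ {standard, target}): Gaussian LMM
  with *independent* random intercepts and slopes.

Fits are Laplace-approximate maximum likelihood (exact for the Gaussian and
inverse-Gaussian/inverse cases); effects are tested with Wald χ² tests,
competing family/link choices compared by likelihood ratio, and block-level
movement by repeated-measures ANOVA with generalized eta squared (η²G).

Signal processing: zero-phase Hamming windowed-sinc FIR filters (10 Hz
low-pass order 330, 0.1 Hz high-pass order 8250), 60-s flatline rejection,
artifact subspace reconstruction (ASR, burst criterion 20) calibrated on
each block's one-minute still segment, ±500 µV amplitude and 2-SD spectral
channel rejection, spherical-spline interpolation, epochs −0.2–0.8 s with
−200–0 ms baseline, joint-probability epoch rejection (2 SDs), and the
vertical bipolar derivation (R2+R3)/2 − (R6+R7)/2.  Movement: per-sample
displacement √(yaw²+pitch²+roll²), movement-free threshold = median +
4·IQR over rapid blocks, SD-binned day time course with a 10-s moving
median.

## Worked example

Simulate a session, fit the models, and check parameter recovery:

```bash
python analysis/01_simulate_session.py     # 8 participants, 5 blocks -> scratch/session
python analysis/02_preprocess.py           # cleaning + channel reports
python analysis/03_erp_analysis.py         # epochs, windows, P3 amplitudes
python analysis/04_movement.py             # full-length gyroscope analysis
python analysis/05_stats.py                # mixed models + ANOVA
python analysis/06_parameter_recovery.py   # simulate-refit table
```

`06_parameter_recovery.py` prints (30 replicates, 8 participants each):

```
                     quantity  truth  recovered  mc_se
            rapid mean RT (s)  1.099      1.107  0.006
              RT increase (s)  0.824      0.844  0.020
        rapid miss chance (%)  3.520      3.803  0.167
           miss increase (pp)  6.900      6.936  0.356
       rapid standard P3 (uV)  1.070      1.080  0.015
   rapid target increase (uV)  1.750      1.748  0.017
    sporadic standard P3 (uV)  1.630      1.631  0.021
sporadic target increase (uV)  1.200      1.188  0.020
```

Each row simulates the named model at its generative truth (the published
link-scale estimates), refits it with this package's estimator, and
reports the replicate mean ± Monte-Carlo SE: every fixed effect is
recovered within sampling error.  `03_erp_analysis.py` reports the
data-driven extraction windows (e.g. rapid peak 316 ms → window
216–416 ms against a generative peak of 312 ms) and `05_stats.py` ranks
the reaction-time family/link candidates, with inverse-Gaussian/inverse
at the top of the likelihood ordering.

The same stages are available as a CLI (`earoddball simulate|preprocess|
erp|movement|stats|all --out DIR --seed N`).

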