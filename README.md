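# emovmd

Frequency-domain analysis of EEG for visual-stimulus evoked emotion
classification (happy / sad / fear).  The package implements the full
chain as a tested, reusable library plus CLI:

1. **Synthetic session generation** — labeled 32-channel, 128 Hz recordings
   following a relax/image-block stimulus paradigm, built from AM-FM
   oscillations u_k(t) = A_k(t) cos(φ_k(t)) on 1/f background noise with
   drift and frontal blink artifacts, and a ground-truth record of
   everything injected.
2. **Preprocessing** — zero-phase FIR bandpass (0.5–45 Hz), Savitzky–Golay
   trend subtraction (frame 127, order 5), and ICA-based ocular artifact
   removal with an automated frontal-correlation criterion.
3. **Variational mode decomposition (VMD)** — a from-scratch ADMM solver
   that splits each signal into K = 5 intrinsic mode functions by
   minimizing total mode bandwidth subject to Σ_k u_k = f, via spectral
   Wiener-filter mode updates and spectral-centroid center-frequency
   updates.
4. **Band-power features** — sliding windows (default 3 s, 50 % overlap);
   per window and channel, each mode's power in the Delta/Theta/Alpha/
   Beta/Gamma bands, averaged across channels into 25 features with exact
   Parseval normalization.
5. **Evaluation** — KNN/SVM/DT/RF classifiers, stratified 80/20 split with
   6-fold cross-validation, window-length sweep, per-IMF/per-band ablation
   table, and per-class feature attribution (tree-path or permutation).

It is aimed at researchers who want a verifiable reference implementation
of this analysis style: every stage is exercised against synthetic ground
truth, from filter attenuation up to recovery of the planted
discriminative (IMF, band) feature.

## Worked example

```python
from emovmd import (
    ParadigmSpec, generate_recording, bandpass_zero_phase, sg_detrend,
    ica_remove_ocular, extract_features, train_eval, ModelSpec, SplitSpec, CVSpec,
)

recording, truth = generate_recording(ParadigmSpec(), seed=1)
cleaned = sg_detrend(bandpass_zero_phase(recording))
cleaned, ica_report = ica_remove_ocular(cleaned, seed=3)
features = extract_features(cleaned)          # 3 s windows, 50 % overlap
report = train_eval(features, ModelSpec(kind="RF", seed=5),
                    SplitSpec(seed=5), CVSpec(seed=5))
print(ica_report.removed)            # [29]     <- the blink component
print(features.shape)                # (50, 30) <- 50 windows x 25 features + metadata
print(report.validation_accuracy)    # 0.9761904761904763
print(report.test_accuracy)          # 1.0
print(truth.discriminative_column()) # 'IMF1_Delta'
```

The default two-phase session (130 s) yields 50 single-emotion windows;
ICA finds exactly one component correlated with the frontal channels (the
injected blink source), and the random forest separates the three classes
almost perfectly because the generator plants a class-dependent 2 Hz Delta
component whose band power is the known-best feature.

The same pipeline is scriptable from the shell:

```bash
emovmd run-all --seed 1 --out run1          # simulate ... explain, with manifest
emovmd simulate --seed 1 --out data --format edf
emovmd decompose --in signal.csv --fs 128 --k 5 --out modes.csv
```

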