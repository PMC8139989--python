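# dircuff

Directionally specific electroneurography (ENG) from a four-contact nerve
cuff: simulation, tetrapolar reconstruction, spike extraction,
afferent/efferent classification, and airway-obstruction response analysis.

## The problem

A cuff electrode around a peripheral nerve (here, the vagus in a rodent
model of upper-airway obstruction) records a few-µV mixture of sensory
(afferent) traffic travelling toward the brain and motor/autonomic
(efferent) traffic travelling away from it. Telling the two apart from a
single cuff would give closed-loop neuromodulation systems a directional
control signal. With four contacts spaced 2.5 mm apart, two tripolar
derivations are subtracted to form the **tetrapolar** signal

    Tetrapolar = [V2 − (V3+V1)/2] − [V3 − (V2+V4)/2]
               = −½(V1−V4) − 3/2(V3−V2),

whose weights sum to zero (common-mode rejection) and are antisymmetric
under contact reversal — so a spike propagating in one direction produces
the exact negative of its opposite-direction waveform. That polarity cue,
plus waveform shape, is what a classifier can learn.

The package provides, as tested library code:

* `dircuff.synth` — a generative simulator: direction-dependent action
  potential propagation past the four contacts, respiration-gated afferent
  and tonic efferent Poisson firing, obstruction-epoch suppression, SNR-
  calibrated Gaussian noise (`SNR = 20·log10[Vpp(signal)/Vpp(noise)]`),
  ECG/EMG/movement artifacts, ECG/BP/genioglossus-EMG channels, and a
  ground-truth manifest for parameter-recovery testing.
* `dircuff.construct` — bipolar/tripolar/tetrapolar algebra, the
  respiratory nerve profile (RnP: band-pass 250 Hz–10 kHz → square → 2-Hz
  low-pass), and the peak-to-peak SNR.
* `dircuff.pipeline` — 700-µV artifact blanking, 8th-order Butterworth
  band-pass, mean ± 3σ noise thresholding against a signal-free reference,
  peak detection, 41-sample (1.025 ms) window extraction, paradigm
  labelling (proximal transection → afferent, distal → efferent, complete
  → noise).
* `dircuff.features` — the 20-descriptor window feature vector (variance,
  skewness, kurtosis, entropy, Hjorth mobility, polarity signs, spectral
  means, …) in a fixed canonical order.
* `dircuff.classify` — the two data-split schemes (pooled 60/40 + 85/15,
  and leave-one-experiment-out + 85/15), four classifier families
  (Gaussian-kernel SVM, coarse k-NN, AdaBoost, small MLP), per-class
  penalty tuning on validation recall balance, confusion/F1/ROC/AUC
  reports.
* `dircuff.physio` — 15-s-bin analysis of HR, BP, GGEMG and RnP, percent
  changes, an exact small-sample Wilcoxon rank-sum, and the obstruction
  hypothesis test on predicted afferent fractions.

See `docs/methods.md` for the model, parameter defaults and numerical
decisions.

## Worked example

```python
import numpy as np
from dircuff import (
    ScenarioConfig, Protocol, simulate_recording, process_recording,
    batch_extract, train_classifier, evaluate, split_model1, compute_snr,
)

proto = Protocol(baseline_s=30, n_obstructions=3, obstruction_s=15,
                 gap_s=20, post_s=15)
rec   = simulate_recording(ScenarioConfig("proximal_transection", proto, seed=1))
eff   = simulate_recording(ScenarioConfig("distal_transection",  proto, seed=2))
noise = simulate_recording(ScenarioConfig("complete_transection", proto, seed=3))

corpus = []
for r, cond in [(rec, "proximal_transection"), (eff, "distal_transection")]:
    windows, report, _ = process_recording(r.contacts, noise.contacts, cond)
    print(cond, "threshold", round(report.thresholds.t_upper, 2), "µV,",
          report.n_windows, "windows")
    corpus.append(batch_extract(windows, 40_000.0))

import pandas as pd
data = pd.concat(corpus, ignore_index=True)
train, val, test = split_model1(data, seed=0)
model = train_classifier(train, "svm_gaussian", class_weights={0: 1.0, 1: 1.5})
rep = evaluate(model, test)
print("accuracy", round(rep.accuracy, 3), "AUC", round(rep.auc, 3))
print("SNR of the 2.007 Vpp ratio:", round(compute_snr(2.007, 1.0), 2), "dB")
```

Output (seed-exact; a few minutes — the SVM trains on ~26k windows):

```
proximal_transection threshold 2.92 µV, 23615 windows
distal_transection threshold 2.92 µV, 28029 windows
accuracy 0.776 AUC 0.868
SNR of the 2.007 Vpp ratio: 6.05 dB
```

The detection threshold lands near 2.9 µV (3σ of the calibrated 6-dB noise
floor), and at that operating point the classifier separates the two
directions at ~78% — rising above 95% as the simulated SNR reaches 12 dB
(see the acceptance suite).

A command-line interface wraps the same stages:

```bash
dircuff simulate --condition intact --out run/rec --seed 1
dircuff process --in run/rec --noise run/noise --out run/proc
dircuff run-all --out run/all --seed 1      # simulate→process→train→analyze
dircuff config-schema                        # full configuration schema
```

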