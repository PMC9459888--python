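# palmdas

**Distributed acoustic sensing + CNN pipeline for early detection of red
palm weevil larvae — with a Φ-OTDR physics simulator so the whole method is
buildable and testable without field hardware.**

Red palm weevil (*Rhynchophorus ferrugineus*) larvae destroy date, coconut
and oil palms from the inside; by the time a tree looks sick it is usually
beyond saving.  The larvae are audible while chewing, and a fiber-optic
distributed acoustic sensor (DAS) — a phase-sensitive optical time-domain
reflectometer (Φ-OTDR) interrogating a single fiber cable wound in a ~5-m
loop around every trunk — can listen to hundreds of trees at once,
non-invasively, 24/7.  `palmdas` is for researchers and engineers
prototyping such acoustic pest-detection pipelines: it implements the full
detection chain and a forward model of the sensor that generates labeled
synthetic data with the same geometry and noise structure.

## The method

A 5-kHz train of 50-ns pulses (~5-m spatial resolution) produces one
Rayleigh backscatter trace per pulse over a ~1-km fiber sampled every
0.5 m.  Chewing perturbs the local refractive index, modulating the trace
intensity only at the infested tree's bins.  The chain per tree and 100-ms
window:

1. **Normalized differential** `d_i(z) = (I_i(z) − I_ref(z)) / I_ref(z)`
   against a reference trace turns trace stacks into per-location acoustic
   signals (ideally zero on a quiet fiber).
2. **Band-pass [100–800 Hz]** (zero-phase) removes low-frequency wind noise
   and high-frequency instrument noise while keeping the dominant larvae
   band.
3. **Images**: the tree's 10 spatial points × 500 samples form a temporal
   image; row-wise FFTs give the 10 × 250 spectral image.
4. **Labels**: with SNR measured against quiet fiber, infested trees with
   SNR > 2 dB are recorded as *infested*; healthy trees yield *calm*
   (SNR < 2 dB) or *noisy* (SNR > 2 dB) examples.
5. **Two CNNs** (one per image kind: conv → pool → conv → pool → dense(50)
   → sigmoid) classify infested vs healthy windows.
6. **Strict AND fusion**: a window counts as an infestation alarm only if
   *both* CNNs agree — since the merged positive set is an intersection,
   `FalseAlarm = FP/(TP+FP)` can only improve over either branch.
7. **Tree verdicts**: per-tree alarm counts are compared with the maximum
   count among reference healthy trees; strictly exceeding it announces
   infestation.

The simulator models each distance bin as a frozen coherent sum of random
scatterers, `I_z(t) = |Σ_m a_m e^{i(φ_m + θ_z(t) w_m)}|²`, with larvae
bursts, wind (colored noise, power ∝ speed³, rolling off above 100 Hz) and
receiver noise driving the phase/intensity terms.  See
[docs/methods.md](docs/methods.md) for the model, its assumptions and
limitations.

## Worked example

```python
from palmdas.dataset import generate_labeled_dataset
from palmdas.experiment import train_branches, evaluate_branches, run_alarm_experiment

# 1. labeled synthetic dataset (2,000 infested + 1,000 calm + 1,000 noisy image pairs)
examples = generate_labeled_dataset(n_per_class=2000, seed=7)
print(f"{len(examples)} labeled image pairs")

# 2. train both CNN branches on a stratified 60/20/20 split
clf_t, clf_s, (train, val, test) = train_branches(examples, seed=7, epochs=8)
ev = evaluate_branches(clf_t, clf_s, test)
print(f"temporal accuracy {ev['accuracy_temporal']:.3f}, "
      f"spectral accuracy {ev['accuracy_spectral']:.3f}")
print(f"FalseAlarm: temporal {ev['false_alarm_temporal']:.2f}%, "
      f"spectral {ev['false_alarm_spectral']:.2f}%, "
      f"merged {ev['false_alarm_merged']:.2f}%")

# 3. controlled-environment experiment: 2 infested + 2 healthy trees, 30 s
res = run_alarm_experiment(clf_t, clf_s, wind_mph=0.0, duration=30.0, seed=7)
for tid, n in res["ledger"].n_alarms.items():
    print(f"tree {tid}: {n} alarms / {res['ledger'].n_examples[tid]} windows")
print(f"reference-healthy threshold {res['threshold']:.0f}; "
      f"announced infested: {[t for t, v in res['verdicts'].items() if v]}")
```

Output of this exact script (`seed=7`):

```text
4000 labeled image pairs
temporal accuracy 0.921, spectral accuracy 0.986
FalseAlarm: temporal 5.07%, spectral 1.25%, merged 0.57%
tree I1: 73 alarms / 300 windows
tree I2: 126 alarms / 300 windows
tree H1: 0 alarms / 300 windows
tree H2: 0 alarms / 300 windows
reference-healthy threshold 0; announced infested: ['I1', 'I2']
```

Reading it: on held-out windows both branches exceed 92% accuracy and the
strict AND rule cuts the fraction of wrong infestation calls (FalseAlarm)
well below both single-branch values (0.57% vs 5.07%/1.25%).  At tree
level, both truly infested trees accumulate far more alarms than the worst
reference healthy tree (the alarm-count threshold), so exactly the
infested trees are announced — and note that even infested trees alarm on
only a fraction of windows, because larvae chew intermittently.

The same pipeline is scriptable from the shell:

```bash
palmdas simulate --config scene.yaml --out traces.h5 --seed 1
palmdas preprocess --in traces.h5 --out pre.h5 --band 100:800
palmdas make-dataset --out data.h5 --n-per-class 2000 --seed 1
palmdas train --branch temporal --data data.h5 --out t.pkl
palmdas train --branch spectral --data data.h5 --out s.pkl
palmdas count-alarms --models t.pkl,s.pkl --stream traces.h5 --reference-trees H1,H2
palmdas run-experiment --out experiment_out --seed 1
```

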