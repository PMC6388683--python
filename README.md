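# erpsource

Forward simulation and inverse modelling of event-related potentials (ERPs)
on a spherical head, organised around a neurocognitive model in the ACT-R
tradition: independent cognitive modules (visual, imaginal/parietal,
declarative/temporal, retrieval/frontal, procedural/basal) that activate at
fixed latencies, each generating one or two equivalent current dipoles whose
summed fields are observed at a sparse 12-site 10–20 EEG montage.

The package is for researchers who want to prototype and stress-test this
modelling chain without access to raw EEG: it generates task-structured
synthetic recordings with known ground truth, runs the full analysis
(filtering, epoching, baseline and ocular-artifact correction, FastICA
decomposition, dipole localization, amplitude fitting) and quantifies how
well the fitted model reproduces the measured scalp activity.

## The model

A dipole with strength *p* and unit orientation **n** at location **x**
produces, at electrode **e**, the potential

    V = k · p · cos θ / r²

where *r* = |**e** − **x**| (Pythagoras) and θ is the angle between **n**
and the dipole→electrode vector. The head is a single homogeneous sphere
(default radius 85 mm) and amplitudes are relative, so *k* ≡ 1. Because the
potential is linear in the moment vector *p*·**n**, a lead-field matrix maps
source strengths to electrode potentials, and superposition gives the scalp
signal of many dipoles.

Module activation is a triangular spike: zero outside peak ± half-width
(default 50 ms), rising linearly to its peak and dropping at the same rate.
Each task carries a fixed schedule of eight module activations (peak time ×
generating region); productions in the accompanying cognitive engine fire
one at a time at a fixed 50 ms cost.

The inverse path mirrors DIPFIT-style practice: FastICA extracts maximally
independent components; each retained component's scalp map is explained by
one or two dipoles found by a coarse interior grid search (moments solved by
linear least squares at every candidate) refined with a Nelder–Mead simplex;
fit quality is residual variance of the map, and overall model quality is
the coefficient of determination R² = 1 − SS_res/SS_tot pooled over all
channel × time samples.

## Worked example

```python
import numpy as np
import erpsource as es

head = es.HeadModel()                      # 85 mm sphere
montage = es.ElectrodeMontage.default(head)
schedule = es.build_schedule("attention")
print("modules:", len(schedule.events))
print("peak times (ms):", [e.peak_time for e in schedule.events])

# How precisely can a dipole be localized from voltages known to ±10%?
dip = es.Dipole(location=[0.0, -59.5, 0.0], orientation=[0.0, -1.0, 0.0])
report = es.sensitivity_analysis(dip, montage, head,
                                 perturbation=0.10, n_reps=100, seed=0)
print(f"median displacement: {report.median_mm:.2f} mm "
      f"(95th pct {report.p95_mm:.2f} mm)")

# End-to-end: simulate 200 noisy trials, decompose, localize, rebuild, score
from erpsource.pipeline import run_pipeline, validate_config
cfg = validate_config({"session": {"n_trials": 200},
                       "noise": {"sensor_sigma": 0.1},
                       "eval": {"run_sensitivity": False}, "seed": 1})
rep = run_pipeline(cfg)
print("components retained:", rep.results["ica"]["n_selected"])
print(f"pooled R^2: {rep.results['evaluate']['r_squared']:.3f}")
```

prints

```
modules: 8
peak times (ms): [100.0, 125.0, 170.0, 220.0, 280.0, 320.0, 380.0, 690.0]
median displacement: 2.85 mm (95th pct 5.59 mm)
components retained: 12
pooled R^2: 0.796
```

The eight scheduled activations are the simulated cognitive events; the
sensitivity report says that multiplying each electrode's noiseless voltage
by an independent factor in [0.9, 1.1] and refitting moves the recovered
occipital dipole by a median of a few millimetres; and the pipeline's pooled
R² means the fitted model (dipoles + triangular spikes + non-negative
amplitudes) reproduces about 80% of the spatial and temporal variance of the
measured average ERP at 10% sensor noise.

A command-line interface wraps the same stages:

```bash
erpsource simulate --task attention --seed 1 --out session.edf
erpsource run --seed 1 --out results/
erpsource sensitivity --perturbation 0.1 --n-reps 100 --seed 0 --out sens.json
```

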