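# Methods

## Forward model

The scalp potential of an equivalent current dipole is computed directly
from Coulomb's law, `V = k·p·cos θ / r²`, with `r` the Euclidean
dipole-to-electrode distance and θ the angle between the dipole orientation
and the dipole→electrode vector (this geometric convention is a package
decision; it makes θ = 0 for a radial dipole directly under an electrode).
The head is a single homogeneous sphere — no boundary or conductivity
correction — because the model works throughout in relative magnitude, where
the field constant `k` and any global conductivity factor cancel. The
default scalp radius is 85 mm, a child-sized head, and is configurable so
displacement results stay meaningful in millimetres for other head sizes.

The 12-electrode montage (Cz, F3, F4, Fz, O1, O2, Oz, P7, P8, Pz, T7, T8)
uses idealized 10–20 angular positions on the sphere, embedded as a
coordinate table (data, not computed): midline sites on the nasion–inion
great circle, temporal/occipito-temporal sites on the equator through the
pre-auricular points. Positions are exactly normalized to the scalp radius
at construction.

Because `p·cos θ / r² = m·(e − x)/r³` is linear in the moment vector
`m = p·n`, the lead field is assembled per location from 3-vector gains;
superposition across dipoles is a matrix product.

## Cognitive scheduling

The production engine is deliberately minimal: match → fire → update at a
fixed 50 ms cost per firing, rules firing one at a time, each buffer holding
at most one chunk. A rule condition may also require a buffer to be empty,
which is how chains of the form "perceive, then act" terminate. Simultaneous
matches resolve by declaration order (documented tie-break). Retrieval-time
modulation (stronger memories returning sooner) is exposed only as the
per-rule `cost_ms` override, default off — simulation uses the fixed task
schedules directly.

Each task carries a fixed schedule of eight module activations (peak time ×
generating region); the attention task and the picture-display event of the
word-verification task share one column, the word event has its own. Region
labels map to representative dipole coordinates through an embedded lookup
(occipital, parietal, frontal, temporal, basal; left/right/midline at about
0.7 of the scalp radius, basal rows as deep midline-adjacent sources
oriented +z because a radial direction is ill-defined near the centre —
an assumption, recorded here). Placement rules, since a module carries at
most two dipoles:

* a single bilateral region → two mirrored lateral dipoles;
* each additional region token → one dipole (lateralized if the token names
  a side, at the region midline otherwise);
* rows naming more than two regions keep the first two.

Spikes are triangles: zero outside peak ± half-width, linear to the peak.
Half-width defaults to 50 ms and amplitude to 1 (relative); per-event
amplitudes are free parameters estimated downstream. Neither is prescribed
per row by the schedules, so these defaults are modelling decisions.

## Synthetic data

The generator emulates the study conditions the analysis chain is meant for:
12-channel 10–20 EEG at 1,000 Hz; epochs spanning the half-open window
[−200, 1000) ms with the stimulus at t = 0 (1,200 samples, stimulus at
index 200); attention sessions of 150 trials at 500 ms stimulus + 500 ms
ISI with targets drawn Bernoulli(0.25) per trial (150 is not divisible by 4,
so exact-count shuffling cannot realize one quarter exactly); word/picture
events for the vocabulary task as separate schedules.

Nuisance structure: white Gaussian sensor noise per channel, with standard
deviation expressed as a fraction of the peak noiseless scalp amplitude
(default 0.1); an optional 1/f-shaped background synthesized by spectral
shaping (off by default — no noise model is prescribed, so both are
config-selectable); stereotyped blinks as ~300 ms raised-cosine bumps on the
VEOG channels at Poisson times (default 8/min — preschoolers blink often),
propagating into EEG channels with coefficients proportional to how anterior
the electrode is and exactly zero at and behind the coronal midline. Blink
amplitude defaults to roughly ten times a typical single-dipole scalp peak,
mirroring the real-world dominance of ocular potentials over ERPs. All
outputs are pure functions of (config, seed) and carry their ground truth
(noiseless projection, noise σ, blink times/template/coefficients).

What the generator does **not** emulate: ongoing oscillatory EEG (alpha,
theta), movement/muscle artifacts, electrode drift or impedance changes,
inter-subject anatomical variability, or behavioural responses beyond event
labels. Passing tests therefore demonstrate correctness of the computational
chain under the stated noise model, not performance on real recordings.

## Preprocessing

Band-pass filtering is zero-phase (forward–backward) with 4th-order
Butterworth sections at 0.15–100 Hz by default. High- and low-pass sections
are designed separately and cascaded: a single band-pass design is
numerically fragile when the edges differ by three decades. Epoching uses
half-open windows and 0-based indexing throughout; events whose window falls
outside the record are dropped with a logged count. Baseline correction
subtracts the per-trial, per-channel mean over [−200, 0) and is idempotent.

Ocular correction follows the average-artifact-subtraction scheme: blink
sweeps are detected on the VEOG as excursions beyond 3 robust standard
deviations (1.4826 × MAD, configurable); a per-channel propagation
coefficient is estimated by least squares of each channel on the VEOG over
artifact samples; the scaled artifact is subtracted sweep by sweep, point by
point. The VEOG reference channels themselves are never "corrected". With a
flat VEOG the transform is the identity and warns. Noise-only sweeps can
cross a robust threshold (the maximum of ~1,200 Gaussian samples sits near
3.4σ), but the estimated coefficients are then regression noise and the
correction stays below the sensor-noise floor — the relevant tests assert
exactly this.

Averaging: per-condition arithmetic means; grand averages are unweighted
means of per-subject averages, never pooled-trial means. Smoothing (for
display) is a 20 ms moving average by default, DC-preserving; a low-pass
variant is available.

## Decomposition

FastICA (fixed-point iteration, tanh contrast, symmetric decorrelation by
default; tol 1e-6, max 500 iterations) runs on concatenated single-trial
epochs (channels × trials·samples), matching the single-trial emphasis of
the modelling chain; averaging first is a caller option. Rank-deficient
data (e.g. noiseless 8-source projections on 12 channels) is detected from
the covariance eigen-spectrum and the component count reduced accordingly.
Non-convergence is flagged on the result, never silent.

ICA leaves magnitude and sign unidentifiable, so every component is
normalized: unit-norm scalp map with its largest-magnitude electrode
positive, the scale and sign pushed into the source timecourse, leaving the
map ⊗ source product invariant. Components are ordered by explained-variance
fraction and retained above 1% by default — a decision; the pipeline on
schedule-driven data retains however many modules carry at least that
fraction of scalp variance, which under equal default amplitudes is seven of
the eight scheduled modules for the attention column (the single-dipole left
parietal module carries ~0.7%).

## Dipole fitting

For a fixed location the potentials are linear in the moment vector, so
only locations are searched: a 10 mm lattice inside 0.85 of the scalp radius
(symmetric about zero so mirror pairs exist) scores every candidate by
linear least squares, the best five candidates are refined by Nelder–Mead
(relative function tolerance 1e-8, location tolerance 1e-3 mm, with a
penalty outside 0.95 R), and moments are re-solved at the winner.
Two-dipole fits start from the best mirror-image grid pairs and optimize
both locations jointly (6 parameters). Ties between equal-residual
candidates break by smaller depth below the scalp, then lexicographic
location. Residual variance is 1 − SS_explained/SS_total of the map about
zero (the convention for scalp maps, which are zero-mean-ish by
construction but not centred for this statistic).

`choose_n_dipoles` fits both models and accepts the second dipole only when
it lowers residual variance by more than 0.05 absolute (default margin).

The sensitivity analysis multiplies each electrode's noiseless voltage by an
independent factor uniform on [1 − δ, 1 + δ] (δ = 0.10 default; a normal
variant is available and the distribution is recorded in the report), refits
a single dipole and reports displacement statistics in mm. The default
scenario — an occipital radial dipole at 0.7 R on the 85 mm sphere with the
12-site montage — is an assumption, as depth, montage and error distribution
are all configurable; under it the large-n median displacement is ≈3 mm
(100-replicate medians scatter roughly 2.5–3.4 mm).

## Model evaluation

A fitted neurocognitive model couples each retained component to a module:
dipoles from its scalp-map fit, spike peak at its averaged source's
peak-latency sample, half-width 50 ms. Amplitudes are solved by non-negative
least squares against the measured average ERP (spikes model recruitment
magnitude; sign lives in the dipole orientation); near-collinear regressors
raise an error naming the offending events. Fit quality is R² pooled over
all channel × time samples, with SS_total about the grand mean of the
measured data, so predicting that mean scores zero; per-channel and
per-component variants are reported alongside because "fit" can reasonably
be read at any of those granularities — the pooled value is the headline.

Under the default study conditions (attention schedule, 10% sensor noise,
200 trials) the pipeline's pooled R² comes out near 0.78–0.80; the residual
misfit is structural — FastICA cannot perfectly unmix temporally overlapping
(hence correlated) spikes, so early components are mild mixtures — not noise
in the 200-trial average, whose variance share is below 1%.

## Statistics

Windowed contrasts are paired t-tests on per-subject window means; the
standardized difference divides the mean difference by the across-subject
spread of the baseline mean, making it an effect size in waveform units. A
zero-variance difference vector short-circuits to t = 0, p = 1 (or ±∞, 0 for
a constant nonzero shift). Multiple comparisons use the Simes
improved-Bonferroni global test (reject when any ordered p(i) ≤ i·α/m) with
Hochberg's step-up rule for per-hypothesis decisions and Hochberg adjusted
p-values — the global test alone gives no per-comparison decisions, and the
step-up rule is its standard companion. Median splits place the
median-valued subject in the Low group for odd n and break ties by subject
id, so the partition is order-independent. Effect-size comparison between
groups Fisher-transforms correlation-scale effects (standardized differences
convert via r = d/√(d²+4)) and refers (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)) to
the standard normal; its type-I rate calibrates to 5% in simulation.

## Numerical and I/O choices

* EDF writing is plain EDF with one-second records, per-channel physical
  ranges widened by 10⁻⁴ and then rounded through the 8-character ASCII
  header fields before quantization, so read(write(x)) differs by at most
  one 16-bit quantization step; the true sample count is stored in the
  header's reserved field so padding is stripped on read. Truncated or
  malformed files raise explicit errors. Events travel in a TSV sidecar.
* Epoch sets serialize to HDF5 with a JSON metadata attribute.
* One global seed drives every stochastic stage through
  `SeedSequence(seed, spawn_key=(stage_index,))`; the per-stage spawn keys
  are logged in the run report, and identical config + seed reproduce the
  report byte for byte.
* Problem sizes in the test suite and acceptance script (200-trial runs,
  100-replicate sensitivity, 5-trial noiseless ICA runs) were chosen as the
  smallest sizes at which the Monte-Carlo quantities stabilize.

## Known limitations

* The infinite-medium Coulomb field ignores the conductivity boundary at the
  skull; absolute amplitudes are meaningless by design and only relative
  patterns matter.
* Region→coordinate placement is a coarse embedded lookup, not an atlas;
  "basal" rows are treated as deep midline sources on assumption.
* With overlapping spikes ICA recovery is only approximate (whitening forces
  uncorrelated components onto correlated sources); peak latencies of mixture
  components can fall between scheduled times.
* The two-dipole search assumes approximate mirror symmetry for its
  initialization; strongly asymmetric two-source maps may need a denser grid.
* The sensitivity claim is scenario-dependent (source depth, montage,
  perturbation distribution); the defaults above are one reasonable reading.
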