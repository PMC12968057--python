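# Methods

`rumblekit` implements an end-to-end seismo-acoustic monitoring pipeline
for low-frequency elephant vocalizations ("rumbles") recorded by a
co-located three-component seismometer and an infrasound pressure sensor,
both sampled at 200 Hz. Because field recordings are not required, the
package ships a synthetic scene generator whose statistical structure
mirrors the phenomenology of a zoo deployment; every downstream stage is
exercised against that generator's known ground truth.

## Synthetic scenes

A scene is a quadruple of waveforms (seismic N/E/Z in µm/s, pressure in
Pa) plus the catalog of injected sources. It is a pure function of a
`SceneConfig` and its seed: identical configurations give bit-identical
bundles.

**Rumbles.** Each call is a harmonic stack over a smooth frequency
contour. The fundamental rises from `apex × (1 − contour_depth)` at the
call edges to the apex frequency over raised-cosine ramps that occupy the
outer quarters of the call, with a plateau at the apex across the central
half. The plateau is deliberate: a pure chirp without dwell places its
periodogram maximum ambiguously inside the swept band, whereas a
plateaued contour anchors the spectral peak at the apex, which is what
the feature-recovery stage estimates. Overtones are exact integer
multiples of the instantaneous fundamental with geometric amplitude decay
per order and zero relative phase (the inter-harmonic phase relation of
real calls is unknown; zero phase is the simplest reproducible choice).
A Tukey (α = 0.2) envelope smooths onset and offset. Default priors
follow the observed ranges: apex uniform on 10–25 Hz, duration triangular
on 1–8 s with mode 3.5 s (mean ≈ 4 s), peak ground velocity uniform on
1–10 µm/s, usually one overtone, occasionally two, with decay factors of
0.3–0.7 so the fundamental stays dominant. Peak pressure for the
infrasound rendering is uniform on 0.02–0.2 Pa; absolute pressure scale
matters less than the signal-to-noise ratio it implies against the
0.002 Pa night background.

The seismic rendering of a call is partitioned across N/E/Z by a random
unit direction-cosine vector per call, so the vector-sum amplitude equals
the spec's peak ground velocity while individual components vary. The
partition is unobservable downstream because analysis averages component
spectrograms.

**Footfalls.** Locomotion impulses are exponentially damped bursts of
high-pass-filtered white noise (4th-order Butterworth at the spectral
corner, default 25 Hz), 0.05–0.3 s long, rendered on the seismic channels
only — the defining channel contract of the two sensing domains. By
default two-thirds of scheduled calls are accompanied by a cluster of
2–6 footfalls within ±30 s, matching the observed motion-coincidence
fraction.

**Noise.** Backgrounds are Gaussian at a night RMS (seismic 0.05 µm/s,
infrasound 0.002 Pa), multiplied inside opening hours (07:00–17:00 UTC,
hard step) by a day factor: 7 for the seismic channels (observed range
5–10) and 2 for infrasound, encoding the much stronger anthropogenic
contamination of the ground-motion channel. Daytime seismic noise
additionally carries three monochromatic machine lines (12/25/30 Hz,
0.07 µm/s RMS each) and Poisson-scheduled broadband bursts (20/h,
0.5–2 s). The line and burst amplitudes were chosen so that the lines
stand ≥ 10 dB above neighbouring spectral bins while the total day/night
RMS ratio stays within a few percent of the configured day factor — both
properties the tests check. Machine lines matter for the classifier: they
are tonal features inside the rumble band that the network must learn to
ignore.

**Activity schedule.** Scheduled scenes draw calls from a Poisson process
whose nocturnal rate is modulated by a per-night housing factor (default
alternating 1.0/4.0), reproducing the every-second-night activity pattern
of alternating indoor housing; the daytime rate is a configurable
fraction of the nocturnal baseline.

What the generator does **not** emulate: propagation physics (attenuation,
dispersion, site response), sensor response, correlated noise between
channels, call-type diversity beyond the single contour family, and
overlapping-call interference beyond linear superposition. Passing tests
therefore demonstrate the pipeline's internal consistency and its
behaviour under the stated statistical structure, not performance on real
zoo recordings — the published accuracies on real data are out of scope
here.

## Spectrogram preprocessing

Traces are band-passed to 1–80 Hz with a zero-phase (two-pass)
Butterworth so pick times are not shifted; the 8th-order design keeps
the transition bands narrow enough that re-filtering already-filtered
data changes its RMS by well under 1 %. Spectrograms are Hann-windowed
STFTs; the default window is 1.0 s with 75 % overlap, giving 1 Hz
frequency resolution (resolving 10–25 Hz fundamentals) and 0.25 s hop
(resolving 1 s calls). The three seismic component maps are averaged
cell-wise on the linear power scale, which raises the ridge-to-background
ratio of tonal signals whose energy is split across components.

Classifier inputs are 12-s snippets with the pick time at the temporal
centre, rendered to 232 × 115 RGB images: power in dB, clipped at the
per-snippet 2nd/98th percentiles, mapped through viridis and bilinearly
resampled. Per-snippet percentile anchors make the rendering adaptive to
absolute level (day vs night) while remaining a pure function of the
map, so training and scanning see consistently scaled images. Snippets
are never padded; picks closer than 6 s to a record edge are rejected.

## Classifier

The network is fixed: three convolutional blocks for feature extraction —
two Conv2D layers with 32 filters (5×5), two with 64 filters (3×3), two
with 128 filters (5×5), each block followed by 2×2 max-pooling and 25 %
dropout — then a flattened dense layer of 128 ReLU units with 40 %
dropout and a 2-class softmax. Convolutions use "same" padding so the
three poolings take the 115 × 232 input to 14 × 29; the parameter count
is 7,350,434 and is checked against the closed form in the tests.
Training uses RMSprop (learning rate 5·10⁻⁴, ρ = 0.9, ε = 10⁻⁸), batch
size 8, sparse categorical cross-entropy, a stratified 70/10/20
train/validation/test split (rounded per class, remainder to train), a
30-epoch cap with early stopping on validation loss (patience 5, best
weights restored), and per-class 1:1 rumble:noise balance with noise
snippets drawn across both day and night.

The engine is written in NumPy (no deep-learning framework is a
dependency): convolutions run as sums of spatially shifted BLAS matmuls
(or a single patch-matrix GEMM for the RGB input layer, where that is
faster), and all randomness — initialization (Glorot uniform), shuffling,
dropout masks — derives from explicit seeded generators. This makes
training and inference bit-reproducible on one machine, which the
determinism tests exploit; it also means throughput is CPU-bound at
roughly 0.4 s per training image-step, which sets the study sizes below.

**Evaluation protocol.** Three networks are trained per study: S-CNN on
seismic images, I-CNN on infrasound images, C-CNN on the union of both
training (and validation) splits. Each network is evaluated on both
held-out test sets, giving six confusion matrices covering within- and
cross-domain transfer. Test sets are never pooled.

**Continuous scanning.** A trained network slides a 12-s window at a
configurable hop (default 2–3 s) over a continuous record, renders each
window exactly like a training snippet, and merges runs of consecutive
windows whose rumble probability exceeds the threshold (default 0.5) into
one detection at the run's peak-score window centre. Detections are
scored against the truth catalog by maximum-cardinality one-to-one
matching within ±6 s (half a window). Truth calls whose centres fall
within one analysis window are collapsed to a single expected event
before matching: a detector with a 12-s window cannot structurally
report two calls 1–2 s apart as separate detections, and they merge into
one above-threshold run.

## Catalog analytics

An *event* is one (timestamp, apex frequency, duration) detection; a
*rumble* groups co-occurring events at near-integer frequency ratios
(tolerance 0.15 on the ratio to the group's lowest frequency, time
overlap required). Inter-call intervals are binned half-open into
<5, 5–10, 10–30, 30–60, 60–120 and >120 s, measured start-to-start; the
final rumble, having no successor, counts in the open bin so the counts
always partition the catalog. Motion coincidence labels a rumble "yes"
when any footfall time falls within [start − 50 s, start + duration
+ 50 s]; the automated labeler is binary, and "not_sure" survives only
when read from manually labeled files. Background noise is profiled as
band-limited (1–80 Hz) RMS per window (default 1 h).

Cross-domain matching pairs rumbles whose start times agree within 2 s
and fundamentals within 2 Hz. The matching maximizes the number of pairs
(solved as a rectangular assignment problem where infeasible pairs carry
a prohibitive cost), and among maximum matchings minimizes the summed
time offset. A nearest-first greedy pairing was rejected because it can
strand matchable pairs (two calls at 1.0/2.0 s against picks at
0.0/1.1 s with a 1 s tolerance: greedy finds one pair, the optimum two),
and the matched count would then depend on processing order; the
assignment formulation is deterministic and symmetric in its arguments.
Histogram similarity is the intersection of the two normalized
histograms — the sum of bin-wise minima, 1 for identical shapes.

Feature estimation inside a detection window takes the per-time-bin
band-power maximum as a ridge, reads the apex frequency at the ridge-power
maximum, measures duration as the contiguous span where ridge power stays
above both half the peak and ten times the median background, and places
the timestamp at the ridge-power centroid of that span. Windows whose
ridge never clears the background margin return no event.

## Polarization

Particle motion is summarized per frequency band by the eigen-structure
of the 3×3 zero-lag covariance of the band-passed, demeaned N/E/Z
window: the vertical-to-horizontal energy ratio `vh = E_Z/(E_N + E_E)`,
the incidence angle of the dominant eigenvector from the horizontal
plane, and rectilinearity `1 − (λ₂+λ₃)/(2λ₁)`. Classification calls a
band Rayleigh-like at `vh ≥ 2` and Love-like at `vh ≤ 0.25`, otherwise
mixed. The Love threshold sits well below 0.5 on purpose: for isotropic
noise the expected ratio is exactly `E_Z/(E_N + E_E) = 0.5`, so a
threshold at 0.5 would put unpolarized windows on the decision boundary
and classify about half of them as Love-like; 0.25 keeps isotropic
windows reliably mixed while genuinely transverse motion (vh ≈ 0) is
still far below it. The default analysis bands are 16–20 Hz
(fundamental) and 30–40 Hz (first harmonic).

## Workflow and reproducibility

`run_pipeline` executes the enabled stages in dependency order
(simulate → preprocess → train → protocol → scan → stats → polarize)
after a pre-flight check that every enabled stage's inputs are
resolvable, and writes a manifest recording seeds, package versions and a
SHA-256 checksum of every artifact. All tabular outputs are CSV/JSON;
waveforms are written as float32 WAV (or CSV) with a JSON metadata
sidecar carrying sampling rate, start time, channel and units. Reruns
from the same configuration reproduce every CSV/JSON artifact
bit-identically, including classifier training.

## Study sizes and numerical choices

The test suite and the acceptance script size the synthetic studies for a
single CPU, as the package's own default desk-scale study:

* classifier protocol: 80 (tests) or 70 (acceptance script) rumble and
  noise snippets per class per domain, trained up to 4 epochs — the
  synthetic task reaches full validation accuracy by epoch 2–3 and the
  early-stopping cap is configurable up to the 30-epoch default;
* injection-recovery scene: 3600 s (tests) / 1800 s (script) spanning the
  night→day boundary at 30 calls/hour, scanned at a 4 s (tests) or 3 s
  (script) hop;
* feature recovery: 100 isolated calls at SNR ≥ 5;
* oracle equivalence: 1000 random catalogs against brute-force
  implementations;
* channel contract and polarization: 20 seeds each.

Detection thresholds, recovery tolerances and accuracy floors are not
scaled. Degenerate inputs are rejected loudly rather than coerced:
zero-energy polarization windows, out-of-band corners, picks near record
edges, harmonics at or above Nyquist, non-uniform CSV sampling. Ties in
max-pooling resolve to the first maximum (argmax order); the
interval-histogram bins are half-open with the last bin open-ended.

## Known limitations

* The classifier is trained and validated on synthetic spectrograms; no
  claim is made about accuracy on real recordings, and the published
  real-data accuracies are not reproduction targets.
* miniSEED I/O is not supported (no reader/writer dependency is
  available); WAV/CSV with JSON sidecars are the supported formats.
* The statistical channel-contract test admits the nominal false-positive
  rate of its α = 0.01 two-sample test; the acceptance check therefore
  requires 19 of 20 seeds rather than all 20.
* Scanning cannot resolve calls closer than its 12-s analysis window;
  such calls merge into one detection, and the evaluation counts them as
  one resolvable event. Calls buried in the densest locomotion clusters
  remain the dominant source of missed detections.
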