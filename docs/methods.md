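# Methods

This note documents the models, conventions and design choices behind
`madopo`, and what the synthetic phantom does and does not establish about
real measurements.

## Coordinate frames and geometry

Poses, search grids and landmarks live in a right-handed head frame in
millimetres; sensor positions are stored in metres and all field evaluation
is SI (tesla, metres, amperes), with the mm→m conversion made once at the
forward-model boundary. The electrode axis points from the tip towards the
top ring contact (C8). Axial rotation `rot` is measured about that axis
with segmented contact C2 at azimuth `rot`, referenced to the frame's +x
direction projected off-axis — the clinical convention references the
AC–PC line instead, but that is a frame choice, not part of the algorithm.

The 1-3-3-1 lead layout is fixed (C1 ring, C2–C4 and C5–C7 segmented
levels, C8 ring; 90° segments with 30° gaps). The dimensional parameters
are configuration, not constants: lead radius 0.65 mm, contact length
1.5 mm, inter-level gap 0.5 mm, tip-to-first-contact 0.6 mm. The defaults
give a 2.0 mm spacing between consecutive level centroids, consistent with
the ~2.03 mm mean spacing implied by published CT-derived level midpoints of
this lead family.

Landmark co-registration is the closed-form orthogonal-Procrustes (Kabsch)
solution on ≥ 3 non-collinear labelled points; collinear sets raise a
degeneracy error rather than returning an ill-defined rotation.

The synthetic helmet is a Fibonacci lattice over a 120° spherical cap of
120 mm radius with radially oriented magnetometers — a stand-in with the
coverage and sensor count of a whole-head SQUID array, not a replica of any
vendor layout (real layouts can be loaded from the TSV sensor format).

## Forward models

Both source models assume an infinite homogeneous quasi-static medium; no
boundary or volume currents are modelled. This is the standard current-
dipole approximation for bipolar stimulation: the primary current is
confined to a few millimetres around the lead while sensors sit ~10 cm
away. The cost of this simplification is absorbed into the accuracy
expectations; it removes any finite-element dependency while keeping the
inverse machinery identical.

* **Equivalent dipole** — location midway between the fraction-weighted
  cathode and anode centroids; moment `I·d` pointing anode→cathode. Sign
  convention: swapping cathode and anode negates every map (verified
  exactly in tests).
* **Distributed source** — each cathode–anode pair `(i, j)` carries
  `I·fᵢ·fⱼ` split into `n_path` collinear elements along the straight
  centroid-to-centroid path (default `n_path = 7`; with a single pair and
  `n_path = 1` it reduces bit-exactly to the equivalent dipole, and it
  converges to it in the far field at < 2 % relative RMS at 10 cm).

Maps are the signed projection `B·ŝ` per magnetometer. Prediction is
linear in amplitude and superposes over current fractions exactly.

## Goodness of fit and search

GoF = 1 − ‖m̂ − x̂‖ / ‖m̂ − mean(m̂)‖ with both maps normalised to their
absolute maxima; it is invariant to positive rescaling of either map and
equals 1 only for a perfect (normalised) match. A constant modelled map has
no spatial contrast and is rejected. Joint fits average per-measurement
GoF; with several configuration families the hierarchical mean (mean of
family means) weights families equally even when they contribute different
measurement counts.

Searches are exhaustive and deterministic: lexicographic lattice order,
first-candidate tie-break. Grid convention: `round(extent/step) + 1` points
per axis symmetric about the centre, matching the published cardinalities
(90 mm/10 mm → 1,000 positions; 29 mm/1 mm → 27,000; 1° → 360 rotations).
With an odd interval count the centre itself is not a node;
`GridSpec.around()` shifts the lattice half a step so a known point lies on
it, which the exact-recovery tests use. The coarse orientation grid is
0–30° tilt in 5° steps × 45° azimuths, deduplicated at the pole (49
directions, configurable). Because the polarity of the source is not known
a priori and the tilt cone covers only one hemisphere, the pre-localizer
also scores each direction with the moment negated (`allow_flip`, on by
default) — the candidate count is unchanged.

Post-localization searches translation only; the implantation axis and
rotation are held fixed (axis refinement would be an extension, off by
default). Orientation detection assumes the position is known, scans
`rot ∈ [0°, 360°)` and errors out if only rotation-invariant (vertical,
ring-to-ring) measurements are supplied. Candidate model maps are cached on
the model objects and reused across fits; results are identical with a cold
or warm cache (tested).

Half-turn disambiguation evaluates the GoF of the two candidate angles with
one directional measurement and reports the winner with its margin; below a
configurable margin (default 10⁻³ GoF) the result is flagged `undecided`
instead of silently picking a side.

## Signal pipeline

High-pass: 60 Hz sixth-order Butterworth, applied zero-phase
(forward–backward) so the pulse-peak latency is not skewed across channels;
`causal=True` restores a single pass. Peak detection runs on the
largest-variance channel with a threshold of 5 robust (MAD-based) noise SDs
and a minimum spacing of 0.8 stimulation periods. Epochs are one period
centred on each peak; incomplete edge epochs are dropped and counted.
The field map takes every channel's signed value at the single epoch sample
maximising the across-channel RMS — a per-channel maximum would destroy the
sign information the dipole fit needs. 50 Hz harmonics are deliberately not
notch-filtered (they do not overlap the stimulation harmonics); the
simulator can inject them to test robustness.

SNR bookkeeping uses the amplitude-ratio dB convention `10·log₁₀(a)` under
which averaging `N` epochs gains `5·log₁₀ N` dB — the unique convention
reproducing the published (N, dB) pairs — and "SNR 20 dB" means the signal
amplitude is two orders of magnitude above the noise.

## Synthetic phantom

`simulate_recording` builds each channel as ground-truth map value ×
shared biphasic waveform plus noise, so the noiseless signal is exactly
rank-1 (spatio-temporally separable); this makes the pipeline-identity
check exact rather than approximate. Defaults are the study conditions:
3 mA, 60 µs, 130 Hz trains; 180 s per measurement; 5 kHz sampling;
3 fT/√Hz white sensor noise (per-sample SD `asd·√(rate/2)`); the
24-measurement protocol (6 vertical with 33/33/33 ring splits, 6 diagonal,
6 horizontal, 6 symmetrical with 50/50 splits) at 3 mA.

The 60 µs pulse is shorter than one 5 kHz sample, so the waveform is
synthesised on an integer-oversampled clock (50 kHz for the defaults) and
box-car averaged down — area-preserving, emulating the acquisition chain's
band limiting. Strict mode raises on unrepresentable pulses instead. The
recharge phase is an exponential with time constant 5× the pulse width and
amplitude set by discrete charge balance (the real pulse generator's
recharge shape is proprietary; only charge balance and the active width are
honoured). The anti-alias low-pass of the real acquisition chain is not
modelled; it does not affect the stimulation-harmonic content the method
uses.

What the generator does **not** emulate: biological artifacts (cardiac,
ocular, motion), correlated environmental noise fields, conductivity
heterogeneity and boundary currents, and co-registration error between
modalities. Passing tests therefore demonstrate the correctness and noise
behaviour of the inverse machinery under the stated model, not the clinical
accuracy of the method on real recordings.

Field-map-level simulation (`perturb_fieldmap` at a stated SNR) is the
default for fitting tests — it is orders of magnitude faster than
time-domain simulation and equivalent once the pipeline identity is
established; recording-level simulation exercises the signal module.

## Problem sizes and numerical choices

Stochastic checks run at the study conditions scaled to desk size, chosen
once: 20 noise realisations for parameter recovery at SNR 20 dB with a
reduced 15 × 15 × 15 mm ROI at 1 mm (4,096 candidates, lattice through the
true tip); 50 trials at SNR 10 dB for half-turn disambiguation; 10–15 seeds
for trend sweeps with 10 mm ROIs. Ties at 10⁻¹² GoF resolve to the first
candidate in scan order. Sensor orientations are validated to unit norm at
10⁻⁶ and renormalised to machine precision on construction.

## Known limitations and observed behaviour

* The homogeneous-medium surrogate ignores the saline/air boundary of a
  physical phantom; absolute GoF values on real data would be lower.
* Localization error is floored by the lattice: an off-node truth costs up
  to half a cell diagonal even noiselessly.
* At 10 mm pre-localization resolution the GoF landscape is flat near the
  optimum: with off-grid positions *and* orientations the winning node can
  land one cell away (mean error ≈ 7.4 mm, occasional 13–14 mm over 20
  draws), which the default 29 mm ROI still covers comfortably.
* Displacing the assumed electrode position by 1 mm laterally shifts the
  recovered rotation by at most one 1° lattice step (2–3 mm costs 1–2°);
  displacement along the electrode axis leaves it unchanged. Diagonal
  (ring-to-segment) configurations produce much flatter GoF-versus-rotation
  curves than horizontal/symmetrical ones and contribute little rotational
  information.
* Under spatially independent white sensor noise and this helmet geometry,
  spatially stratified sensor subsets localize as well as or better than
  same-size nearest-to-source subsets — the advantage of concentrated
  arrays reported for physical phantoms plausibly depends on correlated
  environmental noise, which the generator deliberately omits. The sweep
  machinery reports both strategies so the comparison stays visible.
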