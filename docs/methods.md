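# Methods

`holoctc` is a desk-scale implementation of a dual-modality in-flow
rare-cell detection pipeline: label-free in-line (Gabor) holography
provides a morphological confidence for every cell transiting a
microfluidic channel, two photomultiplier (PMT) channels provide
immunofluorescence readouts for PSMA and EpCAM, and a cell is counted as
a circulating tumor cell (CTC) only by the conjunction of the two
modalities. Because no public instrument data exist for this class of
system, the package ships a physics-based simulator that generates every
input the analysis consumes; all tests and the acceptance checks run on
synthetic data.

## Hologram formation model

The imaging station is modelled after a 405 nm in-line holographic
microscope: 10x / 0.30 NA objective, 3.45 μm sensor pitch (0.345 μm
object-plane pixels), 450 fps, 1440x256 px region of interest. Cells are
pure phase objects: a cell of radius *R* and peak optical phase delay
φ₀ contributes a cosine-tapered radial phase bump
φ(r) = φ₀ · ½(1 + cos(πr/R)) for r < R. The transmitted field
exp(iφ) is propagated to the detector conjugate plane over the defocus
distance *z* by scalar angular-spectrum propagation, and the recorded
frame is the intensity of the propagated field times a background level,
plus optional Gaussian shot noise with std `noise · sqrt(I)`.

At this sampling the Nyquist spatial frequency (1.45 μm⁻¹) lies inside
the propagating band (1/λ = 2.47 μm⁻¹), so no representable component is
evanescent and the propagation operator is exactly unitary — the tests
verify Parseval's identity to 1e-6 and that the fringe pattern's
extremal deviation falls within 2 px of the true cell center.

Class geometry encodes the size/optical-thickness separability the
detector exploits, without claiming biological fidelity: RBC-like cells
3–4 μm radius and 0.6–1.0 rad peak phase, WBC-like 4–7 μm and
0.9–1.5 rad, CTC-like 7–12 μm and 1.5–2.5 rad. Marker expression
defaults: CTC PSMA+ with probability 1.0 and EpCAM+ with probability
0.37 (the phenotype mix the enumeration statistics are exercised
against), WBC PSMA+ at 0.005 (nonspecific binding), RBC never labeled.

In-flow geometry: cells advance along +x by `velocity / frame_rate`
per frame. At the full 1440-px field width the default velocity of
45 mm/s gives a ~5-frame transit. Marker-positive cells add a Gaussian
pulse to the corresponding PMT trace, centered at mid-transit, with full
width at half maximum equal to the transit time; the PMT is sampled at
50 kHz (≥ 10x the frame rate) over a configurable baseline with slow
drift and Gaussian noise.

The defocus distribution of cells in the channel is a free simulator
parameter (`OpticalConfig.defocus_um`, default 0; the test fixtures use
30 μm so fringes are well developed). Out of scope by design: rigorous
electromagnetic scattering, biconcave red-cell morphology, and the
upstream inertial-microfluidic enrichment (represented only as the
concentration parameters handed to the scene generator).

## Preprocessing

The static channel pattern is removed by an exponential moving average
(EMA) background: `mean' = (1-α)·mean + α·frame`, initialized exactly
from the first frame of each session and reset per session. α defaults
to 0.05, which forgets a static pattern with time constant ~20 frames
(<0.05 s) while attenuating a single-frame transient by only 5%; no
motion masking is applied because flowing cells at rare-cell
concentrations contaminate the average negligibly. The residual is then
scaled by a *fixed* mean/std (`NormSpec`), calibrated once on a set of
frames and frozen, so the detector sees consistent intensity statistics
across sessions. The focus score — offered to guide focusing, not used
in the pipeline — is the mean squared gradient magnitude normalized by
the squared mean intensity, which is invariant to global intensity
scaling and strictly decreasing under blur.

## Detector

Cells are represented as Gaussian keypoints rather than bounding boxes:
supervision places an isotropic Gaussian (σ = 2.8 μm, i.e. ≈8.12 px at
default optics) at each annotated center, overlapping blobs combining by
maximum so every keypoint peaks at exactly 1. Detection reads strict
8-neighbour local maxima of the predicted probability surface above an
operating threshold, greedily suppressed so no two keypoints fall within
`min_separation` (default 2σ = 5.6 μm — two cells closer than one blob
width are unresolvable under this target encoding); equal-confidence
ties break by lowest (row, col) for determinism.

The network keeps a high-resolution branch alongside a 2x-coarser
branch with fusion before the head — the multi-resolution idea of
high-resolution keypoint architectures at desk scale: six convolution
layers, ~11k parameters, stride-4 sigmoid output. It is implemented
directly on numpy (im2col convolutions with hand-written backward
passes, Adam), which keeps training exactly reproducible for a fixed
seed and fast enough (about a minute on one CPU for the ~600-frame
fixture corpus). The head bias is initialized at −4 so an untrained
model predicts near-zero probability everywhere.

Because the camera runs much faster than a transit, one cell yields
several per-frame detections. These are deduplicated into *tracks* by
greedy nearest-neighbour linking under a constant-velocity flow prior
(gate 2σ, one-frame gaps bridged); a track's confidence is the maximum
over its members — a cell is counted by its best view. The linking rule
is this package's own construction: the upstream system reports per-cell
counts without describing its deduplication.

## Training

Two streams: *negative* sessions (healthy-blood-like scenes; targets
identically zero, enforced) and *positive* sessions (cell-line-like
scenes; targets rendered from keypoints, in production from a
pseudo-labeling companion model, in the synthetic fixture from ground
truth). The pixel-wise loss is the asymmetric binary cross-entropy

    L = −A·[y·log p + (1−y)·log(1−p)],

with A = 0.1 where the stream is positive *and* the soft target is below
0.5 (an apparent false positive that may simply be a pseudo-label
omission) and A = 1 everywhere else. The 0.5 cutoff resolves how the
binary rule applies to soft Gaussian targets; at such pixels the
y·log p term is already near zero, so the down-weight acts on the whole
bracket. Predictions are clamped to [1e−7, 1−1e−7].

Class imbalance is addressed twice: `mine_hard_samples` is a one-shot
prefilter retaining only images whose maximum heatmap value under a
screening model reaches 0.3, and each epoch draws its batches from
sessions with probability proportional to their previous-epoch mean loss
(uniform fallback when all losses are zero; proportional rather than
rank-based weighting). Sessions are also the unit of the 80:20
train/validation split, so repeated captures of one cell can never
straddle the partition; the split asserts disjointness on every run.

Optimization: Adam, learning rate 0.01 decaying by 0.85 per epoch,
betas (0.9, 0.999), batch 16 (the fixture uses 8), per-parameter
gradient-norm clipping at 5 as a divergence guard, random (He)
initialization — no pretrained weights, which would be meaningless for
synthetic fringes. Non-finite loss aborts with a diagnostic. The
fixture trains 12 epochs on ~590 frames from 10 sessions, a size chosen
so the whole corpus regenerates and trains in about a minute while still
reaching ≥80% held-out recovery at the 0.5 operating threshold with zero
false keypoints on cell-free frames.

## Fluorescence pulse detection

The PMT baseline is a rolling median spanning 50 expected transit times
(computed as block medians at quarter-window spacing with linear
interpolation — an exact rolling median over tens of thousands of
samples buys nothing here), so pulses barely perturb it. The residual is
lightly smoothed with a boxcar of half the minimum pulse width before
characterization, so apex position and width are not set by single noise
samples. The noise scale is 1.4826x the median absolute deviation of
the residual, floored at 0.1% of the largest excursion — without the
floor, a noiseless synthetic trace has a degenerate MAD and the
threshold is meaningless. Excursions above `k_mad` (default 5) robust
standard deviations lasting at least a quarter transit are peaks;
excursions separated by less than half a transit merge. Width is full
width at half prominence; the peak score is amplitude over the detection
threshold, and a marker is called positive iff a matched peak has
score ≥ 1 (boundary inclusive).

Cross-channel matching and track–peak fusion both use greedy
one-to-one pairing committed in order of increasing |Δt| under a
tolerance of half a transit time. Greedy-by-|Δt| is preferred over
global assignment for streaming compatibility; the tests assert
equivalence with the optimal-assignment oracle at the low peak densities
rare-cell work actually produces. Pairing globally by |Δt| (rather than
walking tracks in time order) also prevents a low-confidence track
fragment from stealing the pulse that belongs to a better-centred track.

A practical constraint: the median baseline assumes pulses are sparse
in the analysis window. Above roughly 30% pulse duty cycle the baseline
and MAD inflate and detection degrades — at clinically meaningful cell
rates this regime never occurs, and the synthetic sessions respect it.

## Gating and enumeration

A fused event is a CTC iff its holographic confidence strictly exceeds
the operating threshold (default 0.5; "exceeds" is read as strict) and
every required marker is positive — PSMA alone by default. EpCAM is
recorded but never gates, because epithelial-to-mesenchymal transition
downregulates it in a clinically important fraction of tumor cells; the
EpCAM-positive fraction among counted CTCs is reported as phenotype.
Unknown marker status (absent channel) counts as negative — conservative
toward false positives. Counts are normalized to the initial whole-blood
volume; with no CTCs the EpCAM fraction is reported as null.

## Validation statistics

Predictions match references by spatial proximity: greedy one-to-one in
descending confidence, each prediction to its nearest unmatched
reference within 5.6 μm (2σ; the upstream description gives no number).
TP + FN equals the reference count and TP + FP the prediction count on
every instance. Recovery (TPR) at threshold θ is the fraction of true
cells whose per-cell maximum confidence exceeds θ; FPR is false
positives per mL; and at an assumed abundance *a* (cells/mL),

    PPV(θ) = TPR·a / (TPR·a + FPR_per_mL).

At TPR 0.6, FPR 5/55 per mL and a = 10 cells/mL this gives 0.985 ≈ 0.98.
The same recovery-curve machinery serves both buffer-only corpora
("theoretical" recovery) and spiked-blood-like corpora; the two differ
only in the synthetic corpus they are computed on.

## What the synthetic fixture does and does not show

The generator reproduces the *structure* of the real data streams —
fringe patterns whose scale and contrast grow with cell size and optical
thickness, constant-velocity transits, session-level background
variation, pulse widths tied to transit time, marker mixtures — but not
the hard parts of real blood: debris, cell aggregates, out-of-focus
jitter, platform-to-platform optical variation, or patient-derived
morphological heterogeneity. Passing the end-to-end fixture shows the
training loop, loss, extraction, linking, fusion and statistics are
internally consistent and reproducible; it says nothing about clinical
recovery rates, which require instrument data. The fixture geometry
(256x96 px field, 8 mm/s flow so a transit still spans ~5 frames,
140 cells/s arrivals) was chosen once to keep the full suite under a few
minutes on one CPU.

## Numerical choices and edge cases

- All randomness flows through named integer seeds into
  `numpy.random.default_rng`; identical seeds give bit-identical frames,
  traces, training runs and heatmaps.
- Heatmap-to-pixel coordinates: full-res = stride·index + (stride−1)/2;
  inputs are padded (edge mode) to the network alignment and the heatmap
  cropped back.
- `mine_hard_samples` returns retained *indices* so image/target pairing
  survives filtering. At desk scale there is no "earlier model" to
  screen with, so the pipeline and fixtures train on unfiltered streams;
  the operator is exercised directly by its own tests.
- Degenerate inputs are errors, not silent defaults: empty traces,
  non-positive volumes/gates/sigmas, thresholds outside [0, 1],
  mismatched shapes, negative radii, non-finite positions.
- Session HDF5 layout: `/sessions/<id>/frames` (float32), optional
  `truth/*` columns and `traces/<channel>`, with optics as attributes;
  times in seconds from session start, lengths in μm in metadata and
  pixels in arrays. Artifact CSV/JSON outputs embed the configuration
  hash.

## Known limitations

- The detector is a compact CPU model; it demonstrates the method, not
  state-of-the-art throughput or accuracy.
- Track linking assumes a single dominant flow direction and roughly
  constant velocity; recirculation or stalled cells would fragment.
- The PMT model is two channels with Gaussian pulses; no spectral
  unmixing, photobleaching, or >2-marker panels.
- Patient-cohort quantities (median counts per mL across cohorts,
  cohort-level EpCAM fractions) require clinical samples and are outside
  what synthetic data can certify.
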