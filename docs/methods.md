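# Methods

## Task and conditions

The simulated experiment is a prime–probe (S1–S2) event-file task. Each
trial presents a prime stimulus S1 requiring a pre-cued response R1, then a
probe S2 requiring a choice response R2. Crossing the response relation
(repeat/alternate) with the feature relation (repeat/alternate) between
S1–R1 and S2–R2 gives the four key conditions RRFR, RRFA, RAFR, RAFA; 384
task trials over 16 fine-grained conditions yield 24 trials per key
condition. Partial-repetition conditions (RRFA, RAFR) force reconfiguration
of the retrieved event file, producing reaction-time and error costs. All
epochs are time-locked to S2, spanning −7000…+2000 ms at 256 Hz (2304
samples; every window in the package is half-open `[a, b)` ms, so the
sample at t = 0 belongs to post-S2 and not to pre-S2). Trial periods of
interest are post-S1 [−2500, −1500), pre-S2 [−1000, 0), and post-S2
[0, 1000) ms.

## Forward model

A single homogeneous conducting sphere (conductivity 0.33 S/m, configurable)
replaces a boundary-element head model so that source-level analyses run
without any external geometry files. The surface potential of an eccentric
dipole has the classical Legendre expansion; summing it with generating
functions gives the exact closed form implemented in
`headmodel.spherical_leadfield`:

    4πσR²·V = p_r [2(c − x)/Q³ + (1/Q − 1)/x]
            + (p_t·(r̂ − c·û)) [2/Q³ + (Q + 1)/(Q(1 − xc + Q))],

with x = b/R the source eccentricity, c the source–electrode angle cosine,
and Q = |r − r₀|/R. The test suite checks this against an independently
coded 300-term spherical-harmonic series. Electrodes are a deterministic
golden-angle spiral over a 130° scalp cap (60 channels by default,
emulating an equidistant cap); lead fields are average-referenced. The
source space is a cubic lattice (default 5 mm) clipped to the open sphere,
ordered lexicographically so voxel indices and cluster identities are
reproducible. Geometric octant labels stand in for an anatomical atlas; an
"inferior-posterior" label plays the role of the excluded cerebellum, and
any user-supplied voxel-label table can replace them.

Known limitations: one homogeneous shell (no skull/scalp conductivity
contrast), no realistic electrode montage, no individual anatomy. These
affect absolute gain magnitudes but not the algebraic structure the
beamformer, clustering, and correlation stages operate on.

## Synthetic data

`synthdata` plants exactly the effects the analysis is built to detect.

*Behavior.* RT2 per trial is a shifted lognormal (shift 200 ms; positive
support and right skew; the task protocol does not prescribe an RT
distribution). Condition means are `base_rt + δ·1[RRFA or RAFR]`, so the
expected binding score is 2δ. Defaults: base 480 ms, δ = 35 ms (group means
around 58–71 ms imply δ ≈ 30–35), SD 100 ms, S1 accuracy 0.95, error
probability 0.05 + 0.09·1[partial] (expected error binding score 18
points). Group sizes default to 62 HC / 54 GTS with 24 trials per key
condition.

*EEG.* Each source is a dipole at a grid voxel with a band-limited
oscillation (default frequency at the band center: theta 6, alpha 10, beta
20 Hz), random uniform phase per trial, windowed to its active periods, an
amplitude table per period × condition (nA·m), projected through the lead
field with white sensor noise. Amplitude variability is multiplicative on
the power scale: a participant-level modulator (CV 0.25) shared by all of a
participant's trials times an independent per-trial modulator (CV 0.1).
The pre/post coupling ρ is implemented with a shared Gaussian latent with
loading √ρ on both members of the (post-S1, post-S2) pair — at both the
participant and the trial level — and the amplitude is `base·√modulator`,
so the coupling lives on the power scale and the group-level (participant-
unit) band-power correlation recovers ρ directly without a square-law
distortion. The generator does not emulate ocular/muscle artifacts, 1/f
background, or volume-conducted interactions between sources; passing
tests therefore demonstrate correctness of the analysis algebra and its
statistical calibration, not robustness to real-world artifact structure.

## Sensor-level analysis

Morlet wavelets with width 5 (five cycles at every frequency,
L2-normalized, zero-mean) give per-trial power; samples closer to the edge
than half the wavelet support are flagged invalid. Band power (theta 4–7,
alpha 8–12, beta 13–30 Hz) in 0–1000 ms is averaged into 50 ms bins — the
protocol reports significant sub-windows but not its binning, so the bin
width is a configurable declared choice. FR vs. FA is a paired t-test per
channel × bin, run separately under response repetition and alternation;
the BH family is all channel × bin cells of one (band, response) analysis
(the family definition is likewise declared, not inferred), with
zero-variance cells excluded. Adjusted p ≥ raw p always holds.

## Source-level analysis

The cross-spectral density uses a single Hanning taper per trial and window,
averaged over trials and over the FFT bins inside the band; the window must
cover one cycle of the band's lowest frequency. DICS filters are computed
from the CSD pooled over all trials of all four conditions ("common spatial
filter"), with diagonal loading λ·mean(diag C)·I, λ = 0.05 by default (the
protocol does not state λ; it is exposed in config and logged). The scalar
orientation per voxel minimizes `uᵀ Re(Lᵀ C_r⁻¹ L) u`, i.e. maximizes
unit-gain output power. Pre-trial maps are reported as the neural activity
index — power divided by the λ-level projected noise power
(λ·mean(diag C)·‖w‖²) — which cancels the depth bias of raw beamformer
power; post-trial maps are the per-participant FR/FA power ratio under RR
and RA, averaged across participants.

Cluster selection keeps the top 1 % of eligible labelled voxels: by signed
value for power/NAI maps, and by magnitude separately within the positive
and the negative side for ratio maps (contrast clusters of both signs are
meaningful); ties break by voxel order. DBSCAN with minPts 2 and
ε = 1.5 × spacing then reduces to connected components of the
ε-neighborhood graph (singletons are noise); 1.5 × spacing connects axial
and in-plane diagonal lattice neighbors but not √3-diagonal or two-step
neighbors.

LCMV uses the same unit-gain algebra on the real covariance of a period of
interest (per-trial channel means removed), with filters restricted to
cluster member voxels. Voxel series are averaged into one virtual channel
per cluster *before* the wavelet transform (raw-series averaging; the
alternative, averaging power across voxels, is a declared non-choice), then
per-trial band power is averaged over trials, giving one course per
participant. The post-S2 binding interaction is the participant-wise
FR − FA difference of these courses.

## Pre/post correlation

The observational unit is the participant: trials are averaged per
participant first, matching a group-level analysis (the protocol's unit is
not stated explicitly; this choice is declared). Element (i, j) of a
cluster-pair matrix is the Pearson correlation across participants between
pre-trial power at time i and post-trial power at time j; p-values come
from the exact t transform, and the BH family is the full matrix of one
cluster pair. Two thresholds are reported because the protocol itself uses
both: q < 0.01 (stated threshold) and q < 0.05 (reported in results);
the default mask uses 0.01 and the summary table carries both counts.

## Statistics layer

The Tukey fence uses linearly interpolated quartiles (numpy's default,
"type 7"); the convention is configurable because the protocol does not
name one. The 2×2 χ² applies the Yates continuity correction by default —
this reproduces the reference cohort's three printed demographic values
(0.14, 0.09, 12.34) exactly at two decimals, which the uncorrected form
does not. The mixed 2×2×2 ANOVA exploits the balanced within-subject
design: each within effect is evaluated on an orthonormal per-subject
contrast, turning every stratum into a two-group GLM whose Type III
(unweighted-marginal) sums of squares land on the classical scale even with
unequal group sizes; generalized η² divides each effect SS by that SS plus
all subject-related error SS. Degenerate inputs (zero SD, zero-variance
cells, missing condition means, zero table margins) raise or are excluded
explicitly rather than propagating NaNs silently.

## Validation experiments and problem sizes

`bindwave.experiments` packages the self-contained checks used by
`verify`, the test suite, and `scripts/acceptance.py`: single-dipole DICS
localization (100 replicates, 32 channels, 12 mm grid in a 6 cm source
sphere, 30 one-second trials, amplitude SNR 10, success = NAI argmax within
one grid step); coupling recovery (200 participants, ρ = 0.7, success =
mean matrix r inside the 95 % Fisher interval); DBSCAN vs. brute-force
ε-graph components (50 random 80-point sets); BH vs. the textbook step-up
definition (1000 random p-vectors); ANOVA vs. an explicit cell-means
decomposition; and null calibration (200 replicates of independent
12×12-time matrices at n = 30). These sizes keep the whole validation
under a few minutes on one CPU while leaving each check's sampling error
well inside its decision margin. The end-to-end pipeline test uses a
reduced desk-scale cohort (64 simulated EEG participants, 32 channels,
15 mm grid, theta band only, 12 trials per condition) with a high-SNR
source; EEG cohort sizes are a package choice — the planted parameters,
not the cohort size, carry the scientific content of the simulation.

## Degenerate-input and numerical conventions

Rejection windows step one sample; low activity is peak-to-peak within
100 ms (the metric is unstated upstream; peak-to-peak is declared).
Filters are zero-phase (forward–backward), order 8 Butterworth band-pass
0.5–40 Hz plus a 50 Hz notch; reflection padding of three time constants of
the low edge limits filtfilt transients, but a slow edge transient within
~1 s of the epoch boundaries is unavoidable with a 0.5 Hz zero-phase
high-pass. The power ratio is defined as 0 where both condition powers are
0. Regularized matrices with condition number above 1e12 raise with the
condition number in the message. All randomness flows through
`numpy.random.default_rng` seeds; equal seeds give bit-identical outputs.
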