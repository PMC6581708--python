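# Methods

`mstates` implements the standard resting-state EEG microstate workflow:
brief (~60–120 ms) periods during which the scalp potential topography
stays quasi-stable are identified, reduced to a small set of template
maps, fitted back to the continuous signal, and summarized per subject
by four temporal parameters that are then compared between two groups.
This note documents the models, the numerical choices, and what the
synthetic validation does and does not establish.

## Signal model and conventions

A recording is a `samples × channels` matrix in μV with a sampling rate,
an electrode montage (names + 3-D positions), and a per-sample exclusion
mask. Topographies are considered average-referenced and polarity
invariant: a map and its sign-flip are the same brain configuration.
Sample coordinates are 0-based with half-open intervals; milliseconds
appear only in reports. Class labels are 0-based; −1 marks unassigned
samples.

Global field power is the spatial standard deviation of the map at each
sample,

    GFP(t) = sqrt( Σ_i (u_i(t) − ū(t))² / N ),

a reference-free index of field strength. Spatial similarity between
maps is the Pearson correlation across channels; polarity invariance
takes its absolute value.

## Preprocessing

Stages, in canonical order, each also usable standalone:

1. **Band-pass** 1–50 Hz, 4th-order Butterworth, applied
   forward–backward (zero-phase). Since two passes square the magnitude
   response, the design cutoffs are pre-warped (analytic guess + a
   numeric polish on the actual response) so the *combined* response is
   −3 dB at the stated cutoffs.
2. **Optional cleaning hook** — component-based artifact removal is
   delegated to an externally supplied callable; the package only
   provides the eligibility rule (more than `20·N²` samples for a
   reliable decomposition).
3. **Decimation** by 4 (500 → 125 Hz) with a zero-phase FIR
   anti-alias filter. The exclusion mask decimates conservatively: a
   new sample is excluded if any constituent original sample was.
4. **Average re-reference** (idempotent; leaves GFP unchanged).
5. **Spatial smoothing**: each channel mixes with its 6 nearest
   neighbors using inverse-distance weights normalized to unit sum,
   keeping a self fraction `strength/(strength+1)` (default strength 1;
   `strength → ∞` is the identity). The kernel is this package's own
   stand-in for coordinate-based topographic smoothing in commercial
   toolboxes, whose exact kernel is unpublished; it is instantaneous
   (no temporal mixing).
6. **Amplitude rejection**: every sample within 0.5 s (inclusive in
   time, i.e. |Δt| ≤ pad) of any sample where any channel exceeds
   100 μV in magnitude is excluded. Data values are never modified, the
   mask only grows, so the stage is idempotent and monotone. The
   amplitude test is evaluated after average re-referencing.

## Segmentation (two-step clustering)

Maps at local GFP maxima (strict rise, plateau-tolerant fall; peaks on
or adjacent to excluded samples dropped) are clustered per subject with
a polarity-invariant modified k-means:

* **assignment**: each map goes to the template with the highest squared
  spatial correlation (sign-blind);
* **update**: each template becomes the dominant eigenvector of the sum
  of outer products of its member maps at their original amplitudes.
  This is the polarity-invariant mean — plain averaging would cancel
  sign-flipped members — and, because members keep their amplitude, one
  sweep is exact coordinate ascent on the GFP-weighted global explained
  variance (an amplitude-blind update would not ascend that objective
  when map strengths differ).

GEV of a solution is `Σ_t (GFP(t)·C_t)² / Σ_t GFP(t)²` with `C_t` the
correlation to the assigned template. Restarts (default 50) initialize
from random distinct maps; when the distinct k-subsets number fewer than
the restart budget they are enumerated exhaustively instead, which makes
small instances provably reach the brute-force partition optimum.
Convergence is assignment stability (followed by an exact eigensolve
polish) or a relative GEV change below 1e−6; empty clusters reseed from
the worst-fit map. Everything is deterministic given a seed.

**Model selection** uses a meta-criterion: seven cluster-validity
indices — Krzanowski–Lai, Calinski–Harabasz, silhouette,
Davies–Bouldin, a cross-validation criterion with a degrees-of-freedom
penalty, a gap statistic against unstructured reference maps, and the
GEV-elbow (largest concavity of GEV(k)) — all evaluated on the
polarity-invariant dissimilarity `d² = 1 − C²`. Each criterion that is
defined on the instance votes for one k; the lower median of the votes
wins (ties favor fewer clusters), and with no usable votes (e.g. all
maps identical) the range floor is returned. The battery membership and
the median-vote combiner are this package's choices; both are
configurable in code. The k range searched defaults to 2–10.

The **group step** pools every subject's individual templates with unit
weight and re-runs clustering plus model selection on the pool. Group
classes are ordered by descending explained-variance share; optional
cosmetic naming (A–F) matches them greedily to a user-supplied
reference set by |correlation|.

## Back-fitting and temporal smoothing

Each non-excluded sample is labeled winner-takes-all by |spatial
correlation| with the group templates, but only when the winning
correlation exceeds 0.5. Temporal smoothing then iteratively relabels
each sample to the class `u` maximizing

    (GFP(t)·C_u(t))² + λ · (2σ²/(N−1)) · n_u(t, b)

with λ = 10, window half-size b = 3, `n_u(t,b)` the number of
currently-`u` samples within `t ± b` (excluding `t`; unassigned and
excluded samples never count as neighbors), and σ² the mean squared
residual norm of the current fit, `σ² = N · mean(GFP²(1−C²))` over
assigned samples. Sweeps are synchronous left-to-right and stop at a
fixed point (two-cycles keep the current state; a 100-iteration cap
sets a non-convergence flag).

**Role of the correlation floor.** The floor is treated as evidence
weighting inside the smoothing objective, not as a frozen state: a
sample whose best |r| is at or below 0.5 contributes no data term and is
captured into a class only when its temporal neighborhood supports one;
with no support it stays unassigned. The alternative — freezing
sub-floor samples as permanently unassigned — systematically chops
stable states in two wherever the alpha-band amplitude envelope dips
(in the synthetic model, at every carrier zero crossing), producing
exactly the single-sample interruptions the smoothing stage exists to
remove and biasing mean durations down by ~25 ms. Excluded and
zero-variance samples are never labeled, and λ = 0 leaves the initial
labels untouched.

Maximal runs of one class become segments; unassigned and excluded
spans break runs, and runs abutting an excluded span or a recording
edge are flagged truncated.

## Temporal parameters and statistics

Per class and subject: **mean duration** (ms; truncated segments
excluded by default since they under-observe dwell time — configurable),
**occurrence** (segments per analyzed second; truncated segments count),
**coverage** (fraction of analyzed samples carrying the class; unassigned
time stays in the denominator), and **GEV** (class-wise
`Σ_{t∈u}(GFP·C_u)² / Σ_{analyzed} GFP²`, so class GEVs sum to the total).
When no unassigned or excluded samples exist and truncated segments are
included, `duration × occurrence = coverage × 1000` holds exactly.

Groups are compared per (parameter, class) cell with a two-tailed
Mann–Whitney–Wilcoxon test: exact null enumeration when the combined
sample size is ≤ 12 without ties, otherwise the normal approximation
with tie and continuity corrections (at the reference cohort sizes of
10 vs 13 the approximation applies). A cell with U exactly at n₁n₂/2
reports p = 1. Benjamini–Hochberg FDR correction is applied **within
each parameter's family of classes** (so 4 families rather than one
pool of all cells) at α = 0.05. This family structure is the one that
reproduces the reference table's corrected values from its pairwise
values exactly; pooling all cells does not. Subjects missing a cell
(class never observed) are dropped from that cell's test only.

## Synthetic data generator

The generator emulates 65-channel, 500 Hz eyes-closed resting EEG with
known ground truth:

* **Montage**: Fibonacci lattice on the upper unit hemisphere (seeded
  azimuthal rotation).
* **Templates**: fields of random dipole pairs projected to the
  montage — spatially smooth, average-referenced, unit GFP — with
  pairwise |r| ≤ 0.7 enforced by rejection sampling.
* **State sequence**: semi-Markov; next class uniform over the other
  classes; dwell times gamma-distributed (mean 80 ms, shape 4 — the
  shape avoids sub-sample dwells while giving realistic variability),
  rounded to ≥ 1 sample.
* **Rendering**: `signal(t) = s·A·|sin(2π·10·t + φ)|·T[label(t)] +
  noise(t)` with per-segment random phase φ and polarity s (so polarity
  invariance is exercised end-to-end) and A set per segment so that
  segment-mean template power / noise power equals the configured SNR
  (default 4). The rectified 10 Hz envelope makes GFP peak twice per
  alpha cycle, as in real eyes-closed data.
* **Noise**: per-channel std 5 μV; 70% of the power is spatially
  correlated pink noise (channel mixing by a Gaussian kernel of length
  0.6 chord units on the unit sphere — resting EEG background is
  dominated by a few smooth generators, so inter-electrode correlations
  are high) and 30% is white sensor noise.
* **Artifacts**: Poisson events (default 2/min) of ~50 ms-std Gaussian
  bumps peaking at 200 μV, weighted toward frontal (+y) electrodes, with
  peak times recorded in the ground truth.

Defaults (180 s duration, 500 Hz, 65 channels) mirror the acquisition
conditions the generator emulates. What the generator does **not**
model: biophysical forward solutions (no head conductor model), eye
movements and muscle spectra beyond generic transients, non-stationary
alpha reactivity, inter-subject topographic variability (a cohort shares
one true template set). Passing recovery tests on this model therefore
demonstrates correctness of the algorithms under controlled conditions,
not field performance on clinical recordings.

## Validation experiments and problem sizes

The test suite validates each stage against hand-computed values and
independent oracles (filter frequency responses, exhaustive two-partition
clustering, exhaustive Mann–Whitney enumeration, brute-force smoothing
objective on 12-sample sequences), plus three simulation experiments:

* **Recovery**: a 23-subject cohort (10 vs 13), 4 true classes, 80 ms
  dwell, SNR 4, 60 s per subject. The full two-step pipeline must pick
  k = 4, recover every template with |r| ≥ 0.95, estimate cohort mean
  duration within ±10 ms, and spread coverage within ±0.05 of 1/4.
* **Calibration**: 200 null cohorts (both groups generated identically,
  20 s subjects rendered at 125 Hz against the true templates) must keep
  the per-cell FDR-corrected rejection rate ≤ 7.5% at α = 0.05. The
  four classes of one parameter are positively dependent within a
  subject, so after BH correction per-cell rates sit near α rather than
  α/m; 200 cohorts keep the binomial noise of the estimated rate well
  inside the bound.
* **Determinism**: a fixed manifest + seed reproduces outputs
  byte-for-byte; per-subject random substreams are keyed by subject id,
  so manifest order does not matter.

Subject durations of 60 s (recovery) and 30 s (calibration) are this
package's chosen validation sizes; the generator's default remains
180 s. `scripts/acceptance.py` reruns the recovery experiment and the
reference-table FDR reproduction from scratch and writes the measured
quantities to JSON.

## Known limitations

* The meta-criterion battery is a principled but non-unique choice; on
  weakly structured data different batteries can prefer different k.
* The spatial-smoothing kernel and the smoothing-floor interaction are
  declared stand-ins for unpublished tool internals.
* EDF export is minimal (16-bit, 1 s records, final record padded);
  annotations and discontinuous records are not supported.
* Group clustering weights each pooled individual template equally;
  subjects with more individual templates contribute more maps.
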