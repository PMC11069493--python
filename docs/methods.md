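# Methods

## Head model

The forward problem is solved on an idealized spherical head instead of a
subject-specific boundary-element model.  Three concentric shells represent
brain, skull and scalp with outer radii 87 / 92 / 100 mm and conductivities
0.3 / 0.006 / 0.3 S/m (the standard ~1:50 skull contrast).  This keeps the
two properties of volume conduction that the benchmark exercises — skull
attenuation and spatial blurring of the scalp topography — while removing
every data dependency; it does not reproduce subject anatomy, so absolute
localization errors from this model are comparable across configurations of
the benchmark, not with errors from anatomical head models.

**Montages.**  Electrode positions are generated by the proportional-arc
(10-20) construction: nasion, inion and the preauricular points define the
midline and central arcs; each coronal row is the circle through its midline
point and its two crossings of the 10%-circumference ring, subdivided in 5%
steps; electrodes below the ring sit on two lower circles (5% and 10% below).
The full 5% grid with the legacy temporal synonyms (T3/T4/T5/T6) and without
ear/mastoid positions yields exactly 339 labels; a test cross-checks this
label set against the published 10-05 table shipped with MNE-Python.  The
10-10 montage is the classical 72-electrode chart (F/FC/C/CP/P chains to the
9/10 ring, sparse AF/PO rows, Fp/O triplets, Iz), a strict label subset of
the 10-05 set.  Cz is the vertex by construction.  Montages can also be read
from and written to `.sfp`-style text files.

**Source space.**  Each hemisphere holds a Fibonacci-style lattice of
radially oriented unit dipoles on a 78 mm shell, restricted to the cap
z ≥ −20 mm (a cortex-sheet stand-in: no sources at the skull base, where no
electrodes exist).  The right hemisphere mirrors the left, so the space is
exactly midsagittally symmetric; the lattice's azimuthal phase comes from the
seed.  Default 4098 dipoles per hemisphere (8196 total); the mean
nearest-neighbour spacing at that density is ≈ 3 mm, which bounds the
resolution of any localization-error number the benchmark produces.

**Lead field.**  The potential of a dipole in the layered sphere is evaluated
from its Legendre expansion.  Per degree *n*, continuity of potential and
radial current at the two interfaces plus zero normal current at the scalp
give a 5×5 linear system whose solution yields the scalp-surface radial
profile; radii are non-dimensionalized by the scalp radius so the systems
stay well conditioned at high degree.  Radial and tangential moment
components are handled by the associated-Legendre term with the sine factor
removed (no singularity at the pole), so arbitrary orientations are
supported even though the default sources are radial.  The series is
truncated at 100 terms: the tail decays like (b/R)^n ≈ 0.78^n, giving a
~4·10⁻⁸ relative truncation error at the default geometry, comfortably
below the 10⁻⁶ the convergence test demands (60 terms would sit near that
bound, hence the larger default).  Columns are average-referenced.  The
implementation was validated against the closed-form homogeneous-sphere
dipole potential (equal conductivities) and against a finite difference of
the layered monopole expansion (arbitrary orientations).

## Simulated localization benchmark

Each trial activates one "main" source in the hand-knob regions of interest
and two background sources.  The ROI is the union of the 20 nearest sources
to each of two seed markers; the default markers are the scalp directions of
C3/C4 — the electrodes classically overlying the hand motor cortex — scaled
to the cortical shell, giving 40 ROI sources.  Time courses are
Gaussian-windowed sinusoids `a·exp(−½((t−c)/σ)²)·sin(2πft)`: the main source
at 10 Hz, amplitude 1, center 1 s, width 0.12 s, in 2 s epochs at 250 Hz
(sampling rate is the package's choice; only ratios of amplitudes matter for
localization).  Two epochs per ROI source give 80 trials.  Background
sources (amplitude 10% of the main, widths 0.12 s, frequencies 5 and 20 Hz)
are drawn uniformly per trial from sources outside the ROI and at least 3 cm
from the main source; per-trial RNG streams are spawned from the master seed,
so the set is bit-reproducible.

Sensor noise is i.i.d. Gaussian across channels and samples, with variance
set so that 10·log₁₀(P_signal/P_noise) matches the nominal SNR with powers
averaged over the whole epoch set (a per-trial variant is available by flag);
the realized SNR is recomputable from the stored clean data and is within
±0.01 dB of nominal at these data sizes.  The supported grid is 10, 5, 0 dB.

## Inverse solvers

wMNE and sLORETA as defined in the README.  Numerical choices:

* All kernels are computed by symmetric solves; no explicit inversion.  At
  λ² = 0 (the noiseless/exactness path) an eigendecomposition pseudo-inverse
  with relative cutoff 10⁻¹⁰ is used, since the average-referenced Gram
  matrix is rank-deficient by one.
* λ² defaults to `trace(MMᵀ)/n_channels · 10^(−SNR_dB/10)` (standard
  noise-power scaling); λ² = 0 when the data are noiseless.
* Channel masks remove rows of `M` and `y` physically; the mathematically
  equivalent "zero the excluded rows" formulation is kept as a test oracle.
* Source power is the sum of squares over the full epoch window; the peak is
  the argmax with ties broken at the lowest source index.  Localization
  error is reported in millimeters.

sLORETA's zero-error property for noiseless single sources holds exactly in
this implementation (verified source-by-source on reduced models and on the
full 339×8196 problem).  At 0 dB with all 339 channels the mean error over
the 80-trial benchmark remains 0.00 mm: the power integrates the
Gaussian-windowed event over the whole epoch while the white noise spreads
over all spatial directions, so the ROI peak survives.  With few channels
errors grow and decrease monotonically with SNR, which the suite checks at
Monte-Carlo tolerance.

## Channel-subset search

NSGA-II over binary chromosomes of length g (one gene per candidate
electrode), minimizing the pair (mean LocE over *all* epochs — one
combination for the whole dataset, not per epoch — and the channel count).
Elitist loop: fast non-dominated sort with crowding distance, binary
tournament selection, uniform crossover (rate 0.9), per-gene bit-flip
mutation (rate 1/g), population 100 × 100 generations by default (standard
settings at this chromosome length; the paper-scale run is compute-heavy,
tests and examples use reduced problems).  Constraints:

* search-space restriction (e.g. the 10-10 labels) and cascade parenthood
  are enforced structurally — initialization and mutation only touch allowed
  genes;
* hemispheric symmetry (equal left/right counts, read from label digit
  parity; midline z-labels exempt) is enforced by rejection: violating
  offspring are discarded and redrawn, with a hard error after 10⁴
  consecutive rejections (an infeasible constraint set).

Initial masks draw their channel count uniformly in [4, g/2] to seed the
whole front.  Every evaluation is memoized by mask and archived with its
discovery generation; the Pareto front and the best combination per channel
count are extracted from the archive.  The cascade runs nested searches for
strictly decreasing target counts, each stage restricted to the best mask of
the previous stage (falling back to the nearest achieved count with a
warning).  `mirror_expand` adds each selected channel's opposite-hemisphere
partner (digit parity swap) to turn an asymmetric optimum into a symmetric
cap.  Correctness anchors: the non-dominated sort is tested against an O(n²)
pairwise oracle, and the search against exhaustive enumeration on problems
small enough to enumerate.

## Motor-imagery generator and classification

The generator emulates the physiology a left/right-hand BCI decodes, not a
recording session.  Both hand-knob ROIs carry ongoing 10 Hz mu rhythm whose
generators oscillate coherently within a knob (a common per-trial phase with
0.2 rad per-source jitter — local synchrony is what the (de)synchronization
terminology refers to); after the cue (t = 0 in the −1…3 s epoch) the ROI
contralateral to the imagined hand is attenuated by the ERD depth (default
50%) with a 100 ms ramp.  One hundred non-ROI sources carry broadband
background activity (amplitude 0.3 relative to mu amplitude 1) and white
sensor noise is added at 10 dB.  Trial-to-trial mu amplitude varies
lognormally per source (σ = 0.1); this is the generator's design point — the
dataset is *well separated by construction*, so a correct CSP+LDA pipeline
scores high (≈0.97 source space at defaults), chance on shuffled labels, and
exactly chance when the ERD depth is zero.  What the generator does **not**
emulate: 1/f background spectra, ocular/muscular artifacts, non-stationary
noise, inter-subject variability.  Passing tests therefore certify the
pipeline's mechanics and relative comparisons (source vs electrode space,
channel counts), not absolute decodable accuracy on real recordings.

The classification protocol follows the split-first rule: the channel subset
is taken *before* the common average reference so discarded channels cannot
leak into the reference; then zero-phase Hamming-window FIR filters (notch
at 50/100 Hz when below Nyquist, optional 0.1 Hz high-pass when the epoch
supports the FIR length, 8–12 Hz band-pass with 2 Hz transitions).  Source
features are the sLORETA time courses of the 40 ROI sources; the transform
is linear and label-free, so applying it before cross-validation cannot leak
class information.  CSP solves `C_A v = λ(C_A + C_B) v` on trace-normalized
class-mean covariances, keeps 3 filters per spectral extreme (6 components),
and emits log-variance features; a rank-deficient composite covariance
(inevitable after CAR) is ridge-regularized at 10⁻⁸ of its eigenvalue scale
with a warning.  Evaluation is 10 repeated stratified 70/30 shuffle-splits
("repeated hold-out" — the operational reading of a 70/30 "10-fold" scheme):
CSP, the per-feature standard scaler, and the classifier (RF, RBF-SVM, or
LDA at library defaults) are fit on the training split only; accuracy,
precision, recall and F1 are computed exactly from each fold's confusion
matrix, with 0/0 quotients reported as 0 and flagged.  Everything is
deterministic given the seed.

## Pipeline, configuration, reproducibility

A single JSON document (pydantic-validated, unknown keys rejected) describes
a run; every random draw derives from the master seed through named
SeedSequence spawn streams, with no global RNG state.  Artifacts are written
as text tables (CSV), `.npz` array containers with JSON sidecars, and
`.sfp` montage files; reruns with the same configuration are byte-identical.
Stage failures are logged and isolated; the CLI exits non-zero if any stage
fails.

**Problem sizes.**  The suite runs the montage/forward validation, the
localization properties and the GA oracles on reduced models (72 channels,
100–300 sources per hemisphere, 20-channel search problems), and the
exactness/robustness checks plus `scripts/acceptance.py` on the full
339-channel, 8196-source configuration — the package's study conditions.

## Known limitations

* The spherical shells preserve volume-conduction structure but not anatomy;
  absolute millimeter errors are not comparable to BEM-based studies.
* Radial-only default orientations make deep/tangential configurations
  (e.g. sulcal walls) unrepresented.
* The source lattice's ~3 mm spacing quantizes localization error.
* The third conductivity value is a package default (0.3 S/m, brain); skull
  conductivity in particular varies several-fold across individuals and is
  not explored here.
* The default GA budget (100×100) is sized for the full problem and is
  compute-heavy on one CPU; reduced budgets explore less of the front.
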