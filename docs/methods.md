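# Methods

## Per-voxel outcome regression

The analysis treats tissue fate after hemispheric ischemic stroke as a
voxel-wise regression problem.  For every voxel inside the lesion and
contralateral-normal regions of interest, four acute-phase MRI intensities
(DWI, T1WI, T2WI, PDWI) predict the voxel's T2-weighted intensity at ~3
months, on a normalized scale where the brain mean of every channel is 1.
The continuous framing matters: the chronic T2WI is itself approximately
continuous, and a continuous predictor yields graded outcome maps rather
than hard segmentations.  Binary lesion/normal labels are retained only
for ROC-style evaluation; they never enter the training loss.

Assumptions inherited by everything downstream: all channels of a subject
are co-registered (registration itself is out of scope; phantoms can
emulate residual mis-registration with an integer-voxel shift of the
chronic channel), and intensity normalization to the in-brain mean removes
scanner-gain differences between subjects.

## Preprocessing

1. **Smoothing.** Every slice of every channel (chronic target included)
   passes through a 3×3 unity (box-mean) filter, damping mis-registration
   noise.  Borders use edge-reflected padding so brain-edge voxels are not
   darkened the way zero padding would darken them.
2. **Brain mask.** Voxels of the smoothed acute T2WI at or above a
   configurable fraction (default 0.10) of the slice stack's maximum.
3. **Normalization.** Each channel is divided by its in-mask mean over the
   *whole* study — one mean per channel per subject, not per slice, so
   inter-slice contrast survives.  The result is exactly invariant to any
   positive gain applied to a channel.
4. **ROIs.** The lesion ROI is the supra-threshold region of the
   normalized chronic T2WI.  The threshold is a required configuration
   value (clinically it is the reader's outline of the infarct; there is
   no principled default, and 1.4 is used for phantoms whose lesion and
   normal chronic means are 1.8 and 1.0).  The normal ROI is the lesion
   ROI mirrored across the brain midline — by default the image's central
   column axis, configurable for tilted geometries.  Mirrored voxels
   falling outside the grid are dropped; mirrored voxels colliding with
   the lesion (midline-crossing lesions, midline CSF) are removed from the
   normal mask with a warning.  This construction yields a lesion
   prevalence slightly above 50% (≈ 0.56 on default phantoms) because the
   collisions are debited from the normal side only.  An optional
   prevalence-targeting step resizes the normal mask boundary-first to a
   requested prevalence (±2 points); it is off by default because
   prevalence is an outcome of ROI drawing, not a constraint.

Voxel coordinates are 0-based `(slice, row, column)`; masks are plain
boolean arrays over the study grid.

## Network and training

Architecture `[4+1 bias] : [3+1 bias] : [3+1 bias] : 1`, 31 free
parameters by `sum((fan_in + 1) · fan_out)`.  Hidden activations are the
bipolar sigmoid realized as `tanh` (identical up to reparameterization and
the easiest polar-mode implementation).  The output unit applies
`y = (hi−lo)/2 · (tanh(a) + 1) + lo` with `[lo, hi] = [0, 3]`, so
predictions live strictly inside the normalized-intensity range and an
all-zero network outputs exactly 1.5, the range midpoint.

Training is batch back-propagation: the MSE gradient is accumulated over
**all** samples and applied as one update per epoch,
`Δw = −lr · ∇MSE + momentum · Δw_prev`, with defaults lr = 0.01 and
momentum = 0.  Numerical choices:

* **Cost** is the *mean* of squared residuals on the 0–3 output scale
  (not the sum, so the learning rate's meaning is independent of sample
  count; not a rescaled [−1,1] residual, so the termination error of
  ≈ 0.06 is interpreted on normalized chronic-T2 units).
* **Initialization** uniform [−0.5, 0.5] including biases, seeded.
* **Termination** checks the pre-update MSE each epoch, so a network that
  already satisfies the criterion is never perturbed further; failing to
  reach the criterion within the epoch budget logs a warning and returns
  the final weights rather than raising.
* Bare-library default epoch budget is 1,000; the pipeline raises it to
  3,000 because plain batch descent at lr 0.01 needs roughly 1,000–2,000
  epochs to reach termination errors near 0.05 at phantom sample sizes
  (~1.5k voxels/subject).

Gradient correctness is pinned by a central-finite-difference oracle
(relative error < 1e-5 on random networks and samples).

## Cross-validation, stopping and model selection

Folds are subjects: leave-one-out with K = number of patients (12 in the
emulated cohort), so no subject's voxels ever straddle train and test.
Per-fold seeds derive deterministically from (global seed, fold index).

The stopping rule reads the pooled held-out CCF curve from a fixed-epoch
validation run.  CCF at an epoch is the fraction of held-out voxels whose
prediction and observed value share a 0.05-wide discretization window;
pooling across folds is voxel-weighted (equivalently, the CCF of the
concatenated held-out predictions), with fold traces aligned by truncation
to the shortest.  The plateau is estimated as the mean CCF over the final
10% of epochs, and the stopping epoch is the first epoch whose CCF is
within 10% of that plateau — both fractions are configuration knobs, since
"10% of the plateau" admits more than one reading; this implementation
logs its interpretation.  The mean of the per-fold training MSEs at the
stopping epoch is the common termination error, and the final
leave-one-out networks are trained to that error.

**The validation run must actually reach the plateau.**  On an
unconverged curve, the "plateau" estimate is still low, and transient CCF
fluctuations in the first few epochs (as the freshly initialized network
sweeps its output through the data mass) can exceed 90% of it, stopping
training absurdly early.  The pipeline default of 2,000 validation epochs
puts the plateau (CCF ≈ 0.12–0.13 on default phantoms, against a
theoretical ceiling of ≈ 0.13 set by target noise of SD 0.15 within a
0.05 window) well above those transients.

Architecture search maximizes the AUCCF — the trapezoidal area under the
pooled CCF curve normalized by its span, so a constant curve of height c
scores c — over candidate second-hidden-layer sizes, with ties broken
toward fewer neurons.  The first hidden layer is fixed at 3 (smaller first
layers fail to train on this task).  The search is off by default in the
pipeline; the 4:3:3:1 default is the selected architecture of the emulated
study design.

## Evaluation statistics

* **Discretization**: bin `floor((v − lo)/window)` over [0, 3] with
  window 0.05; the exact upper bound joins the last bin, out-of-range
  values are clipped and logged.  The CCF match rule is *same bin* by
  default; a `|Δ| ≤ window` tolerance rule is available behind a switch
  because the windowing description is ambiguous between the two.
* **ROC/AUROC**: thresholds at midpoints between consecutive distinct
  scores plus ±∞ sentinels; tied scores move between operating points
  together, making the trapezoidal area identical (to 1e-12, tested) to
  the tie-corrected Mann–Whitney pair-counting probability.
* **Half-angle operating point**: the intersection of the piecewise-linear
  ROC with the descending diagonal TPF = 1 − FPF, linearly interpolated
  within the crossing segment, so sensitivity = specificity exactly at the
  returned point.  This is the sensitivity-equals-specificity reading of
  the "half angle" construction (the descending 45° line from (0, 1)),
  which by design yields a single near-equal sensitivity/specificity pair.
* **Cluster-adjusted correlation**: OLS of observed on predicted chronic
  intensity over all voxels; the slope variance uses the cluster sandwich
  (sum over patients of within-cluster score outer products, no
  small-sample correction factor) and the two-sided p comes from a t
  reference with (clusters − 1) degrees of freedom — the conventional
  small-G choice.  Pearson r is reported alongside.  Cross-checked against
  statsmodels' cluster covariance in the tests.

## Phantom generator

The generator emulates the statistical structure the analysis assumes, at
desk scale: default 12 subjects × 7 slices of 40×40 voxels (real cohorts
are 83 slices of 256×192, emulated here at reduced resolution so the full
pipeline runs in minutes).  Per slice, an elliptical brain sits in a zero
background with three tissue classes: normal parenchyma, a disk-shaped
ischemic lesion in one hemisphere, and a mid-line CSF disk.  Channel
intensities are class-conditional Gaussians truncated at zero, on the
brain-mean ≈ 1 scale:

| class  | DWI | T1WI | T2WI | PDWI | chronic T2 | SD        |
|--------|-----|------|------|------|-----------|-----------|
| normal | 1.0 | 1.0  | 1.0  | 1.0  | 1.0       | 0.12      |
| lesion | 1.6 | 0.9  | 1.5  | 1.3  | 1.8       | 0.15      |
| CSF    | 0.5 | 0.6  | 2.2  | 1.4  | 2.4       | 0.15      |

These defaults encode the qualitative contrasts the method exploits —
lesion bright and CSF dark on DWI, both bright on chronic T2 (the
ambiguity the network must resolve), lesion mildly dark on T1 and bright
on T2/PD — at effect sizes typical of subacute infarcts on normalized
clinical images (lesion/normal DWI separation ≈ 4 pooled SDs, chronic-T2
separation ≈ 6).  Spatial coherence comes from smoothing the *noise
field* (Gaussian kernel, σ = 0.8 voxels, per slice, renormalized to unit
variance) while class boundaries stay crisp, so mask-based counting tests
are exact.  The chronic lesion geometry may differ from the acute one to
emulate growth or recovery (default: identical), and an optional
integer-voxel shift of the chronic channel emulates residual
mis-registration (default off — no magnitude is established for it).  An
optional per-subject geometry variation jitters lesion centre and radius.
All randomness descends from one seed through `numpy.random.SeedSequence`
spawning: one child per subject, then one per channel.

What the phantom does **not** emulate: MR physics (no TR/TE/b-value
signal equations), partial-volume gradients at tissue boundaries,
heterogeneous lesion substructure (a salvageable penumbra vs core is not
parameterized — the generator exposes only one lesion class), anatomical
asymmetry between hemispheres, and field-inhomogeneity bias.  Passing the
phantom-recovery tests therefore demonstrates that the pipeline's
machinery is correct and self-consistent, not that clinical data of this
kind would yield comparable accuracy: clean phantoms reach held-out AUROC
≈ 0.99 and r ≈ 0.90 (the acceptance script's numbers), and clinical
cohorts with real noise sources should be expected to land well below
that.

## Degenerate inputs and tie-breaks

Empty lesion masks, empty brain masks, non-positive normalization means,
single-class label vectors, fewer than 2 subjects/clusters and duplicate
subject ids all raise immediately with named messages.  Lesion geometry
leaving the grid names the offending slice.  Architecture-search ties go
to the smaller network; boundary-voxel peeling in prevalence targeting
orders by depth then flat index, so every resize is deterministic.

## Problem sizes

Default study conditions: 12 subjects, 7 slices each, 40×40 grid,
≈ 17,000 ROI voxels, 2,000 validation epochs and an epoch budget of 3,000
for the final folds.  The full pipeline completes in ~2–3 minutes on one
CPU; the test suite's end-to-end check uses the same conditions.
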