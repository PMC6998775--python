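# Methods

This note records the statistical model behind each step of the assembly
workflow, the defaults and why they were chosen, what the synthetic data
generator does and does not emulate, and the numerical conventions a user
relying on the outputs should know.

## Symmetry and resolution machinery

Miller indices are reduced to a canonical asymmetric-unit representative
defined as the **lexicographic maximum over the full orbit**
{R·hkl} ∪ {−R·hkl} of the point group's rotations R.  This convention is
point-group agnostic (no per-group ASU tables), trivially testable, and
idempotent.  A Friedel sign accompanies every reduction: +1 when the
rotation-only orbit of the input reaches the canonical index, −1 when only
its Friedel mate does.  Acentric Bijvoet mates therefore receive opposite
signs — the property anomalous merging actually needs — while centric
reflections get +1.  No claim is made that this ASU matches any external
program's convention; all statistics here are internally consistent.

Eleven rotation point groups are built in (1, 2, 222, 4, 422, 3, 32, 6,
622, 23, 432; trigonal/hexagonal in the hexagonal-axes setting, 32 in the
321 orientation, monoclinic b-unique), generated by closure from hard-coded
generators and validated (identity, closure, determinant ±1) at
construction.  Space-group symbols common in macromolecular work
("p2221", "P43212", …) are reduced to their point group by lookup.
Arbitrary user-supplied rotation sets are accepted and validated.
Systematic absences, centring and cell reduction are out of scope.

d-spacings use the full triclinic reciprocal metric.  Unique-reflection
enumeration scans the index box |h| ≤ a/d_min, |k| ≤ b/d_min, |l| ≤ c/d_min
(exact bounds, since h = s·**a**) and counts canonical representatives;
this count is the completeness denominator.  The enumeration assumes the
cell is compatible with the point group (a tetragonal group with a ≠ b
would mix resolutions within an orbit).

## The statistics engine

*Scaling.*  One multiplicative scale per crystal, fit in closed form
against a reference (the first crystal by sorted id, scale ≡ 1):
k minimises Σ w (I_ref − k·I_crys)² over canonical reflections observed by
both, with weights from the propagated standard errors of the
per-reflection means.  Crystals sharing no reflections with the reference
fall back to k = 1 with a warning.  No B-factor, no per-frame scaling, no
error-model refinement: the assembly logic needs relative consistency and
determinism, not absolute scale.  Scales are fit once per class on the
full class and held fixed through the rejection loops, so ⟨SmRmerge⟩
rankings stay comparable across iterations (re-scaling mid-loop would also
break down when the reference crystal is itself rejected).

*Merging.*  Observations are scaled, ASU-reduced, cut at d ≥ d_min and
combined by inverse-variance weighted mean; merged σ = (Σ σ⁻²)^(−1/2).
Friedel mates are kept separate in anomalous mode.  Negative intensities
are retained everywhere (post-background-subtraction reality); clamping
happens only at amplitude export.

*Rmerge / Rmeas.*  Standard definitions over reflections with
multiplicity ≥ 2, with the unweighted reflection mean:
Rmerge = Σ|I_i − ⟨I⟩| / ΣI_i; Rmeas multiplies each reflection's numerator
by √(n/(n−1)).  Undefined (no multiply-observed reflection) is reported as
`None`, never 0.

*CC½.*  Implemented literally as a half-dataset correlation: each
multiply-observed reflection's observations are shuffled (seeded) and dealt
alternately into two halves; the Pearson correlation of the per-half
unweighted means is returned.  The random-split route was chosen over the
σ²/τ² analytic estimator because it matches the definition directly and is
easy to oracle-test (noise-free data give exactly 1.0 for every seed; the
additive-noise expectation σ_s²/(σ_s²+σ_ε²) is verified in the tests).
Fewer than three usable reflections → `None`.

*DelAnom.*  Interpreted as CCanom: per reflection, the I(+) and I(−)
observations are each randomly halved; the per-half Bijvoet differences
⟨I+⟩ − ⟨I−⟩ are correlated across reflections where both halves define
both mates (requires ≥ 2 observations of each mate).  Whether the original
quantity is CCanom or an anomalous mid-slope is ambiguous in the
literature surrounding this workflow; CCanom is implemented and the name
kept.

*Completeness.*  100 × |merged ∩ enumerated| / |enumerated| at the class-
average cell — the intersection guarantees the value never exceeds 100
even when per-crystal cells put borderline reflections on the other side
of the cutoff.

*SmRmerge.*  The per-frame trace driving both rejection loops.  Raw value
of frame f: Σ|k·I_obs − ⟨I⟩_ref| / Σ⟨I⟩_ref over the frame's observations
whose reflection exists in the current merged reference.  Scoring against
the consensus (reference means in the denominator too) keeps the statistic
defined for frames observing each reflection once.  Smoothing is a
Gaussian kernel over frame number — σ = 2 frames by default, truncated at
±3σ, weights renormalised over the defined frames in the window, so edges
and gaps are unbiased rather than damped.  Frames with no observations
carry NaN through both traces.  The smoothing kernel is a package choice
(the workflow this reproduces reads the trace from external logs without
defining one) and is configurable.

## Wedge selection

Frames divide into q_total (default 10) base wedges as evenly as possible,
remainder frames going to the *earliest* wedges — deterministic, and it
biases size toward the least-damaged part of the series.  Cumulative wedge
q is scored by CC½ at the statistics resolution `reso_cchalf` (default
reso + 1 Å; statistics at lower resolution keep more frames alive).
Scaling is not redone per wedge: within one crystal a common scale cancels
in the correlation.  Selection is argmax CC½ with ties to the larger wedge
(maximal multiplicity at equal quality) — on undamaged noise-free data this
deliberately returns the full series.  A crystal with no defined CC½ in
any wedge is excluded, not an error.

## Classification

Features are the six cell parameters, each column centred and divided by
its sample standard deviation (ddof = 1); zero-variance columns become
zero rather than dividing by zero.  Z-scoring resolves the Å-vs-degree
unit problem, at a known cost: a parameter carrying pure jitter is
amplified to unit variance, so class separation must dominate in the
separating parameter(s).  Clustering is scipy's agglomerative hierarchy
(Euclidean; `single` or `ward`, default ward for balanced classes), and
the N-class cut **replays the first M−N merges** of the linkage record —
unlike a height cut this yields exactly N non-empty classes even with
duplicate cells.  Labels are ordered by descending class size, so class 1
is always the primary candidate.  The number of classes is the user's
decision, informed by the exported dendrogram; automatic N selection and
outlier-cell deletion are explicitly not attempted.

## Rejection loops

Iteration 0 is the full class, always emitted.  A class enters the loops
only when its completeness exceeds the threshold (default 90%) — below it
only the iteration-0 dataset is produced.  Each iteration recomputes
SmRmerge profiles against the *current surviving-set* merged reference,
scores crystals by the unweighted mean of their defined SmRmerge values
(an all-undefined profile scores +∞ and is rejected first), removes
exactly `xtal_step` crystals (ties by id), and re-merges.  The loop stops
when ≤ `xtal_step` crystals remain; the final small dataset is emitted
rather than discarded, since datasets at many crystal counts are the
product.  25 crystals at step 10 therefore yield datasets of 25, 15 and 5.

Frame rejection (optional, requires the crystal loop) runs after each
iteration: frames with SmRmerge above min(SmRmerge) × (1 + decay) are
dropped per crystal, one dataset per decay in the grid (default 5, 3, 2,
1).  Undefined-SmRmerge frames are kept — there is no evidence against
them — an asymmetry with crystal scoring that is intentional: a whole
crystal without evidence cannot be ranked, but a single silent frame
costs nothing.  Kept-frame sets are nested across decays by construction.
Within an iteration, frames are rejected on the post-crystal-rejection
set and each decay's dataset is re-merged and re-scored.

Best-dataset selection is argmax of CC½ (resolution-oriented) or DelAnom
(anomalous-oriented); ties prefer fewer rejections — earlier iteration,
then larger decay (no frame rejection ranks above any decay), then more
crystals.

## The synthetic generator

The generator reproduces the statistical structure the workflow responds
to, not the optics of data collection:

- true intensities are acentric-Wilson (exponential) with mean
  `intensity_scale · exp(−B_wilson s²/2)`, s = 1/d (default B = 20 Ų,
  scale 1000);
- radiation damage is a growing isotropic B factor,
  B(f) = B₀ + β·max(0, f − onset), default β = 0.2 Ų/frame so a long
  wedge roughly doubles the effective B;
- wedge geometry is combinatorial: the unique-reflection list is placed in
  one shared shuffled order, each crystal owns a contiguous window of it
  (window = 8 × the per-frame slice by default) and every frame exposes a
  random contiguous sub-slice, giving within-crystal multiplicity and
  partial inter-crystal overlap;
- noise is Gaussian with σ = √(max(I,0)/gain + σ₀²), reported honestly in
  the σ column (not Poisson: post-integration intensities are
  approximately Gaussian, and the σ column must be truthful);
- cells are jittered per class around class means; frames per crystal are
  drawn uniformly from 10–100 at 0.1–0.3°/frame, the anticipated envelope
  of microcrystal rotation collection;
- anomalous signal is an antisymmetric perturbation ΔI with
  sd = anomalous_fraction × the local Wilson mean, split as I± = I ± ΔI/2;
  "bad" crystals get a noise multiplier.

All randomness derives from one seed: the truth uses stream (seed, 0),
crystal i uses (seed, 1000+i) for its own draws — perturbing one crystal's
spec never changes another's data.  Not emulated: detector geometry,
partiality, absorption, centric reflections, site-specific radiation
chemistry, and real non-isomorphism beyond cell jitter.  Passing tests on
this substrate therefore demonstrate that the *selection and rejection
logic* responds correctly to damage, noise and class structure — not that
real integrated data will show effects of the same magnitude.

## Numerical conventions and problem sizes

Undefined statistics are `None`/NaN throughout, never silent zeros.
Canonical indices are packed into int64 grouping keys with a fixed radix
(|h|,|k|,|l| < 512), so keys from independent computations always agree.
Report files are tab-separated, one header line, floats at 6 significant
digits; the observation interchange tables are written at full precision
so round trips are exact.  Amplitude export is the naive clamped square
root F = √max(I,0) with first-order error propagation and a seeded
free-set flag (default fraction 0.05) — an intentional simplification, not
a French–Wilson treatment; do not use it where accurate weak-reflection
amplitudes matter.

Test and acceptance runs use deliberately small studies — cells of tens of
Å, d_min 2.5–3.5 Å, 4–25 crystals of 10–50 frames — chosen so each check
isolates one effect (a planted damage onset, three noisy crystals, an
89%/91% completeness straddle) while whole-suite runs stay in minutes on
one CPU.  The fixture conditions for the damage-onset check (weak
diffraction: gain 0.005, β = 8 Ų/frame past frame 25) put the CC½-vs-wedge
curve in its informative regime, rising with multiplicity before the onset
and falling after it; with strong diffraction the curve saturates and
wedge choice is indifferent, which is equally true of real data.

## Known limitations

- The linear per-crystal scale model cannot absorb resolution-dependent
  decay between crystals; strongly damaged crystals are *rejected*, not
  corrected.
- Chained scaling is not attempted: a crystal overlapping the class but
  not the reference crystal scales at k = 1.
- Exact tie-breaking of equal-height linkage merges follows scipy's
  internal order; ties are measure-zero on real (jittered) cells.
- hdf5/detector-format ingestion is out of scope; the tabular reader is
  the single entry point and the place an adapter would attach.
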