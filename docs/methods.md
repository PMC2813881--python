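# Methods

`rnafoot` quantifies hydroxyl radical footprinting experiments on RNA and
fits cooperative protein-binding curves. This note records the models the
package implements, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
choices that matter.

## The measurement model

Hydroxyl radicals cleave the RNA backbone at a rate roughly proportional to
the solvent accessibility of each nucleotide. In a capillary-electrophoresis
readout, cleavage positions appear as primer-extension stops: a (+)-catalyst
channel carries cleavage signal plus background, a (−)-catalyst channel
carries background only (reverse-transcription stops, independent of
cleavage), and a dideoxy ladder anchors nucleotide positions. A protein
bound to the RNA shields its contact surface, reducing cleavage there
(protection); conformational changes can increase cleavage elsewhere
(enhancement).

## Quantification pipeline

1. **Background subtraction.** Net intensity is
   `max(plus − s·minus, 0)` with channel scale `s = 1` by default. The
   subtraction formula is a package design choice (the floor at zero keeps
   intensities physical); positions where the (−) channel saturates are
   masked rather than subtracted.
2. **Normalization.** Unmasked net intensities are sorted descending, the
   top `ceil(0.02·N)` values are excluded as outliers, and the mean of the
   next `ceil(0.08·N)` values is the normalization factor. Dividing by it
   puts profiles on a common 0-to-~1.5 scale on which 1.0 is, by
   construction, the exact mean of the highly reactive reference set. Counts
   use the ceiling and ties are broken by position order after a stable
   sort, so the reference set is reproducible. The rule is scale-invariant
   and idempotent. At least 25 unmasked positions are required so the
   reference set is non-empty.
3. **Smoothing.** A centered 3-nt moving average is applied *for display
   and difference plots only*; all statistics (normalization, accessibility
   classification) use unsmoothed values. Windows shrink at the sequence
   ends and masked positions are dropped from each window's mean.
4. **Accessibility classification.** Nucleotides with reactivity at or
   below 0.5 — one-half the reference mean of 1.0 — are classified solvent
   inaccessible. The rule is inclusive ("or less"). We read "one-half the
   mean" as half the *reference* mean because the scale definition fixes
   that mean at 1.0; half the overall profile mean is a different and less
   stable quantity.
5. **Difference mapping.** delta(i) = bound(i) − free(i) on profiles with
   matching smoothing state; masks are unioned. Protections are negative,
   enhancements positive. Differences are computed on smoothed profiles by
   default (matching how difference plots are displayed); an unsmoothed
   mode is available.
6. **Significance calls.** |delta| ≥ 0.2 normalized units, inclusive. The
   0.2 default corresponds to two-fold above a typical mean background
   difference of 0.1; `estimate_threshold` can derive the threshold from
   free-vs-free replicate differences (multiplier × mean |delta|) instead.
   This is a fixed effect-size rule, not a hypothesis test — no
   multiple-testing correction applies, and no replicate-variance weighting
   is attempted.
7. **Segmentation.** Same-direction calls separated by at most `max_gap`
   positions (default 1) share a region, so a single no-data site does not
   split a footprint.
8. **Motif assignment.** Each call is assigned to the structural element
   containing its position. Positions are classified `within` a
   tetraloop-receptor motif (inside a contact tetraloop or receptor helix),
   `adjacent` (within `adjacency_k` nt along the sequence; default 2, a
   deliberate operationalization of "immediately adjacent" exposed as a
   parameter), or `distal`. Because adjacency is a property of sequence
   position, element summaries are emitted per (element, adjacency class);
   `motif_coverage` is then the position-accurate fraction of protected
   nucleotides at or near a motif, and is *undefined* (not zero) with no
   protections. The three-part signature check takes the call list plus the
   model — per-element counts alone cannot distinguish the receptor docking
   face from the receptor extension — and reports, per motif, whether
   protection reaches (i) the tetraloop, (ii) the receptor docking face,
   and (iii) the receptor-helix half extending toward the exterior.
9. **GNRA detection.** A hairpin loop of exactly four unpaired nucleotides
   closed by a pair, with sequence G-N-R-A (R a purine), 5′→3′. Receptor
   motifs are taken from annotation, never predicted from sequence.

## Cooperative binding model

Filter-partitioning titrations are fit to the Hill form

    fraction bound = A·[P]^n / ([P]^n + K½^n)

with A the total bindable fraction (typically ≥ 0.95), n the apparent Hill
coefficient, and K½ the half-saturation protein concentration.
Fitting is unweighted nonlinear least squares (trust-region reflective,
`x_scale='jac'` so fits commute with rescaling concentration units) with a
deterministic multi-start: A₀ = max observed fraction, K₀ = concentration
nearest half-max, n₀ ∈ {1, 2, 3}; the lowest-SSE converged start wins and
the convergence flag reports the optimizer's status honestly. Bounds
A ∈ (0, 1.1], n ∈ (0.2, 6], K½ ∈ (0, 10⁵ nM] prevent degenerate solutions
on flat data. Preconditions: ≥ 5 points spanning ≥ 1 decade; if the RNA
concentration exceeds K½/5 the fit carries a warning (binding regime rather
than titration regime). R² = 1 − SS_res/SS_tot; undefined (raised) on
zero-variance data.

On 12-point log-spaced titrations with Gaussian noise of sd 0.02, the
estimator recovers generating parameters with median K½ error well under 5%
and median Hill-coefficient error ≤ 0.1 when the titration spans roughly a
decade either side of K½; very wide ranges (4+ decades) leave fewer points
in the transition and push the n error slightly higher. This is intrinsic
design variance, not an optimizer artifact — the fit matches an exhaustive
grid-plus-polish search.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

* **Toy structure.** A 540-nt-scale (minimum 80 nt) group-I-intron-like
  model: four hairpins (P2, P5, P8, P9) separated by exon/junction
  segments, with GAAA tetraloops L2 and L9 docked against receptor helices
  P8 and P5 — two tetraloop-receptor motifs linking distal parts of the
  molecule. The docking face is the three receptor base pairs nearest the
  receptor's own loop; the remaining half of the helix is the exterior
  extension. Coordinates are 1-based throughout.
* **Accessibility ground truth.** Free state: motif elements fully exposed
  (uniform 0.7–1.0), emulating an RNA whose tertiary contacts have not
  formed, with 20% of the remaining positions buried (0.05–0.2) so the
  free RNA shows the realistic partial protection of a partly structured
  molecule. Bound state: accessibility × (1 − footprint_depth) over each
  tetraloop and the entire receptor helix. Default footprint_depth = 0.6 —
  a strong but not total occlusion; the literature gives no measured depth,
  so it is a free parameter of the generator.
* **Cleavage noise.** Multiplicative lognormal with unit mean,
  default CV 0.05: probing intensities are positive and right-skewed, and
  CE-resolved hydroxyl radical data is highly quantitative. The (−) channel
  and the (+)-channel background are independent draws at
  `background_rate` (default 0.1) of full scale, reflecting that
  reverse-transcription background is independent of cleavage. With zero
  noise and zero background, (+) intensities are exactly
  scale × accessibility.
* **Traces.** Each nucleotide contributes one Gaussian peak (default
  spacing 10, width 1.5 elution units) whose area is its intensity times
  `decay_rate^index`, emulating exponential primer-extension signal decay.
  No dye mobility shifts and no ladder misalignment are simulated: trace
  integration here is simplified plumbing, not a reimplementation of
  whole-trace analysis software.
* **Binding curves.** Hill values plus Gaussian noise, clipped to
  [0, 1.05] (real filter data slightly overshoots 1).

What passing tests therefore show: the pipeline's rules are implemented
exactly and recover planted signal under realistic noise. What they do not
show: robustness to misaligned ladders, mobility shifts, heteroscedastic
CE noise, or normalization across RNAs with very different reactivity
distributions — none of which the generator emulates.

## Trace integration numerics

Peaks are integrated between the midpoints to their neighbors on the
integer elution grid (midpoint-rule equivalence: a sum over integers in
[lo, hi) approximates the integral over [⌈lo⌉−½, ⌈hi⌉−½]). Window sums
include tail spill-in from neighbors — up to several percent when adjacent
peaks differ 40-fold — so areas are deconvolved by solving the linear
system given by the Gaussian overlap matrix (known centers, shared median
width). Peak area, not height, is the intensity estimate. A peak is flagged
`missing` when the signal at its center is below 10⁻³ of the trace maximum;
missing peaks are masked, never zero-filled, and when fewer peaks are found
than expected the tail rows are flagged rather than silently truncated.
Decay correction divides area(i) by `decay_rate^i` with a single known or
estimated rate — a simplification relative to fitting the decay from the
trace itself, accepted at this fidelity level. The round-trip
simulate → integrate → decay-correct reproduces inputs to well within 1%
per nucleotide at default geometry.

## Problem sizes and determinism

All generators and fits are bit-reproducible for a fixed seed; the pipeline
derives per-stage child seeds from one master seed and records them, with
every threshold and normalization factor, in its summary. Default validation
sizes — 540-nt profiles, 100-seed Monte-Carlo sweeps, 12-point titrations ×
100 replicates — run in seconds and were chosen as the smallest sizes at
which the recovery statistics are stable.

## Known limitations

* Background subtraction assumes a single channel scale (default 1); the
  per-channel scaling used by any given instrument is not modeled.
* The receptor "exterior extension" is a topological definition (the
  non-docking half of the receptor helix), a qualitative reading of how
  such protections are drawn on secondary-structure diagrams.
* No statistical error model for reactivities: the 0.2 rule is an effect
  size, and replicate-variance weighting is out of scope.
* Only nested secondary structures are parsed from dot-bracket input
  (pseudoknot-free); CT input carries pairs only, with elements and
  contacts supplied by side-car annotation tables.
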