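# Methods

This note documents the models, estimators and design choices behind
`eegtree`: what each stage computes, which parameters matter, what the
synthetic cohort does and does not emulate, and the numerical conventions
adopted where more than one reasonable choice existed.

## Pipeline overview

The analysis chain is

1. **Signal conditioning** — zero-phase band-pass 0.5–30 Hz, resampling
   to 500 Hz, exclusion of eight periocular channels (128 → 120 on the
   full montage), tiling into non-overlapping 2-s epochs, head-selection
   of 72 epochs, common-average re-referencing, and decomposition into
   delta (0.5–4 Hz), theta (4–8 Hz), alpha (8–13 Hz) and beta (13–30 Hz).
2. **Connectivity** — instantaneous phase from the analytic signal
   (Hilbert transform) of each band-limited epoch, then the phase lag
   index over all channel pairs:
   `PLI = | < sign(sin Δφ(t_k)) > |`, the asymmetry of the
   phase-difference distribution around zero.  PLI ∈ [0, 1]; 0 means no
   coupling or coupling at lag 0 (mod π), the signature of volume
   conduction, and 1 means perfect locking at any other lag.
3. **Tree topology** — Kruskal minimum spanning tree under link weight
   1/PLI per epoch (120 nodes, 119 links on the full montage), a
   ten-metric panel per tree, and the per-subject mean over epochs.
4. **Statistics** — log transform, Shapiro–Wilk normality gate per
   group cell, parametric or aligned-rank-transform (ART) 2 × 3 mixed
   ANOVA (condition within, group between) with age and IQ residualized
   out, Bonferroni post-hocs on significant interactions, and
   permutation-tested Pearson correlations between metrics and
   behavioral accuracy.

## Signal conditioning

*Filters.* All filtering is forward–backward 4th-order Butterworth
(`sosfiltfilt`), i.e. zero net phase shift.  This is non-negotiable for
this pipeline: any filter phase distortion would bias the
phase-difference distribution that PLI measures.  The squared magnitude
response of the forward–backward pass gives ≈ 0.015 residual amplitude
at 50 Hz for the 0.5–30 Hz filter; the low 0.5 Hz pole rings for a few
seconds at recording boundaries, which is irrelevant after epoching but
matters when validating attenuation on short test signals.

*Epoch selection.* Visual/ICA artifact screening operates on information
this pipeline does not model, so it is replaced by a deterministic
surrogate: epochs whose peak absolute amplitude exceeds a configurable
threshold are discarded, and the first 72 surviving epochs in time order
are kept ("filter-then-head").  Whether a real analyst would take the
first clean epochs or a random subset is unknowable from a protocol
description alone; head selection was chosen because it is reproducible
and order-preserving.

*Eye channels.* Only the count (eight) of excluded eye channels is
conventionally fixed; the default list (E8, E14, E21, E25, E125, E126,
E127, E128 — the orbital rim of the 128-channel geodesic layout) is a
documented, overridable default.

*Band power.* Welch periodograms are estimated per 2-s epoch (one
segment per epoch), averaged across epochs, and integrated per band;
relative power divides by total 0.5–30 Hz power.  An all-zero channel
yields zero absolute power and missing (NaN) relative power.

## PLI conventions

- A configurable edge fraction (default 5%) of every epoch is excluded
  from the PLI sums, suppressing Hilbert transform edge artifacts at 2-s
  epochs.
- Samples where sin Δφ is mathematically zero (lags of exactly 0 or π)
  contribute 0 to the signum mean — they reduce, never inflate, the
  index.  Numerically, |sin| < 1e-9 is treated as zero so that π lags
  behave like their mathematical value despite round-off.
- PLI is computed per epoch and carried forward per epoch; aggregation
  to subject level happens only at the metric panel (arithmetic mean
  over the 72 epochs).
- ROI-pair connectivity is the unweighted mean PLI over all cross-region
  electrode pairs (e.g. 7 × 9 = 63 pairs for left-temporal vs
  left-occipital); within-region pairs never enter.

## Minimum spanning tree and metric panel

Kruskal's algorithm sorts all 1/PLI link weights ascending and adds
links that do not close a cycle until N − 1 links span the graph.  Ties
(equal PLI) are broken by ascending node index pair, making construction
fully deterministic; with continuous PLI estimates ties have measure
zero.  Zero-PLI entries get distance 1/ε (ε = 1e-12) instead of being
excluded: the tree always exists, and such a link is never selected
while any positive-PLI alternative remains.

Panel conventions, and why:

- **Hop distances** (unweighted path lengths) for diameter,
  eccentricity, radius, betweenness and closeness; **PLI weights** for
  node strength.  Mean strengths of ≈ 1.65 (delta) or ≈ 0.83 (beta) on
  120-node trees are only possible with PLI weights, since 1/PLI ≥ 1
  would force the mean strength above the mean degree ≈ 1.98.
- **Betweenness** is the raw count of unordered node pairs whose unique
  tree path crosses the node (max possible C(119, 2) = 7021 at N = 120),
  not normalized.  Only raw counts make the tree hierarchy
  Th = L / (2 · M · BC_max) land at its conventional ≈ 6e-5 magnitude
  for 120-node trees.
- **Closeness** is the plain inverse summed hop distance (no (N−1)
  scaling), giving the conventional ≈ 0.002 maxima at N = 120.
- **Eccentricity** is reported as the mean over nodes (the scalar lies
  strictly between radius and diameter).
- **`reported_diameter` = N + 1 − L** is emitted alongside the true hop
  diameter.  A widely used reporting convention publishes this
  leaf-complement under the name "diameter"; it can exceed twice the
  radius, which the graph-theoretic diameter cannot, so the two are kept
  as separate columns.
- **Kappa** is ⟨k²⟩/⟨k⟩, the standard degree-broadness measure for MST
  panels (path ⇒ κ → 5/3 at length 4; star ⇒ κ = N/2).

## Statistics

*Gate.* Metrics are natural-log transformed (they are strictly positive
by construction; a non-positive value is a data error, not a case to
offset away).  Shapiro–Wilk runs per group × band cell; any rejection at
α = 0.05 routes that metric to ART, otherwise the parametric mixed ANOVA
is used.  Cells with fewer than 3 values or zero variance are flagged
non-testable and do not trigger ART by themselves.

*Covariates.* Age and IQ are adjusted by pooled OLS residualization of
the response before the factorial model, identically on both routes.
ART has no canonical ANCOVA form, so sharing one adjustment keeps the
routes comparable; this is a documented substitute, not a claim about
how any particular study handled its covariates.

*ART.* For each effect (group, condition, interaction) the response is
aligned by removing the estimates of all other effects (via cell,
marginal and grand means), ranked across the entire dataset, and the
standard mixed ANOVA is run on the ranks; only the aligned-for effect's
row is kept.  If every aligned value ties (degenerate input), the effect
is reported as F = 0, p = 1.  The backing factorial engine is
`pingouin.mixed_anova`, which was verified against a hand-computed
split-plot decomposition.

*Post-hocs.* Welch two-sample t-tests between groups within each
condition; Bonferroni correction over the three group pairs per
condition family.

*Permutation correlations.* Pearson r with a two-sided permutation null
(re-pairing of subjects), p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + n_perm),
valid for any permutation count; 5,000 permutations by default,
Bonferroni-corrected across the metric family tested per band.
Correlations are computed on the first condition's (eyes-closed) values,
where the group effects are injected in the synthetic cohort.

Type-I error of all three estimators (both ANOVA routes' interaction
test and the permutation correlation) is verified by 1,000-replicate
null simulation in the acceptance suite and stays within [0.03, 0.07]
at α = 0.05.

## Synthetic cohort

The generator exists because resting-state recordings of this kind are
typically unreleased; it produces signals whose coupling structure —
hence whose PLI matrices and tree topology — is known by construction.

*Signal model.* Per band, each channel carries an amplitude-scaled
cosine of a latent phase process plus white noise.  Latent phases are
frequency-jittered random walks: increments 2π f_c / rate plus Gaussian
phase noise (default σ = 0.1–0.25 rad/sample).  This yields band-limited
but aperiodic signals — identical pure sinusoids would make PLI
degenerate for every pair — and sets the effective number of independent
phase samples per epoch, i.e. the PLI noise floor for uncoupled pairs.
Coupled pairs hold φ_i − φ_j = δ + ε with ε von Mises of concentration
κ (κ = ∞: perfect locking; κ → 0: independence); a lag of 0 with finite
κ emulates volume conduction and is correctly ignored by PLI.

*Cohort model.* Groups of 31/24/29 subjects (early implantation, late
implantation, normal hearing) with two conditions each.  The default
templates couple one hub channel to ~60% of the montage at lag π/2 in
the theta band.  The tree's star-likeness (leaf number, kappa) rises
monotonically with κ because hub edges must out-rank the per-epoch noise
floor of uncoupled pairs to enter the MST; the default concentrations
(κ = 2.5 strong, κ = 1.0 weak for the late-implantation eyes-closed
cell) sit on the steep part of that dose–response curve, a design-time
calibration made while building the generator.  Each subject draws a
coupling multiplier g ~ N(1, 0.25) (floored at 0.05) applied to all
template concentrations; behavioral accuracy is
`intercept(group) + 12·(g − 1) + N(0, 5)`, clipped to [0, 100], with
group intercepts 77/65/89.  Covariates (age, IQ) are drawn per group
with school-age means.  One master seed spawns per-subject substreams,
so cohorts are bit-reproducible while subjects stay independent.

*What the generator does not emulate:* biophysical volume conduction
and field spread (beyond the zero-lag noise construction), implant
electrical artifacts, eye movements, 1/f background spectra, spatially
correlated noise, and realistic per-band PLI distributions.  Passing
tests therefore demonstrate that the estimators and the pipeline recover
known structure under controlled conditions — not that any particular
empirical finding replicates.

## Problem sizes in the test suite

The validation suite runs at reduced scale chosen as the package's own
desk-scale defaults: the end-to-end recovery experiment uses the study's
group sizes (31/24/29) with 16-channel montages, 12 two-second epochs
at 250 Hz, theta band only, 50 replicates; calibration uses 1,000 null
replicates with 199 permutations per correlation.  Montage size, epoch
count and rate scale the precision of each subject's metric estimates,
not the identity of the estimators, so the reduced scale exercises
exactly the code paths used at full scale (which the 120-channel
structural tests cover directly).

## Known limitations

- The amplitude-threshold epoch rejection is a stand-in for human/ICA
  artifact screening and shares none of its selectivity.
- ART with continuous covariates has no canonical definition; the
  residualization approach here is one defensible choice.
- The closeness-centrality magnitudes of published 120-node panels are
  not fully explainable under any single distance convention we tried;
  this package states its convention (inverse summed hop distance)
  explicitly rather than matching every published magnitude.
- `reported_diameter` reproduces a reporting convention, not a graph
  invariant; analyses should prefer the true hop `diameter`.
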