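# Methods

This note documents the models and procedures implemented in `graphot`,
the parameters that matter, the design choices taken where the design
was genuinely open, and the limits of what the synthetic-data tests can
show.

## Glyph rendering and mass distributions

Letters are rasterised with Pillow's FreeType engine at a point size
chosen so the tightly cropped ink bounding box does not exceed
`max_height_px` (default 250 px), then normalised to intensities in
[0, 1] (8-bit value / 255).  Raster coordinates are row-major with the
origin at the top-left pixel; distances are in pixel units.  The default
typeface is DejaVu Sans, an open sans-serif resolved at run time from
matplotlib's bundled fonts: letter-shape measurements are font
dependent, so quantitative results obtained under one typeface (stroke
widths, absolute distances, metric inter-correlations) will differ under
another.  Rendering is deterministic for a fixed (character, font file,
height) triple; anti-aliasing and glyph outlines are whatever the
rasteriser produces — no hinting control is exposed.

An intensity image becomes the unit the transport metrics operate on by
treating each pixel's intensity as mass at its integer position and
rescaling masses to sum to one (tolerance 1e-9).  `min_intensity`
(default 0) excludes faint pixels from the support; the headline metrics
use all non-zero pixels, and only the Gromov-Wasserstein path thresholds
at 0.05 for tractability (see below).

## Pairwise metrics

**Alignment.**  Before Jaccard or Wasserstein evaluation, each pair is
placed at the integer offset maximising its 2-D linear
cross-correlation, computed on a zero-padded common canvas large enough
to represent every shift.  Ties at the correlation peak are broken by
first occurrence in row-major order (the tie-break is arbitrary but
fixed, for determinism).

**Jaccard.**  The fuzzy form `1 − Σ min / Σ max` on intensities is used
rather than a binarised overlap: the inputs are anti-aliased grayscale
rasters and no binarisation threshold is privileged.  With binary images
the fuzzy form reduces to the classical area formulation.

**Wasserstein-1.**  The transport problem is solved exactly as a linear
program with the HiGHS simplex solver (an exact vertex solution, like
the network simplex), with Euclidean ground cost between support pixels.
The reported distance is the sum of transported mass times distance;
plan marginals are verified to 1e-8.  The dense formulation materialises
the full cost matrix, so combined supports above 20,000 points are
refused with guidance to threshold or downscale.  In practice supports
of ~300 points per glyph (glyph heights around 32 px) solve in well
under a second, ~800 points in minutes; full 250 px renderings are out
of reach of the dense LP and are only needed for font-exact replication
of published numbers.

**Gromov-Wasserstein.**  Square-loss GW between the two glyphs' internal
Euclidean distance matrices, minimised by conditional gradient: each
descent direction is an exact transport LP with the current gradient as
cost, followed by a closed-form quadratic line search; iteration stops
at an objective change below 1e-9 or 1,000 iterations.  The objective is
non-convex, so the solver multi-starts from the product coupling plus
seeded random vertices of the transport polytope and random
iterative-proportional-fitting couplings (4 starts by default), and for
tiny equal-mass supports (n = m ≤ 8) additionally enumerates all
assignment couplings exactly — conditional gradient alone is not
reliable at global optimality on such instances.  Supports larger than
`max_support` (default 1,500) are reduced by intensity-weighted
subsampling with a recorded seed.  GW inputs are thresholded at
intensity 0.05; this deviates from the all-nonzero-pixels convention of
the planned metrics and exists purely to keep support sizes tractable.

**Geometric invariance.**  The invariant variants minimise the metric
over transformations of one glyph while the other stays fixed, after
cross-correlation pre-alignment.  Translation is bounded in [−x, 2x]
(x = the glyph's own width/height), scale on a log scale in
[log 0.5, log 2], rotation unbounded with starts spaced over
[−180°, 180°].  Nelder–Mead runs from the full factorial grid of 5
equidistant starts per optimised dimension, plus the identity transform
(so the invariant minimum never exceeds the aligned plain metric) and
any caller-supplied warm starts — passing a smaller transform set's
optimum as a warm start makes the nested-set dominance property
(larger search space cannot hurt) hold by construction.  For Jaccard,
translation is resolved analytically by the cross-correlation peak at
every objective evaluation instead of being given to the optimiser; for
Wasserstein, translation is two optimiser dimensions.  Scale and
rotation use bilinear interpolation about the image centre, clipped to
[0, 1]; transformed mass is re-normalised to 1 by the mass-distribution
constructor.  Transforms that push all ink off the canvas receive a
large finite penalty.

## Neural RDMs

Epoched data (participants × trials × channels × samples, µV) is
consumed as-is: no filtering, baseline correction, artefact handling or
re-referencing happens in the package, and correlation distance over a
fixed window is insensitive to per-channel offsets removed upstream.
Condition ERPs are arithmetic means over trials; pattern vectors
concatenate ROI-channel amplitudes at successive samples end-to-end.
Analysis windows are half-open `[start, stop)` in ms, so 150–225 ms at
1000 Hz contains exactly 75 samples per channel and a 30-channel ROI
yields 2,250-dimensional vectors.  The default ROI is the 30 posterior
channels TP9 … PO10 (temporo-parietal through occipital).  Dissimilarity
is `1 − Pearson r`, clipped to [0, 2]; RDMs are rank-transformed
(average ranks on ties) before any rank correlation.  A known
trigger-to-display delay can be absorbed at ingestion via
`onset_delay_ms` (default 0 for synthetic data).

The leave-one-out noise ceiling averages per-fold Spearman correlations
between the left-out participant's rank RDM and the mean of the others'
rank RDMs (lower bound) or of all rank RDMs (upper bound).  Averaging
operates on rank-transformed RDMs, mirroring the rank-correlation
pipeline; this is a documented choice, as averaging raw RDMs before
ranking is equally defensible.

Time-resolved RDMs tile consecutive non-overlapping bins (default
10 ms — 10 samples at 1000 Hz) from the epoch start, each bin processed
exactly like a window.

## Bayesian correlation model

Per participant, the lower triangles of the neural rank RDM and of each
model rank RDM (shared across participants) are standardised and
stacked; rows are modelled as zero-mean multivariate normal with unit
scales and a shared correlation matrix `R`.  The prior on `R` is uniform
over valid correlation matrices (LKJ with η = 1), implemented as an
indicator on positive-definiteness over the off-diagonal entries.  Two
properties motivate this choice: it is symmetric about zero in every
entry, so prior odds for any directional hypothesis equal 1 and Bayes
factors reduce to posterior odds; and directional conclusions from this
family are robust to substantial prior changes.  The likelihood enters
only through the scatter matrix, so each log-posterior evaluation is
O(k³) in the number of variables regardless of the number of pairs.

Sampling uses the emcee ensemble sampler with differential-evolution
moves (80% DE, 20% DE-snooker): 32 walkers, 1,000 burn-in and 2,500 kept
steps (80,000 draws), initialised near the empirical correlation.  The
stretch move was rejected — its autocorrelation time on these posteriors
(~35 steps) could not reliably satisfy the convergence gate; DE moves
achieve ~12.  Convergence is gated at split-R̂ < 1.01 (walkers treated
as chains); a failed gate raises with diagnostics rather than returning
a dubious posterior.  Seeds are recorded in every posterior object.

Partial correlations are computed per posterior sample from the inverse
correlation matrix (`p_ij = −Ω_ij/√(Ω_ii Ω_jj)`), Bayes factors count
posterior samples on either side of the reference (exact ties excluded;
an empty denominator is reported as "BF > S"), and HDIs are the shortest
contiguous interval containing ⌈mass·S⌉ sorted samples.  The planned
analysis reports, for two model RDMs: posterior medians with 50%/89%
HDIs for raw and partial correlations, BFs for H1 (first model's
correlation > 0), H2a (first > second, raw) and H2b (first > second,
partial), and the noise ceiling.  H2a and H2b coincide whenever the
partial-correlation transform preserves entry ordering, which holds on
every sampled matrix in practice and is asserted in tests; it is checked
empirically rather than assumed as a theorem.  No multiple-comparison
correction is applied to the three directional BFs.

## Trial-schedule generator

The alphabetic decision task presents 30 letters × 25 repetitions and
28 false-font characters × 6 repetitions (918 trials; false-font
counterparts exist for all letters except ö and ß) in 14 blocks of 66
trials, the last of 60, with 10–14 false-font trials per block.  No
stimulus identity recurs within 3 trials of its last presentation
(true/false-font counterparts distinct; enforced across block
boundaries), and for every letter the fraction of its 25 presentations
immediately preceding or following a false-font trial stays below 0.33.

That adjacency bound is only satisfiable if false fonts cluster: fully
dispersed false fonts create ≈336 letter-adjacent positions for 750
letter presentations, forcing a mean adjacency fraction ≈0.36.  The
generator therefore places false fonts in runs of 1–3 consecutive trials
(expected run length ≈1.7) and assigns letters to run-adjacent positions
constructively, capping each letter at 8 adjacencies (8/25 = 0.32).
Adjacency is counted within blocks only, since blocks are separated by
self-paced breaks.  Identities are filled greedily in trial order,
sampling eligible stimuli with probability proportional to remaining
repetitions; dead ends trigger a restart (rejection sampling, at most
10,000 attempts), and every returned schedule passes an independent
validator.  Identical seeds give identical schedules.  A practice block
(17 letters + 3 false fonts) can be generated but is excluded from
analysis outputs.  How identities distribute across blocks beyond these
constraints is uniform at random — the original distribution rule is not
recorded anywhere.

## Synthetic data

The generator controls correlation-distance geometry directly rather
than emulating EEG physics.  Given model RDMs and non-negative weights
summing to ≤ 1, the target similarity has unit diagonal and off-diagonal
`Σ wᵢ (1 − minmax(RDMᵢ))`, so zero weights give an uncorrelated
(pure-noise) target and a single unit weight reproduces that model's
rank order exactly.  The matrix is projected to the nearest positive
semi-definite matrix by eigenvalue clipping and rescaled to unit
diagonal; the projection slightly distorts the target geometry, which
tests quantify via the Spearman correlation between target and realised
RDMs rather than assuming it away.

Per participant, latent letter patterns are drawn Gaussian with this
covariance across letters, independently for every channel × in-window
sample; each trial adds the letter's pattern — only inside the signal
window — to unit-SD white noise, scaled by `snr` (ratio of per-sample
signal SD to noise SD).  Configuration defaults mirror the study design:
14 participants, 25 trials per letter, 30 channels, 1000 Hz, epochs
−200..1000 ms, signal in 150–225 ms.  A full default-size epoch set is
~12 GB, so tests and examples use reduced sizes (250 Hz, −100..400 ms,
6–10 channels, 8–10 trials per letter, 12-letter sets at 28 px) — chosen
as the smallest configuration that leaves every statistical property
comfortably recoverable.  A shortcut generator perturbs the composite
dissimilarity directly with exchangeable pair-level Gaussian noise per
participant (then rank-transforms) for fast inference tests.

What passing synthetic tests shows: the pipeline's averaging, pattern
extraction, correlation geometry, noise ceiling, posterior recovery and
Bayes-factor calibration behave correctly when their own statistical
assumptions hold.  What they do not show: robustness to spatially and
temporally correlated EEG noise (1/f spectra, volume conduction),
artefacts, per-participant latency or topography differences, or
preprocessing choices — none of which the generator emulates.

## Calibration and recovery checks

The acceptance suite verifies, with fixed seeds: exact-OT agreement with
brute-force vertex enumeration (spanning-tree bases of the transport
polytope) to 1e-8 on all instances with ≤ 8 combined support points;
Gromov-Wasserstein ≤ 1e-6 against rigidly transformed copies and
agreement with a permutation-enumeration oracle on 5-point equal-mass
instances; noise-ceiling equality with explicit fold computation;
posterior-median recovery of generating Spearman correlations
ρ ∈ {0, 0.1, 0.3, 0.5} within 0.05 averaged over 25 replications of 14
participants × 435 pairs (latent bivariate normals at Pearson
2 sin(πρ/6), so ranks carry Spearman ρ); BF(ρ_W > ρ_J) > 15 in ≥ 90% of
20 high-SNR end-to-end runs generated with weights (0.6, 0.2); a median
H1 Bayes factor within [1/3, 3] over 25 zero-weight replications; and
equality of the raw and partial model-comparison Bayes factors on every
run.

## Known limitations

- The dense-LP transport solver is exact but does not scale to full
  250 px renderings; font-exact replication of published values
  additionally requires the original (licensed) Arial Light typeface.
- Gromov-Wasserstein at realistic support sizes is a local-optimisation
  result; only tiny instances carry a global-optimality guarantee.
- The Bayesian model stacks participants' rank vectors flat (one shared
  correlation matrix, no participant-level hierarchy) and treats ranks
  as multivariate normal after standardisation — a pragmatic likelihood
  for rank data, not a generative claim.
- Mirror-symmetric glyph pairs in geometrically regular typefaces
  produce exact ties in Jaccard distances; ranks use midranks, so
  downstream rank correlations are well defined but the 1..435 rank
  sequence is not a strict permutation in every font.
- The trial-schedule adjacency definition (before-or-after, per letter,
  within block) is one reading of the design constraint; the directed
  variants (letter→false-font and false-font→letter transition
  probabilities) are bounded a fortiori by the same cap.
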