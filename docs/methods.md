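# Methods

This note records the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data layer does and does not
emulate, and the known limitations.

## Synthetic punctate fields and rendering

A field is a set of N particles with integer pixel² areas drawn lognormally
(default mean 12 px², log-sd 0.35, clipped below at 6 px² so every punctum
is comfortably above camera noise) and placed uniformly with a hard-core
minimum separation by rejection sampling (budget 100·n attempts, then a hard
error — a silent partial field would corrupt round-trip tests).  Rendering
rasterises each particle as the Ap nearest pixels to its centroid — an
exact-area disk — at its peak intensity, convolves with a Gaussian PSF
(default σ = 0.8 px) and adds a flat background (default 100).  Integrated
blob intensity above background therefore equals area × peak exactly; this
is the calibration that makes detected-vs-true area comparisons meaningful,
and it is recorded in the image metadata.  Noise follows the standard camera
model: Poisson shot noise on signal + background, then additive Gaussian
read noise; both optional, so noiseless images remain exactly invertible.

With the defaults (peak 1000, background 100, Poisson + read noise sd 3) a
fixed threshold at 500 sits roughly mid-blob-amplitude and ≥ 35 noise sd
above background, so detection of well-separated puncta is exact in count
and within a few percent in total area.  Threshold choice is exposed; the
local-mean adaptive variant (window 15 px, offset 0) mirrors common ImageJ
practice, with the sign convention that the mask is `pixel > local_mean −
offset` (negative offsets raise the threshold).

## Particle statistics

Size distributions use unit (1 px²) bins up to the largest area Ap′ by
default; rebinned displays use arithmetic mid-point representative areas.
Fractional coverage is computed per bin as the exact sum of member-particle
areas divided by C_t.  At unit bins this equals the textbook Np_i·Ap_i/C_t
formula, and under any binning it keeps Σ f_i = 1 to machine precision; the
representative-area product form is used only for model curves, which have
no particle list.  Connectivity defaults to 8 (exposed); a `min_area` filter
removes single-pixel noise components.  S/B uses arithmetic means of raw
intensities in rectangular on-cell/off-cell regions; percentages are rounded
to integers only at the reporting layer.

## Redistribution models

The binomial terms are plotted against particle area with the linear map
p = Ap/Ap′ onto (0, 1] — the single largest interpretive choice in this
module, recorded here and in output metadata.  Curves are continuous
expected counts; the scale factor making Σ Np_i·Ap_i equal the target C_t
defines N_t.  A seeded Poisson-sampling mode turns a curve into integer
counts for stochastic tests.  Stripping multiplies all areas by the scale
factor (N_t fixed); disassembly replaces each particle by m tangent
fragments of area Ap/m (C_t conserved exactly; sub-pixel fragments warn
rather than fail, since the bookkeeping is still exact).  Divergence uses L1
distance on normalised counts (and, for reporting, on coverage): L1 is exact
on binned data and needs no smoothing; a Kolmogorov–Smirnov variant was
considered and rejected because binned ties make its null distribution
awkward.  The verdict is "no effect" when the observed after-distribution is
at least as close to the before-distribution as to the prediction.

## Electrophysiology

The Boltzmann orientation is fixed as I(V) = g(V−Vrev)/(1+exp((V50−V)/k))
with k > 0, so activation grows with depolarisation and inward currents are
negative.  Fits use bounded trust-region least squares with a deterministic,
protocol-aware initial guess: Vrev from the interpolated zero crossing of
the descending limb, V50 from the half-extremal voltage on the rising limb,
k = 5 mV, g from the slope of the final two protocol points.  I_max is the
signed extremum of the fitted curve on a fine grid over the protocol range
(−30…+65 mV); fold-changes use its magnitude.  The preset group pair sets
the "+subunit" conductance so the fine-grid |I_max| ratio is exactly 4.0 and
shifts V50 by exactly −13 mV; per-cell jitter (lognormal on g, Gaussian on
V50) is off by default so zero-noise datasets invert exactly.

Kinetic fits are single exponentials per phase.  The activation window runs
from onset to the peak; because the rising limb is attenuated by concurrent
decay, the rising model carries a fixed decay factor exp(−t/τ_decay) with
τ_decay estimated first from the post-peak phase — leaving τ_act as the
single free time constant and removing a ~16% bias that a bare 1−exp fit
shows at τ_act/τ_inact = 2/50 ms.  The inactivation window starts at twice
the peak time (configurable), where the activation gate is > 99.8% open for
those constants.  A configurable onset skip (default 0 ms in the synthetic
setting, where there is no capacitive transient) is available for real
traces.

Group summaries report mean ± SEM per quantity with unpaired t-tests against
a reference group at the */**/*** tiers; for more than two groups, one-way
ANOVA with Student–Newman–Keuls step-down pairwise decisions at α = 0.05,
implemented on the studentized-range distribution with harmonic-mean n for
unequal group sizes and ties in means broken by group-label order.

## GPI-motif rule engine

Hydropathy uses the Kyte–Doolittle scale; "hydrophilic" means value < 0.
Defaults: spacer window 12 residues from ω+3 with strictly more than 6
hydrophilic residues required; terminal stretch of ≥ 8 contiguous residues
with mean hydropathy ≥ +1.5 ending within 3 residues of the C-terminus;
search window 40 residues from the C-terminus (cryptic internal motifs are
rare; internal scanning is available by widening the window).  The composite
is the unweighted mean of the four component scores, each capped at 1, and
the anchored call additionally requires every component to pass — gating
prevents partial matches from accumulating into a false positive, and makes
the composite monotone: weakening any one element can only lower it.  All
candidate ω positions are reported rather than adjudicated, since even
dedicated predictors disagree on exact ω assignment.  Residue numbering is
1-based on the full polypeptide.  On uniform-random length-100 sequences the
false-anchored rate at these defaults is below 5% (measured by simulation in
the test suite).

## Gradient profiles and raft quantification

Profiles are two Gaussians over the 1–15 fraction index (raft peak at 4,
non-raft at 11, width 0.7), each normalised to unit mass on the grid, so
total signal is conserved exactly and the raft share of a noiseless profile
reproduces the configured weight within ~0.01 discretisation.  Noise is
signal-proportional Gaussian (the sd parameter applies at the peak
fraction), matching film densitometry where fluctuations grow with band
density and avoiding the rectification bias that additive noise plus
clipping at zero would inject into near-empty fractions.  Raft share is the
normalised sum over the designated fractions (3–6 by default, configurable
because gradient geometry varies); the shift call requires a relative drop
of ≥ 0.5 by default.

## Problem sizes in tests and drivers

The test suite and the acceptance script use 200-particle fields on
512×512 px frames (3 rendered replicates, plus 100 generator-level
replicates for the null-experiment verdict rate), 10 cells per group with
200 replicates for Boltzmann estimator bias, 100 seeded traces for kinetic
recovery, 100 profiles per raft weight for densitometry bias, and 400
random sequences for scanner specificity.  These sizes give stable
Monte-Carlo estimates of the quantities asserted while keeping a full run
fast.

## What the synthetic layer does not emulate

Rendered images are 2-D with a spatially uniform Gaussian PSF, flat
background and independent pixel noise: no optical aberrations, no
deconvolution artefacts, no cell-shaped background structure, no
out-of-focus light.  Puncta are non-overlapping by construction when a
minimum separation is set, so detection exactness on synthetic fields says
nothing about segmentation of contiguous or overlapping clusters (the regime
where real analyses fall back on contour maps and line scans).  I-V noise is
i.i.d. Gaussian, without series-resistance or leak artefacts.  Sequences
are random outside the designed motif, not homologous to any real protein
family.  Passing tests therefore validate the estimators and bookkeeping,
not performance on real micrographs, recordings or proteomes.

## Known limitations

* The binomial p ↔ area mapping is a declared convention; other monotone
  maps would change curve shapes (but not the C_t normalisation invariant).
* The adaptive threshold reproduces a local-mean rule, not any specific
  plug-in's kernel; exact particle counts from real thresholded images
  depend on that choice and on visual QC.
* SNK decisions follow the classical step-down scheme; it controls the
  type-I rate per family only approximately for unequal n.
* The motif scanner's thresholds (spacer count, tail length, hydropathy
  cutoff) are config-exposed conventions, not fitted parameters; its calls
  are qualitative.
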