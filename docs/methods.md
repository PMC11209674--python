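# Methods

This note documents the models implemented in `groomcode`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user should know about.

## Behavioral model

Grooming is modeled as a first-order Markov chain over the five phase
symbols {P1A, P1B, P2, P3, P4} with an absorbing STOP state.  Events are
half-open intervals `[start_s, end_s)` in seconds; within a sequence each
phase begins exactly when its predecessor ends, which makes contiguity an
exact (not tolerance-based) check.  The 40 ms video-frame grid is treated
as a validation option of the I/O layer, on by default for scored real
data and off for continuous-time synthetic data: the grid is a property
of the camera, not of the model.  Immediately repeated identical phases
(a unilateral phase done left then right) are merged at ingest, so the
transition matrix has a zero diagonal by construction.

**Transition statistics.**  `P(Y|X) = N(Y←X)/N(X)`, where every phase
occurrence contributes exactly one observed successor (the next phase or
STOP), so row sums of the count matrix equal the phase totals.

**Transition bias.**  `β = log( P̂(Y←X) / (P̂(X)·P̂(Y)) )`, natural log.
The marginals are the row and column marginals of the joint count matrix.
For the from-symbol this is identical to the occurrence frequency
`N(X)/ΣN(X)`; for the to-symbol it counts incoming transitions (it
differs from occurrence counts only by sequence-initial events, and it
gives STOP a well-defined marginal).  This convention was chosen because
it is the unique one under which an exactly independent table gives
`β ≡ 0` and the over/under flags are calibrated: with occurrence-based
marginals that include STOP in the normalization, a memoryless generator
with exit probability `q` leaves a constant offset `−log(1−q)` in every
cell.  Confidence intervals are parametric: the count matrix is resampled
`n_sim` times (default 1000) from a multinomial at the plug-in joint
probabilities with the observed number of transitions, β is recomputed
(marginals re-derived per resample), and the central band is taken at the
configured level (default 0.95).  Flags are per-cell without multiplicity
correction, matching the star convention of transition-matrix displays.
Cells never observed get `β = −∞`; their resampled band is degenerate at
−∞ and they flag as underrepresented.

**Markov validation.**  The fitted chain is simulated forward (vectorized
batches; a sequence of L phases consumes L transitions including the
exit) and the lengths are split into `n_sets` sets of `set_size` lengths
each — the set size defaults to the observed number of sequences so the
band answers "what would a corpus of this size look like if the chain
were true".  Per integer length bin (1..40 plus an overflow bin, since
longer sequences are rare) the 95 % band is the empirical 2.5–97.5
percentile range of per-set counts.  The number of observed-histogram
bins outside the band is summarized by the binomial tail
`P(X ≥ k), X ~ Bin(n_bins, 0.05)`.

**Conditional uncertainty.**  For order i ≥ 1,
`Ĥ(i-tuples) = log₂N − N⁻¹ Σ_j n_j log₂ n_j` over the observed i-tuples
(within sequences only, STOP excluded, c = 5), and
`Ĥ_i = Ĥ(i-tuples) − Ĥ((i−1)-tuples)` for i ≥ 2, where the lower-order
counts are obtained by marginalizing the i-tuple counts over their last
symbol so both terms share one sample.  `Ĥ_0 = log₂5`.  The estimator is
the plug-in (bias-prone at small N); the flatness check `|Ĥ_3 − Ĥ_2|`
is read with a 0.05-bit tolerance at N ≈ 10⁵ tuples for exactly this
reason.

**Exit test.**  Pearson chi-square of homogeneity on the
(exits, non-exits) × phases contingency table, no continuity correction,
df = phases − 1.

**Durations.**  Pairwise two-sample Kolmogorov–Smirnov tests over the
five phases plus (optionally) the inter-sequence pauses, Bonferroni
corrected by the number of pairs; a two-way ANOVA (`duration ~ phase +
animal`, type II, via statsmodels) on phase durations, with the animal
factor dropped when only one animal is present.

## Synthetic generator

The generator exists so that every downstream stage can be tested against
known ground truth.  It emulates:

* sequences from a configurable 5×6 row-stochastic matrix (default chosen
  to reproduce the qualitative regime of scored grooming: P1A/P2 dominate
  occurrence frequency, the chain steps P1B→P2→P3→P4 are overrepresented
  relative to phase frequencies, exit probability differs strongly by
  phase — highest from P4 — and mean sequence length is ≈ 7);
* log-normal phase durations (positive, right-skewed, two parameters per
  phase; defaults match the characteristic scored ranges, e.g. P1B ≈ 1 s
  with small variance, P4 long and variable) and log-normal
  inter-sequence pauses (default median 15 s — pause structure is
  otherwise unconstrained, this is a convenience choice);
* spikes as inhomogeneous Poisson processes, sampled by thinning:
  rate(t) = baseline + Gaussian bumps locked to the archetype's events
  (sequence onset for starters; 0.5 s before sequence end for stoppers;
  onset and 0.5 s after end for bracketers; each phase transition for
  transition-event cells, optionally restricted to a (from, to) pair with
  wildcards; multiplicative per-phase gain for phase-tuned cells; bump
  amplitude `intercept + slope·P(trans)` floored at zero for probability
  coders).  The boundary archetypes place their bumps mid-epoch so that
  the planted class matches the taxonomy's definition — a stopper bump
  centered exactly at the end would straddle the boundary and be a
  bracketer by construction.

It does **not** emulate refractoriness, correlated noise across units,
non-Poisson spike-count statistics, electromyographic signals, or
duration-dependent transition probabilities.  Passing tests therefore
demonstrate that the estimators recover planted structure under the
model's own assumptions, not that real recordings satisfy those
assumptions.

Reproducibility: one global seed; unit k draws from the counter-based
substream `SeedSequence((seed, k))`, so enlarging a unit set never
changes the spikes of existing units.

## PETHs and single-cell statistics

Smoothing and binning commute for linear operators, so "smooth then bin"
is implemented exactly: each spike contributes the mass of its Gaussian
kernel inside each bin (a difference of normal CDFs) and bin mass is
divided by bin width.  Two regimes: sequence boundaries (125 ms bins,
σ = 167 ms, ±10 s window, baseline = all bins of the window — a mixed
grooming/non-grooming baseline) and phase transitions (40 ms bins,
σ = 40 ms, ±3 s window, baseline restricted to bins whose centers fall
inside grooming sequences, passed in as valid intervals; the restriction
applies per (event, bin) sample rather than dropping whole events).
Standardization uses a single mean/SD over the baseline bins of the
trial-averaged PETH.  Silent units (zero baseline SD) get Z ≡ 0 and a
flag.  Events whose window leaves the recording span are dropped, not
zero-padded.

**Epoch significance.**  A cell is significantly modulated in a 1 s epoch
when it shows a run of consecutive bins with |Z| > 2 at least one
smoothing-kernel FWHM long (3 bins in the boundary regime).  The
single-max-bin rule is available (`min_consecutive=1`) but was not made
the default: an epoch contains many correlated bins, and the max-bin rule
yields 13–22 % false positives per epoch on null units, which destroys
the specificity that the starter/stopper/bracketer taxonomy needs (a
starter must be *non*-significant in two end epochs).  Since the kernel
guarantees that any real modulation spans at least its own FWHM, the run
requirement costs essentially no sensitivity.

**Taxonomy.**  bracketer = significant pre-onset and post-end; stopper =
significant pre-end without post-end; starter = significant pre-onset
without any end modulation; the precedence (bracketer first) makes a
cell significant in all four epochs a bracketer.  Starters and stoppers
are mutually exclusive by construction.  The taxonomy is only
well-defined when sequences are longer than the epoch (otherwise the
onset of a short sequence sits inside the end PETH's pre-end epoch);
recovery tests therefore use generator settings with ≥ 2 s phases.

**Population bin test.**  Per bin, the mean Z over cells is compared with
N(0, 1/√n) (one-sample z-test, α = 0.001).

**Time warping.**  Trials sharing one phase pattern are averaged after
linearly rescaling each phase interval to the median duration of that
phase position; each unit's warped profile is standardized before
averaging so high-rate units do not dominate.

**Upcoming-phase preference.**  Mean Z in the 200 ms before the
transition, per upcoming phase (phases with < 5 instances excluded); a
cell prefers a phase when exactly one phase exceeds |Z| > 2.  The chance
rate for the population binomial test is the same statistic evaluated in
a 200 ms control window 1.5 s earlier (still within grooming); a zero
chance estimate is guarded with half a count.

## Population decoding

"Pseudolinear" discriminant = linear discriminant with pooled *diagonal*
covariance and uniform priors.  Features for bin b are the
Gaussian-weighted sum of the 11 adjacent 40 ms bins (σ = 2.2 bins =
88 ms, so ±220 ms ≈ ±2.5σ; the exact σ is a package choice).
Leave-one-out is exact and vectorized: class means and the pooled
variance are down-dated in closed form for each fold, which is
algebraically identical to refitting without the held-out trial.
Classes with fewer than 2 instances are dropped.  Chance is 1/c; the
significance threshold is chance + 2.3 binomial SD (the one-sided 1 %
tail).  Neuron-inclusion curves resample n units (default 100 repeats)
and estimate chance by replacing all rates with standard-normal
surrogates, which keeps the estimator geometry while destroying label
information; added-information curves keep all units of the other
structures in every subset.  When several recordings are analyzed,
curves are averaged per recording first.

## Transition-probability coding

Observations are per (cell, transition instance, window): firing rate in
500 ms windows stepped 100 ms over [−3, 3] s (the grid extent is a
package choice), standardized per unit over all its samples (an
in-grooming-context baseline), and paired with the `P(trans)` of the
transition that occurred, looked up in the conditional matrix fitted on
the same corpus.  Group fits are ordinary least squares of Z on P(trans)
per (structure × cell class × window), p-values uncorrected; windows
with < 20 observations or constant P(trans) are skipped and reported.
The per-cell null shuffles the transition-type identities across the
cell's instances — one permutation per shuffle applied to all windows,
which permutes P(trans) against responses while keeping the response set
fixed; since Σ(x−x̄)² is permutation-invariant the 1000-shuffle null is a
single matrix product.  A cell-window is significant outside the
empirical 95 % band; negative sign = more active around rarer
transitions.  Significant-coder counts per window are compared with the
binomial critical count k*(n) (smallest k with
P(Bin(n, 0.05) ≥ k) ≤ 0.001; k*(100) = 14), and negative vs positive
counts over the [−1, 1] s windows are compared by Wilcoxon signed-rank,
Bonferroni over groups.

## Cell-type classification

Fuzzy c-means (m = 2, 20 restarts, 300 iterations, relative objective
tolerance 1e-8) on z-scored (valley width, peak width, peak-to-valley
time); widths are FWHM by linear interpolation of half-maximum crossings
relative to the zero baseline.  The cluster with the smaller raw-scale
mean spike width is labeled IN (narrow-spiking interneuron convention).
Units below 0.75 membership stay unclassified.  Clustering runs per
structure, pooling structures with fewer than 10 units for stability.
Note that on a single undifferentiated cluster fuzzy c-means still
bisects the cloud, so a minority of outlying points can exceed the
membership threshold; absence of bimodality should be judged from the
membership distribution, not from the labels alone.

## Problem sizes and determinism

The test suite and the acceptance script run everything on synthetic
corpora sized so that the statistical claims are meaningful but cheap:
10⁵ transitions for matrix recovery and entropy profiles, 120 null units
× 100 events for PETH calibration, 80 units per archetype for taxonomy
recovery, 60-sequence sessions with 20-unit ensembles for decoding, and
1000 shuffles for the per-cell coding nulls.  Every random quantity
derives from an explicit seed; pipelines rerun byte-identically.

## Known limitations

* The Poisson spiking model understates real spike-count dispersion
  differences; calibration results (e.g. the 4.55 % |Z| > 2 rate) are
  exact only under that model.
* The plug-in entropy estimator is biased downward at high orders; only
  differences with marginalized counts are reported, and order-5 values
  on small corpora should not be over-read.
* The bias CI is a plug-in parametric band, not a studentized bootstrap;
  for very sparse cells its coverage is approximate.
* Inter-sequence pause structure and the start-phase distribution are
  weakly constrained by scored data; both are explicit, overridable
  generator parameters.
* The drift-diffusion account of phase durations is out of scope; the
  generator's log-normal durations are a phenomenological stand-in.
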