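# Methods

This note documents the models, parameter choices and numerical decisions
behind `smfsid`, and what the synthetic benchmarks do and do not establish.

## The measurement model

A retraction F-D curve of a single unfolding membrane protein is modelled as
piecewise worm-like chain: while the `j`-th intermediate is loaded, the force
follows the WLC interpolation formula

    F(x) = (kB*T/lp) * [ 1/4 (1 - x/Lc_j)^-2 - 1/4 + x/Lc_j ]

until the rupture force of that barrier is reached, then drops to baseline
and the next intermediate (larger contour length `Lc_{j+1}`) takes over.
Parameters: persistence length `lp = 0.4 nm` (unfolded polypeptide),
`T = 297 K` (experiments at 24 °C), contour length `0.4 nm` per residue.
The formula is trusted only for `30 <= F <= 500 pN`; outside that window the
contour-length inversion is undefined and the point is excluded rather than
raised.  The constant term is `-1/4` so that `F(0) = 0`; the `+1/4` variant
one occasionally sees typeset is available via `WlcParams(constant_term=+0.25)`
but is almost certainly a typesetting artifact — with it the worked values of
the force law (e.g. `F = 12.8 pN` at `x/Lc = 0.5`) do not reproduce.

Contour-length inversion solves for the relative extension `u = x/Lc` (the
model is strictly increasing in `u`, so the root is unique) with Brent's
method to `1e-14`, then `Lc = x/u`.  Inversion residuals are below `1e-6 pN`
and round trips recover `Lc` to `1e-6 nm` (verified on 10^4 random points).

## Preprocessing choices

- **Tail region**: the non-contact baseline is taken as the final 20% of
  samples (at least 50 points).  This is a compromise for 1000–3000-point
  curves: long enough for stable statistics, short enough to stay clear of
  the last unfolding peak.
- **Contact point**: the first negative-to-positive force crossing in
  acquisition (ascending-separation) order — adhesion precedes the first
  unfolding rise on retraction curves.  Traces without any such crossing are
  rejected (`no_contact`).
- **Deflection correction**: `s = z − F/k` with the baseline-zeroed force;
  small rupture-induced non-monotonicities (< 2 nm) are stably re-sorted,
  larger ones rejected (`unsortable`).
- **Resampling**: linear interpolation onto a 1-nm grid anchored at the
  contact point.  The grid is fine relative to instrument sampling; no
  further smoothing is applied (the 8-nm histogram bin is the smoother).
- **Trace length** is counted from contact to the last grid point above
  30 pN.  The quality ratio uses this length as its denominator; including
  the unfolding-free tail would dilute every trace below the 0.5 cut.

## Quality scoring

Histogram peaks are local maxima of the 8-nm-binned `Lc` counts (plateaus
keep their leftmost bin, ties in flank minima resolve leftmost — both for
determinism).  A maximum is meaningful when its points number more than 5
and more than 1% of the trace's valid force measures; its score is
`W = exp(-2 f^2)` with `f` the mean flank-to-peak density ratio.  Sub-30-pN
points inherit the score of the next above-floor scored point within 75 nm,
scanning toward larger separation (those points precede the rising branch
that ends in their peak).

Rupture peaks (used for the center length `L`, the length prefilter and the
mean-force observable) are detected on a 5-nm moving average with a 30-pN
prominence requirement, so baseline noise cannot masquerade as a rupture;
the reported height is the raw local maximum near the smoothed peak.

## Distances and clustering

The alignment match score is applied exactly as defined, including its
discontinuity at `|ΔF| = F_scoring`.  The gap penalty is 0 by default: the
mismatch branch is already negative, and length mismatch is penalised
through `N_max` in `d = 1 - SD/N_max`.  `d` is not clamped; values above 1
are possible for grossly dissimilar pairs and propagate as very low
densities.  The pair prefilter (peak-count difference ≤ 2 AND length
difference ≤ 20%) is conjunctive; a disjunctive reading would exclude almost
no pair and defeat its purpose (`prefilter_mode="any"` restores it).
Skipped pairs are infinite distances throughout: k-NN density, δ, and
assignment, which is what isolates statistical outliers.

Density uses `ρ_i = quality_i · (−log r_{k,i})` with
`k = max(10, ceil(sqrt(N)))` by default — the log form preserves density
ranks without estimating the intrinsic dimension, which is why the
dimension-explicit k-NN density estimator is deliberately not implemented.
The global density maximum takes `δ = max` computed distance; ρ ties break
by ascending trace id.  Center selection sweeps points by descending
`γ = ρδ`; a point is a center iff it lies at least `r_cut = 0.3` from every
previously accepted center.  (The alternative reading in which the third
point would require distance *smaller* than `r_cut` contradicts the rule
stated for the second point; the consistent generalisation is used.)  This
sweep deliberately over-generates centers — every pattern seed further than
`r_cut` from existing seeds becomes one — and relies on the refinement stage
to consolidate them.

## Refinement

The area of similarity (AoS) is exact integer-cell arithmetic: cell index
`(floor(x/5), floor(F/5))`, union over the center and its two nearest
computed neighbours, restricted to points above 30 pN and before the
center's last rupture peak.

The membership threshold reads the knee of the descending similarity-score
curve with a two-segment piecewise-linear least-squares fit (the breakpoint
minimising total SSE).  Two guards make this robust:

- the center and its two AoS neighbours are excluded from the fit (their
  scores are ~100% by construction and would fake a knee at rank 3);
- the knee is accepted only if the two-segment fit at least halves the
  single-line SSE **and** the scores drop by ≥ 15% of the top score at the
  breakpoint.  Otherwise the pool has no off-pattern curves to separate
  (a knee requires two populations) and the threshold falls back to 30% of
  the top score, which keeps a uniformly high-scoring pool and rejects a
  uniformly poor one.

Merging processes clusters largest-first; a cluster merges into the earliest
retained cluster sharing more than 40% of its above-threshold traces, with
the overlap measured against the *smaller* set so a small cluster engulfed
by a large one merges.  The stop rule is literal: after four consecutive
merges, if every remaining unprocessed cluster has fewer than 3 traces,
processing stops and those clusters are reported as dropped.

Cluster observables: `Lc_max` is the position of the rightmost meaningful
peak of the pooled `Lc` histogram, refined below bin resolution as the mean
`Lc` of the points in that peak's bins (falling back to the 95th percentile
of member final `Lc` when no pooled peak is meaningful); the mean force
averages the members' rupture-peak heights; the peak profile is the pooled
`Lc` histogram of points in the 40–100 pN band, normalised to unit area.

## Bayesian identification

The prior is the normalised `abundance × ismembrane` product; the abundance
column is assumed pre-normalised to a single scheme (emPAI, PSM or coverage)
per run.  The `Lc` likelihood is Gaussian with mean `0.89 L` and relative
standard deviation `sqrt(0.05² + 0.07² + 0.05²) = 0.0995` (reported as
0.10), replaced by a uniform density on `(L − L_domain, L)` when the
terminal soluble domain exceeds twice that spread (the anchoring point is
then unconstrained within the domain).  Both are proper densities in nm⁻¹,
so they are directly comparable inside one normalisation.

The force likelihood is a per-structure-class lognormal; the shipped
location/scale values (helix ~110 pN, sheet ~200 pN, mixed ~150 pN medians,
shapes 0.45–0.55) are calibration defaults meant to be refit from literature
force tables, configured in `LikelihoodConfig.force_model` and never
hard-coded in logic.  An unknown class is uninformative (constant 1).

The loop-profile factor cross-correlates the cluster's unit-area peak
profile (upsampled linearly from its 8-nm bins to a 1-nm grid) with a
unit-area sum of Gaussians (FWHM 15 nm) at the protein's loop centers, or a
flat line when no structure is annotated, taking the maximum over integer
lags within ±15 nm.  It enters the posterior as a raw nonnegative factor:
any common scaling cancels in the normalisation.

The sampling-yield helper solves the linear relation
`N1c = K · Ntot · P2D` for either the pulling efficiency `K` (μm²) or the
required `Ntot · P2D` budget.

## The synthetic generator

The generator defines the study conditions for every benchmark:

- Gaussian force noise, default `sd = 10 pN` (a typical AFM baseline), plus
  a uniform ±20 pN baseline offset that preprocessing must remove (both
  disabled in noiseless mode, which produces ideal curves for construction
  identities);
- deflection folded back in (`z = x + F/k`, `k = 840 pN/nm`) so the
  separation transform is exercised;
- a 5-nm adhesive dip (−50 pN) before contact and a flat baseline tail of at
  least 60 nm after the last rupture;
- premature detachment truncating at a uniformly chosen intermediate, 23% of
  multi-barrier unfoldings by default;
- spurious traces as sums of 2–4 independent random sawtooths (simultaneous
  attachment: individually WLC-like, jointly inconsistent), and tether
  traces as constant-force plateaus;
- template rupture forces drawn from the class-conditional stability trend
  (sheets unfold at higher forces than helices), mirroring the empirical
  relation the force likelihood encodes;
- paired proteome records derive residue counts from the last barrier via
  `Lc_max ≈ 0.89 × 0.4 nm/residue × n_residues`, place loop centers at the
  unfolding barriers, and keep decoy lengths at least a factor 1.35 away
  from every template (the "separable" regime, ~3 combined sigmas).

What passing the synthetic benchmarks shows: the pipeline's stages are
internally consistent, the clustering separates patterns whose lengths
differ beyond the pair prefilter, and the posterior ranks the generating
template first when length, force class and loop profile are informative.
What it does not show: robustness to drifting baselines, varying persistence
length within a curve, correlated instrument noise, loop-attachment events,
or proteome tables with heterogeneous abundance units — none of which the
generator emulates.

## Benchmark problem sizes

The recovery benchmarks run at desk scale by design: 150-curve mixtures for
clustering recovery (1:1:1 and 1:7:20), 300 curves when 30% spurious traces
are mixed in, and 20 clusters of 25 curves against a 20-protein proteome
(adjacent nominal lengths spaced 11%, ~1.1 combined sigmas, so length alone
does not decide the ranking) for identification.  At these sizes a full
pipeline run takes a few seconds.

## Known limitations

- The knee guard's constants (50% SSE gain, 15% cliff, 30% fallback) are
  heuristics chosen on synthetic score curves; real batches with slowly
  thinning member populations may need per-dataset adjustment.
- With heavy spurious contamination the center sweep plus literal stop rule
  retains small junk clusters (their above-sets exceed 3 traces); the
  template clusters are still recovered and pure, but the *total* cluster
  count is not 3 — consolidating junk requires information the algorithm
  does not model.
- Lognormal force defaults are calibration placeholders, not fits.
- The alignment is O(N²) per pair; batches beyond ~10⁴ curves need the
  prefilter tightened or blocking by length.
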