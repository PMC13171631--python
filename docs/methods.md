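# Methods

This note documents the models, estimators and numerical choices behind
`microcensus`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Census model and provenance stratification

The unit of observation is a marker-gene sequence assigned to a
species-level cluster (clustering happens upstream at a fixed identity
cutoff, conventionally 96.5%; the package records the cutoff as metadata
and accepts any cluster assignment). Each sequence carries a provenance
label — isolate reference genome (`PROGENOMES`), reference catalogue
(`GTDB`), study MAG (`SPIRE_MAG`) or unbinned contig (`UNBINNED`) — plus
sample, contig and habitat fields where applicable.

Clusters are attributed to the *highest* tier present among their members:
one isolate-reference sequence makes the whole cluster a reference cluster
regardless of its other members. Unbinned-only clusters count as
*non-singletons* only when they contain at least two sequences from
different contigs; this independent-observation requirement is the
conservative lower bound on unbinned diversity, since a singleton may be an
assembly artefact. We implement the different-contig test (an option can
tighten it to different samples). The four top-level categories are
disjoint and their cluster counts sum to the total — an invariant the test
suite enforces at every rarefaction point.

## Conversion factors

Cluster counts are converted to species counts by the slope of
`species ~ clusters` with the intercept forced through the origin
(`Σxy / Σx²`), estimated along a logarithmic downsampling of the
genome-derived (species-labelled) sequences with 10 random draws per grid
step. The standard error is the usual through-origin form
`sqrt(Σr² / ((n−1)·Σx²))`.

Because the species-vs-clusters trajectory is concave (a species' first
sequence reveals one cluster; its full cluster multiplicity only appears at
depth), the through-origin slope carries a small upward bias relative to
the asymptotic species-per-cluster ratio — in synthetic recovery runs with
true factor 0.8 the estimate averages ≈ 0.83–0.85. Per-data-source fits
(isolate + catalogue references, where every cluster of a species is
genome-backed) are less biased than pooled fits that include MAG-tier
species whose rare clusters may never be observed; the function exposes a
`sources` argument for this reason and the conversion is fit per source by
default in the analysis scripts.

## Rarefaction and discovery coefficients

Rarefaction is sample-based and without replacement: at each point `N` of
the logarithmic grid (10, 20, …, 100; 200, …, 1,000; …, capped at and
including the dataset size), 5 random sample subsets are drawn and
discovered clusters counted, stratified by the provenance of the *full*
cluster (genome-derived records are attachable annotations, never samples).
Permutations are drawn independently per marker. For ≤ 6 samples an
exhaustive mode enumerates every subset; the tests verify it against the
closed-form hypergeometric expectation
`E[discovered] = Σ_c (1 − C(n−m_c, N)/C(n, N))`.

The discovery law is fit on *marginal* gains: differences of the
permutation-mean cumulative curve between consecutive grid points, placed
at geometric midpoints `√(N_i·N_{i+1})` (the unbiased abscissa on a log
grid), with `log(ΔS/ΔN)` regressed on `log N`; `γ = −slope`,
`α = 1 − γ`. Zero gains are excluded from the log regression; if more than
half the marginals are zero the curve is reported as empirically saturated
(sentinel fit with `α = 0` and a `saturated` flag) rather than fitted. An
alternative `mode="cumulative"` fits the integrated form
`S_cum ∝ N^(1−γ)` as a cross-check; log-marginal is the default because it
transcribes the law's definition directly. Saturation classes: `α ≤ 0`
saturated, `α ≥ 0.8` near-unsaturated (virtually no slowdown), otherwise
open.

The synthetic curve generator places its marginal gains exactly at the
fitter's geometric midpoints, so noise-free recovery of γ is exact to
machine precision — this checks the estimator's algebra, not its
robustness; robustness is checked separately with multiplicative lognormal
noise (γ recovered within ±0.02 at noise_sd = 0.05 over 50 seeds).

## RED and clade delineation

RED is computed by the standard recursion
`RED(node) = RED(parent) + (d/u)·(1 − RED(parent))` with `u` the mean
branch-length distance from the parent to the tips descending through the
node; tips are fixed at 1, the root at 0, zero-length branches inherit the
parental value, and multifurcations are supported. Since `d ≤ u`, RED is
monotone along every root-to-tip path. On ultrametric trees RED equals
relative node depth exactly, which the planted-tree tests exploit.

Trees are cut with the first-crossing rule: clade roots are the maximal
nodes with `RED ≥ cutoff`; every tip then belongs to exactly one clade
(tips not under an internal crossing become singletons), so the output is
always a partition. Cutoffs per rank are calibrated by scanning candidate
cutoffs — a uniform grid of step 0.01 *augmented with the observed node RED
values*, so that every achievable partition is visited — and scoring each
partition against reference labels (restricted to labelled tips) with AMI
under arithmetic-mean normalization (scikit-learn). Ties are broken toward
the smallest cutoff. The ±0.1 tolerance is carried as the acceptance window
around the selected cutoff, not as a modification of the cut rule. GTDB's
reference cutoffs are shipped as config defaults for Bacteria-mode runs;
data-driven calibration is the default otherwise.

Alternative rootings (each recognized phylum in turn as outgroup) are
supported by matching nodes across rootings via their descendant tip sets
and averaging RED over the rootings in which a node exists outside the
current outgroup; the root is placed at the midpoint of the branch
subtending the outgroup's MRCA. We average RED first and scan once
(per-rooting scanning remains possible by calling the scan on each rooting).

Clades are labelled `reference` (≥ 1 isolate/catalogue member),
`mag_only`, or `unbinned_only`, and clade counts are summarized as the
median ± sample s.d. across markers (s.d. 0 for a single marker). Phylum
subtree profiles locate each phylum's MRCA from a random 80% subset of its
genome-backed tips, 5 times, and average the ratio of unbinned-only to
genome-backed tips, damping label and inference errors.

## Clade-size laws

The Willis fit is an unweighted OLS of `log C` on `log S` over observed
sizes only (no fabricated zeros), matching the plain log–log-slope
convention; `ω = −slope`, `a = exp(intercept)`. Two options matter for
heavy-tailed data: `binning="log2"` pools counts into geometric bins of
ratio 2 and fits bin densities, which removes the severe flattening bias
caused by the count-1 scatter in the tail, and `s_min` drops the smallest
sizes, where the Yule–Simon pmf genuinely deviates from its power-law
asymptote (at ρ = 2 the pmf at S = 1 is 2/3 versus 4 for the asymptote).
The raw unbinned fit is the default; the binned variant with `s_min = 2` is
what verifies the asymptotic relation ω ≈ ρ + 1 (within 0.3 at 10⁵-clade
samples for ρ ∈ {0.5, 1, 2}).

The Yule–Simon pmf `ρ·B(S, ρ+1)` is evaluated in log space via `betaln`.
ρ is estimated by maximum likelihood: one-dimensional bounded minimization
of the negative log-likelihood over `log ρ` (±12 natural-log units around
the method-of-moments start `ρ₀ = mean/(mean−1)`, or 5 when the mean does
not exceed 1; `xatol = 1e-12`), with the standard error from the observed
information (central second difference). The bounded search is robust when
the optimum sits far from the start (e.g. two very large clades pushing
ρ̂ → 0). An all-singleton sample sits on the ρ → ∞ boundary and raises
`DegenerateDistributionError` instead of returning a fit. The MLE is
verified against a dense (10⁻³) grid-search oracle and recovers ρ within
±0.05 from 10⁵-clade samples. Size distributions can be tabulated from
nested RED partitions (tips per clade, or subclades of the subordinate
rank per clade), or from flat parent/child taxonomy tables with unlabelled
placeholders excluded; stratified fits rebuild distributions per habitat or
phylum and report the median ρ across markers. No truncation is applied by
default (neither singleton exclusion nor large-size capping); both are
available as explicit choices.

## Synthetic world

The generator emulates the *structure* of a cross-habitat census, not its
sequences (no nucleotides, reads or assembly artefacts are produced):

- **Occupancy.** Per-species sample-occupancy probabilities follow either
  a clipped lognormal (default `μ = −6, σ = 2` on the log scale — median
  occupancy ~0.25% of samples with a heavy tail, putting the default world
  in the open-discovery regime where roughly half the species pool is
  unobserved at 500 samples) or a log-series (`θ = 0.95`), both standard
  long-tailed choices reproducing a singleton-heavy cluster-size spectrum.
  Species have a home habitat; off-habitat occupancy is scaled by a
  leakage factor (default 0.1).
- **Provenance tiers.** Each species draws one tier from a categorical
  (defaults 0.10/0.10/0.20/0.60 for isolate/catalogue/MAG/unbinned).
  Reference-tier species contribute genome records — with geometric
  (mean 20) genome counts floored at the species' cluster count, so a
  sequenced species exposes all its clusters, as deep reference catalogues
  do — and their sample occurrences surface as unbinned contigs; MAG-tier
  species surface as study-MAG sequences in samples.
- **Cluster splitting.** Each species has `1 + Poisson(rate − 1)` gene
  clusters per marker (expected `cluster_split_rate`, the ground-truth
  inverse conversion factor); rates below 1 switch to a lumping regime
  where species share cluster slots.
- **Gene trees.** Pure-birth (Yule) trees with exponential waiting times;
  all tips contemporaneous, so branch lengths are time and RED equals
  relative depth exactly. Rank labels are planted by cutting the *true
  chronology* at fixed fractions (0.20/0.35/0.50/0.65/0.80 of the
  root-to-present span for phylum…genus), never from RED, keeping the
  calibration tests non-circular; cutting above the first split guarantees
  at least two clades per rank.
- **Simon process.** Species are added one at a time; with probability `p`
  a new clade is founded, otherwise the new species joins the clade of a
  uniformly chosen earlier species (size-proportional attachment). The
  first step always founds the seed clade, making the `p → 0` limit well
  defined. The stationary clade-size law is Yule–Simon with
  `ρ = 1/(1−p)`.

All randomness flows through one `numpy` generator per operation, seeded
explicitly; fixed seeds give byte-identical outputs, which the pipeline
tests verify file-by-file.

**What passing tests show — and don't.** Recovery on these worlds
demonstrates that the estimators are correctly implemented and statistically
consistent under the stated generative assumptions. Real censuses violate
those assumptions in known ways (chimeric and fragmented assemblies,
paralogue cross-mapping, habitat annotation errors, non-ultrametric gene
trees with rate variation, correlated sampling), so synthetic recovery
bounds are not error bars for real-data estimates.

## Problem sizes and defaults

The default pipeline world (2,000 species, 2 × 250 samples, 3 markers,
150-tip trees) is sized so a complete run finishes in seconds while leaving
every regime visible (open discovery, mixed provenance, multi-rank
partitions); the acceptance checks use larger dedicated draws where
precision matters (10⁵-clade Yule–Simon samples, 5 × 10⁴-step Simon runs,
50-seed discovery recovery, 300-tip calibration trees, 1,000-tree RED
monotonicity sweeps).

## Known limitations

- The through-origin conversion regression is biased upward a few percent
  on concave trajectories (see above); the bias vanishes as reference
  sequencing depth per species grows.
- RED-vs-chronology equivalence holds only for ultrametric trees; on real
  gene trees with rate variation, planted-style exactness is unattainable
  and calibration quality degrades gracefully with AMI < 1.
- `average_red_over_rootings` matches nodes by tip set; nodes dissolved
  under every alternative rooting keep their original-rooting value.
- The Willis raw-OLS default reproduces the conventional log–log slope but
  is a poor estimator of the tail exponent on heavy-tailed data; use the
  binned variant when the exponent itself is the target.
- No extrapolation beyond observed sampling depth is offered (no Chao-type
  richness estimators), by design.
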