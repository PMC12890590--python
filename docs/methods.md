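# Methods

This note documents the models, estimators and numerical choices behind
`ccons`: what each stage computes, what the synthetic-data generator does
and does not emulate, and where the design was genuinely open.

## 1. The community-conservatism statistic

For an OTU pair (i, j) the relatedness axis is the patristic distance on a
rooted, branch-length tree over fine-level ("99%") OTU ids. Polytomies are
resolved deterministically into caterpillars of zero-length branches in
child order, which leaves all leaf-to-leaf path sums unchanged; missing
branch lengths read as 0 with a logged warning. Distances are computed
once into a dense matrix by a postorder sweep (depth(i) + depth(j) −
2·depth(MRCA)); the dendropy distance matrix serves as an independent
oracle in the tests.

The similarity axis is the mean Bray–Curtis similarity (BCS = 1 − BC)
between the sample set S_i (samples containing i) and S_j. Comparisons are
the ordered cross-set pairs (x, y), x ∈ S_i, y ∈ S_j, excluding x = y and
pairs sharing a project id. This yields the closed-form count

    n = |S_i|·|S_j| − |S_i ∩ S_j| − #{(x, y): x ≠ y, project(x) = project(y)},

which the implementation reproduces exactly and the tests verify on
hundreds of synthetic pairs. Samples without a project id are treated as
singleton projects (never excluded against each other). A sample that
contains both OTUs participates on both sides (against every *other*
sample of the partner set); only self-comparisons are excluded. BCS is
computed on relative abundances at the coarse ("90%") OTU level, making
the statistic invariant to sequencing depth; a raw-count mode exists
behind a flag. Above a configurable cap (default 250,000) the comparison
set is estimated by a seeded uniform subsample and flagged; the recorded
`n_comparisons` is always the closed-form total.

Robustness variants re-transform every sample before normalization:
`log` (log(1+c), a zero-safe stand-in for log-fraction weighting — it
approximates, not reproduces, the corresponding option of the original
cluster tool), `rarefied` (multivariate-hypergeometric subsample to a
fixed depth, samples below depth dropped), and `top_k` (richness
restricted to the k most abundant OTUs, ties broken towards the
lexicographically smaller OTU id).

## 2. Pair sampling

Pairs are drawn uniformly over distance: the retained range is [0, q] with
q the 97th percentile of pair distances (estimated from all pairs when the
tree is small enough to enumerate, otherwise from 100,000 random pairs);
the range splits into 50 equal-width bins with quota ⌈n_pairs/50⌉ each,
trimmed from the last bins to the requested total (and the bin count is
capped at n_pairs for degenerate requests). Bins fill round-robin from
seeded-shuffled candidate lists, skipping any pair that would lift either
OTU above its usage cap (9; relaxed to 30 when the OTU pool is under
3,000, an opt-in parameter so that small test trees still honour the
9-cap by default). Exhausted bins underfill with a logged warning — on
Yule trees the near-zero-distance bins genuinely run out of cherries.

The most specific shared taxonomic rank of a pair scans species → domain
and returns the first rank where both lineages are filled and equal.
Sample-set overlap is Jaccard on occupancy sets (a min-denominator option
exists); the choice of denominator was open and Jaccard was preferred for
its symmetry.

## 3. Null models

The global baseline is the mean BCS of uniformly drawn distinct,
cross-project sample pairs (the same exclusions as the signal, so null and
signal stay exchangeable). Environment-combination baselines condition
both samples on carrying given environment labels (a sample annotated to
two environments belongs to both classes; unannotated samples form an
`unassigned` class). Group-specific expectations re-weight the combination
baselines by the group's observed combination frequencies (weights sum to
1 within 1e−9). Normalization is element-wise division; 1.0 means
"at baseline".

The calibration band for a distance bin of m pairs is bootstrapped from
the weighted baseline: each null pair draws a combination from the weight
mixture and one BCS value from that combination's stored draws; the band
is the central 95% of the resulting bin means. Treating a null pair as a
*single* comparison-level draw upper-bounds the dispersion of true pair
means (which average many correlated comparisons), so the band is
conservative; on shuffled (conservatism-free) data the observed coverage
is nevertheless informative because bin means also carry the combination-
mixture variance that dominates at desk scale.

## 4. Trend fitting

Lowess uses tricube weights, local linear fits, span 1/5 and 3 robustness
iterations (statsmodels); duplicate x positions are averaged so the output
grid is strictly increasing. The parametric fit is y = a·e^{kx} + c by
Levenberg–Marquardt least squares, initialized at a = max(y) − min(y),
k = −1, c = min(y); the three-parameter form with an additive asymptote is
the default because empirical curves flatten above the null baseline, and
c can be fixed at 0 for the pure two-parameter form. Non-convergence,
near-zero amplitude and a positive fitted k are flagged, never raised.
Bootstrap bands resample cases (pairs), fit lowess per resample, evaluate
all fits on a common 200-point grid (linear end-slope extrapolation where
a resample does not reach the grid edge) and report mean ± 1.96 SD.

## 5. Rank windows, ratios, generalism, outliers

Because not all OTUs carry full taxonomy, curve steepness uses distance
windows rather than labels: for species, genus and phylum, the window is
the [20th, 80th] percentile interval of the distances of pairs sharing
exactly that rank. Window membership is interval-wise (windows may in
principle overlap). The species/genus and species/phylum ratios of window
mean BCS quantify steepness; baseline normalization rescales the means but
cancels in the ratios. Contrasts use the two-sided Mann–Whitney U test
(exact enumeration when both sides have ≤ 8 untied values, otherwise the
tie-corrected normal approximation), Benjamini–Hochberg correction within
each test family, and Cohen's d with pooled Bessel-corrected SD — the
variant was unspecified and pooled-SD is the common default.

Generalism is the Shannon entropy of an OTU's per-environment mean
relative abundances normalized to sum to 1 (0·ln 0 = 0; bounds 0 … ln K).
Top/bottom 10% by entropy define generalists/specialists, ties broken by
OTU id. Outlier pairs require a minimum number of comparisons (default
10,000) and are `related_divergent` when distance < 0.2 and mean
BCS < 0.04, `distant_similar` when distance > 0.8 and mean BCS > 0.08;
thresholds refer to raw (unnormalized) means. Phylogeny-matched controls
draw, per focal pair, one candidate within ±0.025 distance uniformly
without replacement, never the focal pair itself; unmatched focals are
reported.

## 6. Time series

OTUs present in strictly more than 10% of timepoints are retained;
relative abundances are computed over the retained reads per timepoint;
replicate samples at one timepoint are averaged after relative-abundance
conversion. Pairwise Pearson correlations of the profiles are joined with
tree distances (constant profiles are flagged and excluded, using a
relative tolerance of 1e−9 against float residue). Summary correlations
are refused below 3 pairs, and a constant similarity column is flagged as
undefined rather than crashing.

## 7. The synthetic-data generator

The generator plants exactly the structure the analysis is designed to
detect, and nothing else.

**Tree.** Yule pure birth, conditioned on n tips, rescaled to root height
1 (so all distances lie in [0, 2]); leaves named in birth order.

**Niche evolution.** Each leaf carries a K-dimensional latent trait that
starts at 0 at the root and evolves along branches as an
Ornstein–Uhlenbeck process with Brownian diffusion rate σ (the
*conservatism rate*) and fixed stationary standard deviation s
(`niche_sd`, default 0.22), i.e. mean-reversion rate θ = σ²/(2s²). The
between-leaf trait correlation decays as e^{−θd} with patristic distance
d, so σ sets purely *how fast lineages forget their ancestral niche*
while the stationary variance pins how strongly niches differentiate at
all. This separation is the reason for preferring a mean-reverting trait
over unbounded Brownian motion: under shared-root Brownian motion the
between-leaf correlation equals the MRCA-depth fraction regardless of σ,
so σ only rescales trait magnitude and *larger* σ produces a stronger —
not weaker — distance signal; a σ-tunable conservatism rate is then
impossible. With σ = 0 the trait never moves and all affinities are
uniform. Affinities are softmax of the latent trait standardized to
spread 3.0 (times `affinity_sharpness`; > 1 plants specialists, < 1
generalists). Defaults (s = 0.22, rank cuts below) were chosen once so
that at σ = 0.5 the decay spans the full observable distance range while
remaining clearly resolvable between the species and genus windows;
σ = 4.0 decorrelates niches below species-level distances and serves as
the conservatism-free contrast.

**Samples.** Each sample draws an environment (uniform over the five
canonical labels by default, so all 15 combination baselines are
estimable at desk scale; a corpus-like skew is configurable) and a
project uniformly; each OTU enters with probability
clip(occupancy·K·affinity, 0, 1) and, if present, expected relative
abundance ∝ lognormal base abundance × affinity; counts are multinomial
at 10,000 reads (matching the rarefaction-control depth). Raw metadata
keywords use synonyms (ocean, sea, lake, river…) so the keyword lexicon
is exercised in-pipeline. The coarse OTU map and the taxonomy come from
cutting the tree at fixed ages — species 0.04, genus 0.16, family 0.28,
order 0.40, class 0.55, phylum 0.70, coarse level 0.10 — so taxonomic
ranks track phylogenetic distance and nest by construction.

**Time series.** Per-OTU sinusoidal intensities with Brownian-evolving
phases and multinomial counts. Note a compositional subtlety the tests
respect: a seasonal factor shared by *all* OTUs cancels under per-
timepoint renormalization, so planted co-fluctuation is only recoverable
from counts when phases differ between OTUs; the shared-phase property is
asserted on the underlying intensities.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: uneven sample counts per project, spatial or
temporal autocorrelation between samples, taxonomy–phylogeny
disagreements, 16S copy-number variation and horizontal transfer,
detection noise beyond multinomial sampling, and realistic corpus-scale
marginals (beyond order of magnitude). Results on synthetic data
demonstrate the pipeline's correctness and calibration, not ecological
conclusions.

## 8. Problem sizes and determinism

The test suite and the reproduction script run the full analysis at
300 OTUs × 2,000 samples with ~2,000 requested pairs and a 150–200
comparison subsample per pair, with 20-replicate checks at the same or
slightly smaller sizes; these sizes give each window dozens to hundreds
of pairs and stable window contrasts on a single CPU in minutes. Every
stochastic operation takes a seed or numpy Generator and all outputs are
byte-identical under a fixed seed.

## 9. Known limitations

- Near-zero-distance bins on Yule trees (and on real 16S trees) are
  supply-limited; the sampler underfills them with a warning rather than
  biasing towards reused OTUs.
- The species window at desk scale holds only ~50 pairs, so
  species-vs-genus contrasts on unlucky trees can be underpowered; the
  replicate-level ordering of σ is robust.
- The log-BCS variant is an approximation (log(1+c) pre-normalization);
  the exact weighting of the original cluster tool's log-fraction option
  is not public.
- The null-calibration band is deliberately conservative (§3); it bounds
  the null dispersion from above rather than estimating it exactly.
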