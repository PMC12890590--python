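# ccons — community conservatism in microbial communities

Phylogenetic signal and niche conservatism — the tendency of related
organisms to resemble each other and to retain ancestral niches — are hard
to assess in microorganisms because most lineages are uncultured and their
phenotypes unknown. `ccons` implements a community-centric alternative:
treat the *community composition* of the samples an OTU occurs in as a
proxy for its realized niche, and ask how the similarity of two OTUs'
communities decays with their phylogenetic distance. A strong decay —
**community conservatism** — indicates that close relatives occupy similar
communities and, by proxy, similar niches.

The package is aimed at microbial ecologists and method developers working
with large 16S OTU tables (samples × OTUs), sample metadata and a
phylogeny, and at anyone who wants a fully testable, synthetic-data-driven
implementation of the workflow.

## The statistic

For an OTU pair (i, j) with patristic tree distance d(i, j), every sample
containing i is compared against every sample containing j — excluding
identical samples and samples from the same research project, which would
inflate similarity through co-occurrence and batch effects. Each
comparison is scored with the Bray–Curtis **similarity**

    BCS(u, v) = 1 − BC(u, v) = 2 Σₖ min(ũₖ, ṽₖ) / (Σũ + Σṽ),

computed on relative abundances at a coarse (genus-like, "90%") OTU level,
and the pair is summarized by the mean (quantiles are recorded too). The
analysis then:

- samples OTU pairs **uniformly over phylogenetic distance** (50 equal
  bins, furthest 3% of distances trimmed, each OTU used in at most 9
  comparisons — 30 in pools under 3,000 OTUs);
- fits the distance→similarity trend with **lowess** (frac = 1/5) and an
  **exponential decay** y = a·e^{kx} + c, with 30-bootstrap ±1.96 SD bands;
- compares the trend against **null models**: the expected BCS of random
  cross-project sample pairs, stratified by environment combination
  (animal, marine, freshwater, plant, soil) and re-weighted per group;
- quantifies **curve steepness** as the ratio of mean BCS in the species
  window to the genus and phylum windows (the middle 60% of each rank's
  pair-distance distribution), with Mann–Whitney U contrasts,
  Benjamini–Hochberg correction and Cohen's d;
- scores **habitat generalism** per OTU as the Shannon entropy of its
  normalized mean relative abundances across environments, flags **outlier
  pairs** (closely related yet community-divergent, or distantly related
  yet community-similar), draws **phylogeny-matched controls**, and checks
  temporal consistency by correlating OTU **abundance profiles over time**
  against tree distance.

Everything runs on synthetic data with a *planted* conservatism signal: a
Yule tree whose leaves carry environment-affinity vectors evolving under a
mean-reverting latent trait, so the rate at which lineages forget their
ancestral niche is a tunable parameter (σ). See `docs/methods.md` for the
model and its assumptions.

## Worked example

```python
from ccons.pipeline import run_planted

# 300 OTUs, 2,000 samples, 5 environments, strong conservatism (sigma = 0.5)
dataset, result = run_planted(sigma=0.5, seed=0, n_pairs=2000, fit_expdecay=True)
print(f"pairs analysed:        {len(result.valid_pairs)}")
print(f"lowess–distance rho:   {result.lowess_spearman:.3f}")
print(f"decay coefficient k:   {result.expdecay.params[1]:.2f}")
print(f"species/genus ratio:   {result.ratios.sg_ratio:.2f}")
print(f"species/phylum ratio:  {result.ratios.sp_ratio:.2f}")
```

prints

```
pairs analysed:        1429
lowess–distance rho:   -0.935
decay coefficient k:   -2.86
species/genus ratio:   1.46
species/phylum ratio:  2.03
```

The fitted curve falls almost monotonically with distance (Spearman −0.94
between fitted values and distance), the similarity of species-window
pairs is 1.46× the genus window and 2.03× the phylum window, and both
window contrasts are significant after Benjamini–Hochberg correction
(adjusted p ≈ 8×10⁻⁶ and 7×10⁻⁶): the planted conservatism is recovered
end to end. Re-running with `sigma=4.0` (fast niche turnover) flattens the
curve and pulls both ratios towards 1.

The same workflow is available from the shell:

```bash
ccons --seed 1 simulate --out data/
ccons qc --table data/table99.tsv --meta data/metadata.tsv --out qc.tsv
ccons collapse --table qc.tsv --map data/child_to_parent.tsv --out table90.tsv
ccons --seed 2 pairs --tree data/tree.nwk --taxonomy data/taxonomy.tsv \
      --n-pairs 2000 --out pairs.tsv
ccons --seed 2 bcs --pairs pairs.tsv --table table90.tsv \
      --occupancy-table qc.tsv --meta data/metadata.tsv --out pairs_bcs.tsv
ccons fit --pairs pairs_bcs.tsv --method both --out trend.tsv
```

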