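# Methods

## Data model

The 16 typed KIR markers are treated as presence/absence bits per individual.
Chromosome-level variation is modeled as *gene-content haplotypes*: a
centromeric motif (Cen-A, Cen-B1, Cen-B2 or Cen-B3) and a telomeric motif
(Tel-A, Tel-B, or Tel-B with the KIR3DS1 deletion) on a fixed framework
(KIR3DL3, KIR3DP1, KIR2DL4, KIR3DL2).  Motif content follows the published
segregation/sequence-based catalog: Cen-A = {2DL3, 2DP1, 2DL1}; Cen-B1 =
{2DL2, 2DS2, 2DL5, 2DS3S5, 2DP1, 2DL1}; Cen-B2 = {2DL2, 2DS2}; Cen-B3 =
{2DL3, 2DL5, 2DS3S5, 2DP1, 2DL1}; Tel-A = {3DL1, 2DS4}; Tel-B = {3DS1, 2DL5,
2DS3S5, 2DS1}.

KIR2DS3 and KIR2DS5 are alleles of the duplicated 2DS3S5 locus.  Because the
assay types them as separate markers, the a priori haplotype list is stored
at marker level: every occupied 2DS3S5 slot is expanded into one variant per
allele (Cartesian over motifs), so the 8 motif-level haplotypes (6 common
Cen×Tel combinations + Cen-B3~Tel-A + the 3DS1-deletion haplotype) become 18
marker-level variants.  Expansion is the default because it makes every
downstream operation pure set arithmetic; estimates can be re-aggregated to
motif level by summing variants (`HaplotypeFrequencyEstimate.aggregated`).
Copy number is not modeled: a locus present on both motifs of a diploid
yields one presence bit (union semantics), exactly what the typing observes.

Genotype tables are CSV (population, region, individual_id, 16 binary
columns).  Rows with missing or out-of-domain values are rejected with a
logged diagnostic rather than imputed — there is no principled single-locus
imputation for gene-content data at these sample sizes.

### Packaged reference tables

`hgdp_populations.csv` stores the 52 HGDP-CEPH samples (region, n,
coordinates); printed coordinate ranges are resolved to midpoints with south
and west negative.  Four entries are internally inconsistent in the source
(Biaka Pygmies, Bedouin, Barusho, Pathan); they are stored as printed and
marked in `coordinates_flagged` rather than corrected, since any correction
would be a guess.  `hgdp_kir_frequencies.csv` stores the published carrier
and gene frequencies (3-decimal precision) for all 52 populations × 16 loci.

## Frequency estimation

Carrier frequency is k/n.  Gene frequency for a dominant presence marker uses
the null-homozygote square root: with x = (n−k)/n, `p = 1 − √x`.  The
packaged gene-frequency table is reproduced *exactly* (832/832 cells at three
decimals) by this uncorrected estimator applied to counts back-computed as
k = round(carrier·n), so `bias_corrected=False` is the default.  The
Lynch–Milligan correction, `q = √x / (1 − Var(x)/(8x²))` with
Var(x) = x(1−x)/n, is provided for completeness; it lowers the gene-frequency
estimate (the plain square root overestimates p by underestimating the null
allele q) and equals it at k = 0 and k = n.

The biallelic loci (2DL2L3, 3DL1S1) are direct-counted at genotype level:
A-only individuals are AA, B-only BB, A-and-B AB, giving
pA = (n + kA − kB)/2n.  Individuals carrying neither allele contradict the
locus-always-present assumption; `biallelic_direct_frequency` raises with
their count and `biallelic_frequency_excluding_negatives` drops them from the
denominator with a warning — the behavior used throughout, since deletion
homozygotes at 3DL1S1 are known but rare (one in the whole reference panel).

Display rounding is half-up to 3 decimals (`present_3dp`); computation is
always unrounded.

## Constrained EM

Individuals are grouped by distinct presence pattern.  For pattern g the
compatible set is every unordered pair (i ≤ j) from the expanded a priori
list with markersᵢ ∪ markersⱼ = g; candidates are prefiltered to subsets of g
(verified against unfiltered brute-force enumeration in tests).  The list
spans a sample when no pattern has an empty compatible set.

E-step: posterior weight of pair (i,j) for an individual is proportional to
(2 − δᵢⱼ) fᵢ fⱼ (HWE random union of gametes).  M-step: f_k = expected count
of k over the 2N resolved chromosomes.  The observed-data log-likelihood
Σ_g c_g log Σ_{(i,j)∈C(g)} (2−δᵢⱼ) fᵢ fⱼ is non-decreasing per iteration
(asserted on every fit in the tests).

Numerical choices: convergence at absolute log-likelihood change < 1e−8 with
a 2000-iteration cap; restart 0 always initializes uniformly over the list
(deterministic default), optional extra restarts draw Dirichlet(1) vectors
from a generator seeded by `EMConfig.seed` — compatible-pair likelihoods can
be multimodal, but reproducibility comes first; frequencies below 1e−10 are
truncated to zero and renormalized on output only.  Two marker-level variants
can share a marker set (e.g. 2DS3-cen/2DS5-tel vs 2DS5-cen/2DS3-tel); they
are then likelihood-equivalent and EM splits their mass symmetrically, which
is why recovery is evaluated after aggregation to motif level.

Sharp mode is the stated contract of constrained estimation (error and
"increase the a priori set"); lenient mode — exclude unspanned individuals
and report `unresolved_fraction` — reflects how estimates are produced in
practice when a few percent of genotypes fall outside the list.  How
unresolved mass should be renormalized into reported frequencies is not
standardized; this package reports frequencies over resolved chromosomes plus
the unresolved fraction separately, and callers may pool the remainder as
"other".

List augmentation is greedy set-cover over a candidate space (default: all
Cen×Tel motif recombinants plus single-marker deletion variants of the base
list), adding the candidate that newly spans the most unspanned distinct
genotypes, ties broken by fewer markers then name.  Greedy cover is not
always minimum-cardinality; the tests compare against exhaustive minimal
subsets on small instances.

## Hierarchical gene-diversity partition

For one locus with per-population allele frequencies: H_S = mean
within-population diversity (1 − Σp²), H_R = mean over regions of the
diversity of the region's mean frequency vector, H_T = diversity of the
global mean vector; reported shares are (H_S/H_T, (H_R−H_S)/H_T,
(H_T−H_R)/H_T).  Two estimator options matter at HGDP-CEPH sample sizes
(7–46 individuals):

* `weighted` — populations weighted by sample size everywhere (equivalent to
  pooling allele counts).  Default off, matching the textbook unweighted
  treatment of gene-diversity analysis.
* `unbiased` — Nei's small-sample correction 2n/(2n−1) applied to each
  within-population diversity.  Default off.

On the packaged tables the unweighted default attributes far more diversity
to the between-population level than the published partition (sampling noise
from small n inflates apparent differentiation, and unweighted means let the
smallest samples dominate).  The weighted + unbiased combination is the
better match: it reproduces the published KIR2DL2L3 partition within ±0.01
per component and the KIR3DL1S1 between-population share (0.003 vs 0.002),
though the 3DL1S1 within/between-region split still differs by ~0.018 — no
consistent estimator variant tested closes that gap from the printed tables
alone, plausibly because the published computation used unrounded genotype
counts and/or its own deletion handling at that locus.  The acceptance tests
compare the weighted + unbiased variant and leave the 3DL1S1 discrepancy
visible rather than hiding it.

Raw between components can be negative under unweighted means; they are
clamped to zero with a warning and the triple renormalized.  Monomorphic data
(H_T = 0) is an explicit error.

Nei (1972) standard distance is D = −ln(J₁₂/√(J₁J₂)), summing
allele-frequency products across loci before the log; disjoint allele sets
give an infinite-distance sentinel.  The distance measure behind published
KIR distance tables is not named, so D is offered as the standard default
and no published value is asserted against it.

Clustering uses Euclidean dissimilarity with complete linkage on both axes of
the (unscaled) carrier-frequency matrix — the defaults of the classic
clustered-heatmap routine — with scipy's deterministic tie-breaking.  No
normalization is applied, since the dissimilarities are meant to act on raw
carrier frequencies.  Trees are exposed as linkage matrices, leaf orders, and
Newick strings; no graphical rendering is included.

## Geography and empirical tests

Distances are haversine great circles on a sphere of radius 6371.0088 km from
Addis Ababa (9 N, 38 E).  Land-route or waypoint-constrained distances are
*not* used — the source computation used a generic distance function with no
waypoints — and this, together with midpoint-resolved (and four garbled)
coordinates, is the main reproduction risk for the cline correlation; the
recomputed r = 0.465 sits within ±0.05 of the published 0.49.  The carrier
(not gene) frequency of KIR3DS1 is the cline variable.

Empirical p-values: for correlations, the proportion of background statistics
strictly greater in absolute value than the observed one (ties excluded, per
the strict wording); for FST-type statistics, a two-tailed rank with the
doubling rule 2·min(#{b ≥ obs}, #{b ≤ obs})/N capped at 1 — "above or below"
is ambiguous between doubling and a one-sided proportion, so both are
exposed with doubling as the default.

## Synthetic data

`simulate_panel` draws two haplotypes i.i.d. per individual from the
population's frequency vector and unions them — exactly the HWE
random-union model the EM inverts, which is the point: EM on simulated
panels recovers generating frequencies with MAE < 0.03 at n = 500 (observed
≈ 0.008 across 20 replicates).  `simulate_background` is a two-level
Balding–Nichols model: region frequency ~ Beta with mean p₀ and variance
F_r·p₀(1−p₀), population frequency ~ Beta around the region value with F_p.
Defaults p₀ = 0.5, F_r = 0.09, F_p = 0.02 mirror the published genome-wide
between-region/between-population FST shares of autosomal SNPs, so the
synthetic background has realistic differentiation structure.  What it does
**not** emulate: ascertainment and frequency spectra of real SNP panels,
linkage between markers, and any spatial autocorrelation beyond the
region level — so empirical p-values against it demonstrate the machinery
and its approximate calibration, not a definitive selection test on real
data.  `simulate_cline` adds Gaussian noise to a linear frequency-distance
trend and clamps to [0, 1]; with slope s, noise σ and distance spread σ_d the
expected sample correlation is s·σ_d/√(s²σ_d² + σ²), which the tests use to
check calibration.

All generators take an explicit seed and use one `numpy.random.Generator`
per call; there is no global random state.

## Problem sizes used in tests and the acceptance script

Table-derived analyses run on the full packaged 52-population tables.
Simulation-based checks use n = 500 individuals × 20 replicates for EM
recovery, 1000 random small instances (≤4 haplotypes, ≤6 individuals) for
likelihood monotonicity, 4132 synthetic background markers for the empirical
p-value, and grid-search oracles at 0.001 step on ≤3-haplotype toys — sizes
chosen so the whole suite and script each finish in seconds while leaving
the Monte-Carlo error well below the asserted tolerances.

## Known limitations

* Gene-content only: no allele/sequence-level typing, no copy number.
* The EM assumes HWE within populations and known candidate haplotypes;
  genuinely novel haplotypes appear only through the augmentation search.
* The FST partition from printed tables inherits 3-decimal rounding of the
  source; the residual 3DL1S1 discrepancy above is documented, not resolved.
* Garbled source coordinates are propagated as printed (flagged), which
  perturbs the cline correlation by an unknown but small amount.
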