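# Methods

This note documents the models and conventions behind `hexapop`, the
parameter choices that matter, and the limits of what the synthetic-data
tests demonstrate.

## Marker data model

A panel carries two marker datasets. **SNP** markers are codominant,
unordered allele pairs over {A, C, G, T}; internally each call is the ALT
dosage 0/1/2 against a designated REF allele (REF = the reference-genome
base when known, otherwise the major allele — a deterministic convention).
**PAV** markers are dominant presence/absence calls 0/1: a 1 covers both
the homozygous present/present and the heterozygous present/absent state,
so no heterozygote class is observable. Missing calls are `-1`. Coordinates
are 1-based inclusive everywhere internally; only BED export converts to
0-based half-open. Unanchored hits ("Un") are kept as a fourth stratum:
they enter genome-wide statistics but are excluded from subgenome
contrasts.

## Per-marker statistics

* call rate = non-missing / total calls;
* variant frequency p: allele-level for SNPs (a homozygote contributes two
  copies, a heterozygote one of each), presence-state frequency for PAVs;
  **MVF** = min(p, 1 − p). Allele-level counting was chosen over
  genotype-level because it is the standard population-genetics frequency
  and the two differ only in the weighting of heterozygotes;
* **PIC** (Botstein): `1 − (p² + q²) − 2p²q²`, maximum 0.375 for a
  biallelic locus;
* heterozygosity = heterozygous / non-missing calls (SNP only);
* transitions are A↔G and C↔T; everything else is a transversion.

Filtering applies three rules in a fixed order so audit counts are
deterministic: unique mapping (exactly one hit tying the maximum alignment
score), then MVF, then call rate (SNPs only). Thresholds are strict
inequalities (`> 0.1`, `> 0.6`). The audit log reports retention against
both the total and the mapped marker count, since selection rates can be
quoted against either denominator. Filtering is idempotent.

## Hemizygosity diagnostics

In an allohexaploid, a marker assay that cannot separate homoeologous
copies reports fixed A/B/D differences as heterozygotes. Three read-outs:
mean heterozygosity stratified by the number of subgenomes a marker's
sequence hits; a Pearson chi-square on best-hit subgenome × number of hit
positions (1 / 2 / >2); and a flag list = heterozygosity > 0.5 (default,
configurable) AND hits in ≥ 2 subgenomes. The 0.5 threshold sits far above
the residual heterozygosity of a selfing crop (< 0.1) and below the
near-1 heterozygosity a truly hemizygous marker shows, so the flag is
insensitive to its exact value.

## Linkage disequilibrium

LD is the squared partial correlation of two markers' numeric codes (SNP
dosage, PAV 0/1) given q principal-coordinate axes of the kinship matrix
(default q = 3, configurable; the value is not critical for the synthetic
panels and is exposed as a flag). Computation residualizes both markers on
[1, PCO₁..PCO_q] over pairwise-complete accessions (default minimum 30)
and squares the correlation of residuals; with q = 0 this is exactly the
squared Pearson correlation. Pairs with no residual variance are undefined
and excluded.

The **unlinked null** is the empirical 95th percentile of LD over seeded
uniform random cross-chromosome pairs (default 10,000). The
**decay distance** comes from a cubic penalized B-spline of r² on raw
physical distance with a second-difference penalty, with λ bisected so the
trace of the hat matrix equals 12 effective degrees of freedom (~20 knot
segments leave ample basis freedom). The spline is evaluated on a 1 kb
grid; the decay distance is the largest d\* with the spline above the null
at every grid point up to d\*; it is 0 when the spline starts at or below
the null and censored at the largest observed distance when it never
crosses. Within-chromosome pairs can be subsampled (seeded, stratified by
distance decile) to bound the table size without starving any distance
range.

**Marker blocks**: group-average (UPGMA) agglomeration on dissimilarity
1 − r² per chromosome, cut at height 1 − r²-threshold (default threshold
0.2 — a common block criterion, exposed as a flag; block counts are
cut-dependent and not comparable across thresholds). Undefined pairwise LD
becomes dissimilarity 1, which is conservative against false linkage.
Each block reports its bp span and a representative (highest call rate,
ties to the lowest marker id).

## Kinship, ordination, groups, scan

**Dice kinship**: each SNP contributes two binary bands (REF present, ALT
present; a heterozygote carries both, matching the present/present reading
of a dominant assay), each PAV one band;
`K(i,j) = 2·shared / (bandsᵢ + bandsⱼ)` over pairwise-complete markers.
Multiple datasets can be pooled at the band level. Pairs with no complete
markers are NaN and flagged.

**PCoA** double-centers the similarity matrix (Gower), eigendecomposes,
and scales eigenvectors by √λ; negative eigenvalues are reported and their
axes dropped; signs are fixed by forcing the largest-magnitude loading
positive.

**Stable groups**: the reference partition is complete-link clustering of
1 − K cut into G groups (G defaults to the silhouette maximizer over
2..12). Partitions at exactly g groups are obtained by applying the first
n − g merges in merge order, which is robust to tied merge heights. Each of
B bootstrap replicates (default 100) resamples *markers* with replacement
— group membership of accessions is the inference target, so the marker
set is the random quantity — recomputes kinship and the partition, and
accumulates pairwise co-clustering frequencies. A reference group is
stable iff its mean within-group co-clustering ≥ τ (default 0.7) and its
size ≥ 5; everything else is ungrouped.

**Year scan**: registration year is treated as a quantitative trait and
regressed per marker on the dosage code plus the first q PCO axes
(default 3), with a two-sided t-test on the marker coefficient and
Benjamini–Hochberg adjustment over tested markers. The structure
correction is deliberately a fixed-effects eigenanalysis regression rather
than a kinship-random-effect REML fit: it is deterministic,
dependency-light, and the eigenanalysis is the essential correction; a
full mixed model is a noted extension point. Markers below an MVF floor
(default 0.05) or with < 10 informative accessions are skipped and
excluded from the adjustment. Distribution comparisons between kinship
samples use Mann–Whitney on raw coefficients (scipy's auto mode: exact for
small samples, tie-corrected normal approximation otherwise) or chi-square
on 10 equal-width bins over [0, 1] with adjacent bins merged until every
expected count reaches 5.

## Core collection

Complete-link partitions for g = 1..n; for each partition the **average
within-group kinship** is the unweighted mean over groups of the mean
off-diagonal within-group kinship, with singletons contributing 0. The
unweighted-by-group form was chosen over pair-weighting because the
singleton penalty then creates the interior maximum that defines the
optimal g\* (ties break toward smaller g). Representatives: per cluster
the member with the highest mean yield (ties to the lexicographically
smallest id), or a seeded uniform random member when the cluster has no
yield data; clusters are processed in ascending id order so the random
fallback reproduces exactly. The core-vs-whole comparison bins off-diagonal
kinship (whole panel vs within-core) and applies Pearson chi-square.

## Synthetic panels

The generator reproduces the statistical fingerprints of a hexaploid GBS
panel, not its sequences:

* subpopulation allele frequencies are Balding–Nichols draws,
  `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with F = Fst and ancestral
  p ~ U(0.1, 0.9);
* haplotypes carry a latent uniform along each chromosome, resampled
  between adjacent markers with probability `1 − exp(−d / L)`
  (L = `ld_decay_bp`), so two markers at distance d share the latent with
  probability `exp(−d/L)` — giving monotone distance-decaying LD with
  `r² ≈ c·exp(−2d/L)`;
* selfing is modeled by an inbreeding parameter (default 0.9): with that
  probability an accession's second haplotype copies the first per
  chromosome, keeping marker heterozygosity mostly below 0.1, as expected
  for a self-pollinating crop;
* hemizygosity is phenomenological: a fraction of subgenome-D SNP markers
  (matching where the marker deficit and heterozygosity excess concentrate
  in such panels) is overwritten as heterozygous with probability
  `het_call_prob`, regardless of genotype — this reproduces the observable
  (inflated heterozygosity + multi-subgenome hits) without simulating
  homoeologous sequence collapse;
* PAV markers are dominant recodings of simulated SNP markers (present =
  ≥ 1 copy of the tracked variant);
* the hit table gives every marker a best hit at its true location, adds
  lower-scoring extra hits at rate `multi_hit_rate`, score ties at
  `tie_rate` (exercising the unique-mapping filter), and sends hemizygous
  markers an extra hit on a homoeologous chromosome with high probability;
* year = base + Σ effect·dosage + N(0, sd), rounded and clipped to a
  plausible registration window; yields share per-subpopulation offsets,
  and a fraction of accessions lacks trial data.

All randomness flows from one integer seed through named
`SeedSequence` children (layout, frequencies, haplotypes, assignment,
hemizygosity, PAV, missingness, hits, phenotypes), so identical
configurations are bit-identical.

Default sizes (300 accessions, 3 subpopulations at Fst 0.1, three
chromosomes per subgenome with a D-marker deficit, 5 Mb LD scale, 3%
missing calls, 30% PAV fraction) describe a mid-sized breeding panel;
tests and the acceptance script state their own sizes per scenario (for
example 200 accessions × ~2,000 markers for null calibration — large
enough for stable percentiles while keeping the suites fast).

## What the synthetic tests do and do not show

The generator has independent chromosomes, exchangeable accessions within
subpopulations, marker-independent missingness, and hemizygosity confined
to one subgenome. Real panels add pedigree structure, ascertainment bias,
genotyping-error correlation, and hemizygosity in all subgenomes. Passing
tests therefore demonstrate that the *algorithms* recover planted
parameters under their stated assumptions — not that any particular real
panel satisfies those assumptions.

Known limitations worth stating explicitly:

* **Flat-block kinship has no interior g\***: if within-cluster kinship is
  constant plus noise, splitting a cluster never lowers the unweighted
  group-mean average until singletons appear, so the optimal-g\* criterion
  only pins the planted cluster count when the within/between contrast
  dominates the noise. The recovery tests use constant-block kinship
  (gap ≥ 0.4) accordingly; real panels show an interior maximum because
  within-group kinship is heterogeneous at every scale.
* **Kinship pairs are not independent**: pairs sharing an accession are
  positively correlated (each accession has its own allele-composition
  effect), so the Pearson chi-square comparing pair-level kinship
  distributions is anticonservative on genotype-derived kinship even for
  perfectly random cores. Its p-values are calibrated only when pair
  values are exchangeable and approximately independent; treat it as the
  descriptive check it is in practice, not an exact test.
* The year scan's fixed-effects correction controls structure captured by
  the leading PCO axes; confounding along discarded axes is uncorrected.
* The decay distance is an exceedance point of a smoothed curve, not a
  model parameter; its value moves with the null percentile, the spline
  df (12 by convention) and the distance range sampled, which is why the
  recovery test accepts a band around the planted scale rather than a
  point.

## Numerical choices

* Degenerate inputs are explicit: all-missing markers are flagged with
  call rate 0; undefined LD (constant marker after projection) is NaN and
  excluded; accession pairs with no shared complete markers are NaN with a
  warning; an empty post-filter marker set aborts the pipeline with a
  stage-named error.
* The P-spline solve adds a 1e-9 ridge for numerical safety; λ is bisected
  on log₁₀ λ ∈ [−8, 14] to |edf − target| ≤ 1e-4.
* Linkage uses scipy's `complete`/`average` methods on symmetrized, clipped
  dissimilarities; exact-g cuts apply merges in order (tie-safe).
* The pipeline report contains no timestamps and hashes every output file,
  so a rerun with the same config is byte-identical.
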