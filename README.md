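# hexapop

Population-genetics tooling for **allopolyploid genotyping-by-sequencing
(GBS) panels** — the kind of dataset produced when a few hundred wheat
(AABBDD) varieties and breeding lines are genotyped with a DArTseq-style
platform yielding codominant SNP calls and dominant silicoDArT
presence/absence (PAV) calls.

It is written for breeders and quantitative geneticists who need to go from
raw marker tables plus a marker-to-genome hit table to:

1. **Marker QC** — call rate, minor variant frequency (MVF), Botstein PIC
   (`PIC = 1 − p² − q² − 2p²q²`), heterozygosity, transition/transversion
   class; selection of uniquely mapped markers with `MVF > 0.1` (all
   markers) and `call rate > 0.6` (SNPs only).
2. **Subgenome diagnostics** — per-subgenome (A/B/D) marker density,
   diversity contrasts (Mann–Whitney), and *hemizygosity* detection: in an
   allopolyploid, fixed alternative alleles at homoeologous loci masquerade
   as heterozygotes, so markers whose sequence hits ≥ 2 subgenomes and show
   inflated heterozygosity are flagged as pseudo-heterozygous.
3. **Structure-corrected LD** — LD between markers i, j is the squared
   partial correlation `r²(xᵢ, xⱼ | PCO₁..PCO_q)` of dosage codes given
   principal-coordinate covariates; an empirical null (95th percentile of
   LD for random cross-chromosome pairs), a 12-effective-df smoothing
   spline of r² on physical distance, the **decay distance** where the
   spline drops to the null, and UPGMA marker blocks cut at `1 − r²`.
4. **Kinship and structure** — Dice band-sharing kinship
   (`K = 2·|shared bands| / (bandsᵢ + bandsⱼ)`, with each SNP expanded into
   two presence bands), PCoA via Gower centering, complete-link grouping
   with marker-bootstrap stability scores, and a registration-year
   association scan (`year ~ marker + PCO covariates`) with
   Benjamini–Hochberg correction.
5. **Core collection** — complete-link partitions for g = 1..n, the average
   within-group kinship with the singleton = 0 convention, the optimal
   cluster count g\* at its maximum, one highest-yield (or seeded random)
   representative per cluster, and a chi-square check that the core
   reproduces the panel-wide kinship distribution.
6. **Synthetic panels with planted truth** — a first-class generator
   (Balding–Nichols subpopulation frequencies, Markovian haplotype copying
   for distance-decaying LD, subgenome-D marker deficit, planted hemizygous
   markers, dominant PAV recoding, year/yield phenotypes with planted
   marker effects) so every stage is testable without any external data.

## Worked example

`examples/03_ld_decay.py` simulates a 200-accession panel with a planted
5 Mb LD scale and recovers it:

```
pairs used                : 6000
unlinked null q95         : 0.0237
decay distance            : 6.36 Mb (planted scale 5 Mb)
spline effective df       : 12.0
```

The decay distance is the span over which expected LD exceeds the unlinked
background — markers closer than this are partially redundant for
association scans. `examples/05_core_collection.py` builds a core
collection on a 150-accession, 5-subpopulation panel:

```
optimal cluster count g*  : 21 (14.0% of the panel)
avg within-group kinship  : 0.767
core vs whole chi-square p: 0.458
```

g\* = 21 clusters maximize the average within-group kinship; the chi-square
p of 0.458 says the 21 representatives reproduce the panel's kinship
distribution. The other examples cover simulation (`01`), marker QC and
hemizygosity diagnostics (`02`), and structure/association (`04`).

A thin CLI mirrors the library:

```bash
hexapop simulate --out panel/ --seed 7
hexapop qc --snp panel/markers_snp.csv --pav panel/markers_pav.csv \
           --hits panel/hits.tsv --out qc/
hexapop run-all --config examples/pipeline_config.json
```

## Layout

```
src/hexapop/      simulate, io, qc, ld, structure, core, pipeline, cli
examples/         one narrative script per capability + pipeline config
tests/            unit, property and acceptance suites (pytest)
docs/methods.md   models, parameter choices, numerical details, limitations
```
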