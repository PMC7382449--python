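# Methods

## Scope and model

`triovar` implements the tertiary-analysis stage of a trio WES study:
it starts from called, annotated genotypes and ends with a prioritized
variant list, relatedness matrices, CNV segments, and enrichment
statistics.  Primary/secondary analysis (alignment, variant calling)
and the in-silico predictors themselves (CADD, PredictSNP2, FATHMM-MKL)
are upstream inputs, not reimplemented.

### Trio classification

Each (variant, family) pair receives exactly one transmission label,
decided from the proband/mother/father genotype triple:

| proband | parents | label |
|---|---|---|
| carries ≥1 alt | both HOM_REF | DE_NOVO |
| HOM_ALT | both carry | AUTOSOMAL_RECESSIVE |
| HET | ≥1 carries, configuration Mendel-possible | AUTOSOMAL_DOMINANT |
| carries, on X non-PAR, transmitted | X_LINKED |
| HOM_REF, or Mendel-impossible | UNRESOLVED |

Mendel-impossible configurations (e.g. hom-alt proband with a
hom-ref parent) are labelled UNRESOLVED rather than dropped: whether
such a site is genotyping error, mosaicism or uniparental disomy is a
caller-level judgement the pipeline surfaces instead of making.  The
convention that a carrier child of two hom-ref parents is DE_NOVO is
applied uniformly, including the (biologically implausible) hom-alt
child — flagging it for review rather than hiding it.

On X non-PAR (PAR1/PAR2 at hg19 coordinates are excluded), males are
evaluated hemizygously; diploid-style HET/HOM labels from array or
Sanger screening tables normalize to HEMI_ALT on input and print back
in the table dialect on output, since screening reports use diploid
labels regardless of ploidy.  A de novo event on X is labelled DE_NOVO
(with a hemizygous detail flag for males) so de novo counts are
chromosome-uniform.

The classifier is verified against an independent gamete-enumeration
oracle over all 27 autosomal genotype configurations.

### Filter cascade

Four conjunctive predicates; order is immaterial.

* **Functional**: consequence ∈ {missense, in-frame indel, stop gain,
  frameshift, splice site}.
* **Brain expression**: ≥ `min_brain_votes` (default 3) positive of the
  four databases GTEx, BioGPS, CGAP, HBT; a missing entry is a
  non-positive vote.
* **Rarity**: every *reporting* panel MAF < `maf_threshold` (default
  0.01, strict `<`).  A panel that never observed the variant does not
  veto; printed zeros are stored as 0.0 (observed-absent), distinct
  from missing.  A strict mode makes an all-missing profile fail
  instead.
* **Deleteriousness consensus**: votes = [CADD phred ≥ `cadd_cutoff`]
  + [PredictSNP2 = deleterious] + [FATHMM-MKL ≥ `fathmm_cutoff`];
  pass iff votes ≥ `min_deleterious_votes` (default 2) or, with
  `lof_exempt` (default on), the consequence is truncating.

Defaults and their rationale:

* `cadd_cutoff = 20.0`: no single published threshold exists; 20 (top
  1% of CADD's genome-wide scale) is consistent with the packaged
  cohort — every retained missense variant scores above it, and the two
  splice variants that score below (15.00, 14.39) pass on the other two
  votes.  Configurable.
* `fathmm_cutoff = 0.5`: the tool's published decision boundary.
* `lof_exempt = True`: the three predictors are calibrated on
  missense-like substitutions; an unambiguous stop-gain can score low
  on two of them (one packaged example reaches only 1/3 votes under any
  sane cutoffs yet was Sanger-validated and retained).  The exemption
  encodes that inference explicitly and can be switched off.
* pLI and missense Z are annotations only — gene-level constraint is
  inadequate to infer or exclude pathogenicity on its own.

Cohort summary counts are over unique (chrom,pos,ref,alt) keys; the
per-family listing keeps duplicates.  The analyzed-family denominator
counts pedigrees whose trio data passed QC (15 of the 16 packaged
families).

### Segregation

`fully_segregates` is true iff every screened affected member shares
the proband's exact genotype and no screened unaffected member does;
undefined (None) when the proband is the only screened member.
Individuals with *suspected* status are excluded from both sides by
default and promoted to affected only by the `include_suspected` flag,
because the cohort tables mark one screened sibling as suspected
without stating whether that individual entered the published
segregation judgements.

### Relatedness

* **A_jk** (Yang et al. genomic relationship, the "unadjusted" variant
  as computed by `vcftools --relatedness`): off-diagonal
  A_jk = meanᵢ (x_ij − 2pᵢ)(x_ik − 2pᵢ) / (2pᵢ(1−pᵢ)); diagonal
  A_jj = 1 + meanᵢ (x_ij² − (1+2pᵢ)x_ij + 2pᵢ²) / (2pᵢ(1−pᵢ)).
  Allele frequencies default to cohort plug-in estimates (matching the
  unadjusted estimator's definition); external frequencies can be
  supplied.  Monomorphic sites are excluded; missing genotypes are
  handled by per-site pairwise deletion; a pair with zero joint sites
  is NaN.  With cohort-estimated frequencies on a cohort of related
  samples the estimator is slightly biased toward zero (order 1/N);
  calibration tests that target exact expectations therefore supply the
  true simulation frequencies, while the cohort-level test accepts
  0.45–0.55 for parent–offspring pairs.
* **Shared homozygosity**: restricted to sites with MAF > 1% (common
  variation carries the homozygosity signal; rare alt-homozygotes are
  mostly noise), S_jk = |H_j ∩ H_k| / N with H the alt-homozygous site
  set.  The normalizer N is configurable — min (default), mean, union —
  because the original method's exact normalization constant is not
  public; min is bounded in [0,1] and robust to unequal call rates.
  This choice is an interpretation, not asserted as the original
  authors'.

### CNV calling

Probe states by fixed thresholds: gain iff log2 > 0.58, loss iff
log2 < −1, both strict.  Segments are maximal runs of same-state
probes; any different-state probe (including neutral) breaks a run, as
does a genomic gap > `max_gap_bp` (default 100 kb, covering array
coverage holes) between consecutive probes.  Runs shorter than
`min_probes` (default 5) are discarded.  These two parameters are this
package's choices — the commercial segmentation engine behind the
original calls is proprietary and only the thresholds are public.

Coordinates are 1-based inclusive; segment size is end − start (not
+1), the convention forced by the printed size arithmetic of the source
tables (e.g. 51,197,838 − 51,073,379 = 124,459 bp printed as
124.459 kbp).  Only two states are modelled; zygosity ("het" loss) is
input annotation, never inferred from log2 alone, as the het/hom-loss
distinction is threshold-ambiguous.  Family comparison flags a proband
segment inherited when it reciprocally overlaps (≥50% both ways,
configurable) a same-state parental segment; matches in both parents
are reported as shared-unknown rather than resolved arbitrarily.

### Over-representation analysis

Exact hypergeometric upper tail P[X ≥ k] for a query of n genes
against an m-gene set in an N-gene universe, BH-FDR adjusted across
tested sets, stable-sorted by (p_adjusted, p_raw, set_name).  The
universe defaults to the union of the collection's genes (the
reference-set concept of the web tools this replaces); the original
study's universe is unstated, and its historical term lists depend on
2019 database snapshots, so no attempt is made to reproduce them —
correctness is instead established against combinatorial enumeration
on small universes.

## Synthetic cohort generator

`simulate_cohort` emulates the study conditions: by default 15
nuclear families (two parents, proband, one affected and one unaffected
sibling; proband sex ratio 3:1 male:female), 13 of which carry two
passing planted rare variants each under a mix of transmission modes,
plus one designed failure per cascade stage.  Background sites
(default 1,000; relatedness tests use 10,000) are drawn at
uniform(0.05, 0.5) allele frequencies in Hardy–Weinberg founders and
transmitted by gamete dropping, so Mendel holds everywhere except
planted de novo events.  Passing plants carry panel MAFs of 5×10⁻⁴,
CADD 28 / PredictSNP2 deleterious / FATHMM 0.9, and 4/4 brain votes;
each failure design flips exactly one stage (synonymous consequence,
1/4 brain votes, one panel at 2%, or all-predictor-benign).  Planted
CNVs add a fixed log2 shift (−1.5 loss, +1.0 gain) over the planted
interval on a 5 kb probe grid under Gaussian noise (σ = 0.2).
Optional knobs: founder inbreeding coefficient (default 0, reflecting
that the emulated population's consanguinity is a property to study,
not assume) and a per-call genotype error rate (default 0) that
exercises the UNRESOLVED path.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linkage disequilibrium, site-specific error
modes, batch effects, segmental duplications confounding array probes,
incomplete penetrance of planted variants (plants are fully penetrant
by design so recovery is exact), and annotation disagreement between
predictors.  Planted-truth recovery demonstrates the pipeline's logic,
not its robustness to messy inputs.

## Packaged fixtures

The cohort's printed tables are packaged as TSV: the affected-roster
(sex/age/role), the 15 CNV segment rows, and the 32 validated variants
with per-member screening genotypes.  Genomic positions in the variant
fixture are synthetic ordinal placeholders (the table prints HGVS
coding coordinates only); chromosomes are real, which the X-linked
logic requires.  Per-database brain-expression votes are a synthetic
reconstruction consistent with the published statements (all genes
brain-positive in ≥3/4 databases; one gene negative in HBT) and are
named accordingly.  One family's trio failed sequencing QC and is
loaded with `passed_qc=False`.

## Numerical and testing choices

* Genotype normalization is total: every table-dialect label and every
  diploid/haploid VCF GT string maps to exactly one call.
* A_jk calibration tolerances are 3 standard errors of the per-site
  contribution mean at 10,000 sites; planted-CNV recovery is defined as
  ≥50% of the planted interval covered by called same-state segments
  (robust to single-probe miscalls splitting a run), with boundary
  accuracy measured on the bounding box of called segments; at σ = 0.2
  the per-probe miscall probability is Φ(−2.5) ≈ 0.6%, giving a
  recovery rate well above the 95% requirement over 100 seeded tracks.
* Test problem sizes (10,000 sites for relatedness, 100 seeded CNV
  tracks, 100-site cohorts for end-to-end runs) were chosen so each
  property test finishes in seconds while keeping Monte-Carlo noise far
  from the tested tolerances.
* Degenerate inputs are errors, not silent defaults: empty query in
  ORA, all-monomorphic input to A_jk, NaN log2 ratios, cyclic
  pedigrees, unknown genotype labels.

## Known limitations

* No statistical phasing: compound-het phase comes only from parental
  transmission; pairs with ambiguous origin stay "unphased".
* No liftover; all coordinates are GRCh37/hg19.
* The CNV caller models exactly two states and cannot distinguish
  heterozygous from homozygous loss.
* Enrichment results depend entirely on the supplied GMT; the package
  ships only a toy collection for testing.
* The shared-homozygosity normalizer is an interpretation (see above);
  cross-study comparability of its values is limited.
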