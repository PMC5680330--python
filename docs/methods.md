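# Methods

`privar` implements a case-versus-panel variant prioritization analysis:
one affected, deeply sequenced individual is compared against a panel of
healthy genomes from related populations, and candidate disease variants
are isolated by a deterministic cascade of filters. This note documents
the models, the defaults and their rationale, the numerical choices, and
what the synthetic cohorts do and do not emulate.

## Quality filtering

A multi-sample VCF (e.g. a FreeBayes cohort callset) is filtered site by
site. A site survives only if it passes every rule:

- **Site quality** — QUAL > 30, strictly. A missing QUAL fails: a site
  whose quality is unknown cannot be shown to exceed the threshold.
- **Depth** — every *polymorphic* genotype (any called genotype carrying a
  non-reference allele) must have DP > 5, strictly. Hom-ref genotypes are
  not depth-checked; sites with no polymorphic genotype pass vacuously.
- **Completeness** — any missing genotype ("./.") in the cohort removes
  the site: a private allele cannot be certified when some panel sample is
  uncallable there.
- **Allele balance** — for each heterozygote, AB = reads supporting the
  higher allele index over reads supporting both carried alleles,
  recomputed from AD. The accepted band is inclusive, [0.2, 0.8]; one
  out-of-band heterozygote removes the whole site (per-genotype handling
  can be switched off via `site_level_ab`). A heterozygote lacking AD
  fails with its own label (`ab_missing`).
- **Hardy-Weinberg equilibrium** — a two-sided exact test on the pooled
  cohort, with multiallelic genotypes collapsed to ref vs any-alt.
  Conditioning on the observed allele counts, the p-value sums the
  probabilities of all heterozygote counts no more probable than the
  observed one:
  P(n_ab | n, n_a) = n! / (n_AA! n_ab! n_BB!) · 2^n_ab · n_a! n_b! / (2n)!.
  Sites with p < alpha are removed; alpha defaults to 1e-4, a conventional
  VCF-QC choice, and is configurable because "substantial" deviation is a
  judgement call. Note two caveats: the test is discrete and therefore
  conservative (the realized type-I rate is below alpha), and pooling
  samples from diverged populations builds in a Wahlund heterozygote
  deficit, so on a structured cohort the filter removes slightly more than
  alpha. Both behaviours are exercised by the tests. With fewer than ~14
  diploids no table can reach p < 1e-4 at all.
- **Mappability** — optional BED mask of mappable regions; sites outside
  it are removed.

Removed sites are tallied per label (a site may fail several rules).
Coordinates: VCF positions are 1-based, BED and all internal window
arithmetic half-open 0-based; conversions live in `variant_io` only.

## Private-variant cascade

Privacy is allele-level: an alternate allele carried by the case
(heterozygous or homozygous) whose count across all panel genotypes is
zero. Other alternate alleles at the same site are irrelevant. The
cascade then runs, per impact branch (HIGH, then MODERATE, from SnpEff
`ANN` worst impact — the reported gene is the gene of the worst-impact
entry, ties broken by first occurrence):

1. **Predictor consensus** — SIFT = D and PolyPhen2-HDIV = D and
   PolyPhen2-HVAR = D (the most severe categories of each tool).
   Multi-transcript dbNSFP values collapse to the worst call; an absent
   call is non-damaging, since a variant cannot qualify on missing
   evidence. An optional GERP RS > 4 stage exists but is off by default:
   the conservation score is reported with candidates rather than used to
   select them.
2. **Phenotype crossing** — surviving genes are looked up in a local
   OMIM-style TSV snapshot (gene, phenotype, MIM number, inheritance).
   Live database access is deliberately out of scope (reproducibility,
   licensing); a six-row LRP5 snapshot ships as the bundled default.
3. **Inheritance compatibility** — a heterozygous candidate is kept only
   for dominant phenotypes (AD, and X-linked dominant as a documented
   extension); a homozygous one for any Mendelian mode. Unrecognized
   inheritance strings normalize to `other` and are never compatible.
4. **Category filter** — phenotypes that are OMIM "nondiseases"
   (bracketed), "susceptibility to multifactorial disorders" (braced), or
   provisional gene-phenotype relationships (leading `?`) cannot carry a
   gene on their own; a gene survives only with at least one unflagged
   phenotype. Inheritance is applied before the category filter, matching
   the order of the original analysis.

A gene needs only one compatible phenotype to survive a stage (the
alternative — requiring all phenotypes compatible — would discard genes
with both recessive and dominant disease forms). Variants removed late in
the cascade are kept in the report with a removal-stage code rather than
silently dropped. Stage survivor counts are recorded at every arrow and
are non-increasing within each branch by construction.

## Coding-effect calculator

For single-base substitutions in an in-frame CDS: codon number =
ceil(cds_pos / 3), offset = ((cds_pos − 1) mod 3) + 1; both codons are
translated with the hard-coded standard nuclear code (no alternative
codes); HGVS strings are emitted as `c.<pos><ref>><alt>` and
`p.<RefAa><codon><AltAa>` (synonymous changes as `p.<RefAa><codon>=`).
The protein length reported for a CDS of L nucleotides is L/3 − 1, the
stop codon excluded. Splice and frameshift consequences are out of scope;
those arrive pre-computed in `ANN`.

## Heterozygosity scan and ROH calling

The per-sample heterozygosity track counts heterozygous genotypes in
1 Mbp windows advanced in 2 kbp steps (both configurable), anchored at
offset 0 per chromosome; terminal windows keep their true length, and
densities are per kbp of window span (a callable-length correction via
the mappability mask is available as an option).

ROH calling is two-stage. Maximal runs of windows with het/kbp strictly
below a threshold (default 0.1) locate candidates; each candidate is then
trimmed to the span of its zero-heterozygote windows, and segments
shorter than 1 Mbp are dropped. The refinement matters: a 1 Mbp window
overlapping an ROH end by d bp still looks "low" until the overlap shrinks
below threshold·window/background-density — about 100 kbp of boundary
smear at threshold 0.1 against a 1 het/kbp background. The zero-het core,
by contrast, is bounded by the nearest flanking heterozygous sites, so
the boundary error is the flanking het gap, quantized by the step. At a
background of ~2.5 het/kbp this recovers planted boundaries to within one
step (2 kbp) in far more than 95% of runs; at ~1 het/kbp, expect ±(1-3)
kbp errors. Because the original procedure was visual, the scanner also
exports a per-chromosome plot (y fixed to 0-3 het/kbp) alongside the
bedGraph track and BED segment calls. Model-based (HMM) ROH calling is a
non-goal.

## Ancestry PCA

Biallelic SNVs are coded as alt-allele dosages; sites with more than 10%
missing calls are dropped and remaining gaps mean-imputed. Columns are
mean-centered and by default scaled by sqrt(2p(1−p)) — the
PLINK/EIGENSTAT standardization — then decomposed by SVD; scores are
U·S, and variance fractions are eigenvalue shares over all nonzero
eigenvalues. Each component's sign is fixed so its loading vector sums
non-negative, making outputs deterministic. LD pruning is exposed as an
(off, stub) option only; the analysis this package reproduces did not
prune. The case is assigned to the panel population with the nearest
centroid (Euclidean, in the top-k score space, k = 3 by default); an
exact tie within 1e-9 raises an explicit ambiguity error rather than
picking arbitrarily.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not the
biology of any real genome. Defaults mirror the study design: 26 samples
— four chimpanzee-subspecies-like clusters of five at F = 0.1, a more
distant bonobo-like cluster of five at F = 0.3, plus a case drawn from
the central cluster — with 20,000 SNVs on two 10 Mbp chromosomes
(complete in seconds at desk scale; the real callset had 22.4 M variants
on full genomes). Per site, an ancestral frequency p ~ Uniform(0.05,
0.95); each population's frequency q ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
(Balding-Nichols — the simplest generator with a controllable FST knob,
and the Hudson estimator on its output recovers F); genotypes
binomial(2, q), so Hardy-Weinberg holds within populations. DP ~
Poisson(30), matching 30X coverage; heterozygote AD ~ Binomial(DP, 0.5);
QUAL ~ Uniform(40, 1500). Annotation strings follow the SnpEff/dbNSFP
field order with impact classes drawn at the rates of the real callset
(HIGH 7.7e-5, MODERATE 2.1e-3, LOW 3.7e-3, rest MODIFIER), so a real
annotated VCF is drop-in compatible. Everything is deterministic under
the spec seed (same spec + seed → byte-identical VCF).

Planting operations record a machine-readable truth: case-private coding
variants with chosen impact/predictor profiles (ANN built from a
synthetic single-exon gene model via the coding-effect calculator), ROH
segments (the sample's genotypes forced homozygous for an existing
allele), and sites failing exactly one named filter. The ROH test
fixtures use a denser site grid (~7 sites/kbp, base frequencies 0.3-0.7,
giving ~2.5 het/kbp) so that boundary recovery is limited by the caller,
not by the sparseness of informative sites.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: linkage disequilibrium (sites are independent),
mutation-rate and recombination heterogeneity, indels and complex
alleles (SNVs plus planted substitutions only), genotyping error
correlated with depth or mapping, reference bias, and real SnpEff/dbNSFP
behaviour (annotations are fabricated, not computed from sequence).
Recovery rates measured here are therefore upper bounds on real-data
performance, while the brute-force oracle equivalences (exact HWE
p-values, private-allele detection, window counts, PCA scores) are
scale-independent correctness checks.

## Problem sizes used in the shipped checks

Unit and property tests run on cohorts of 100-2,000 sites. The
acceptance-style checks use: 100 generator seeds of the default
20,000-site cohort for cascade recovery; 100 seeds of a 3 Mbp / 22,000
site chromosome with a planted 1.5 Mbp ROH; 50 seeds of a 4-cluster,
5,000-site panel at FST 0.1 for assignment accuracy; 20,000 sites for
HWE type-I calibration; 1,000 sites for FST calibration. These sizes were
chosen as the smallest at which the binomial error bars are comfortably
inside the asserted bounds.

## Known limitations

- Pooled-cohort HWE filtering on structured panels is anticonservative
  (Wahlund effect); per-population stratification is a possible extension.
- The cascade assumes one causal gene per analysis and has no
  compound-heterozygote or trio logic (no parental genomes).
- The PCA is a direct eigendecomposition; for cohorts of thousands of
  samples a randomized or iterative solver would be preferable.
- FILTER labels are written only for sites the battery removes; the
  shipped pipeline writes survivors as PASS.
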