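# Methods

`hybridload` implements a complete exome-style analysis of mutation load in
a two-species hybrid complex: from diploid SNP genotypes and reference
coding sequences to predicted-deleterious amino-acid variants, per-individual
load and homozygosity profiles along an ancestry gradient, and
synonymous/nonsynonymous nucleotide diversity. Because no suitable dataset
can be redistributed with the package, a first-class synthetic-data
generator defines the study conditions under which every stage is tested.

## The analysis pipeline

**Quality control.** Genotypes with GQ <= 20 or depth <= 5 are set missing
(strict comparisons). Sites are retained only when QUAL >= 20, mapping
quality >= 40, FisherStrand <= 40, HaplotypeScore <= 13, MQRankSum >= -12.5,
ReadPosRankSum > -8, the mean heterozygote allele-balance ratio
(max(AD)/min(AD)) <= 2.3, at least 10% of individuals are genotyped, and
observed heterozygosity <= 0.7. Rank-sum annotations are emitted by callers
only when computable, so a missing annotation counts as passing; sites
without heterozygotes skip the balance test. Filtering is idempotent and
monotone in each threshold.

Individuals are dropped when their callrate falls below the 1st percentile
of the callrate distribution (computed after site filtering; the ordering
is configurable), when their method-of-moments inbreeding coefficient
F = 1 - obs(het)/sum(2p(1-p)) exceeds 0.35 (just below the outlier range a
screen of this kind typically flags), or when third-species ancestry
exceeds 0.12 — the expectation for a double backcross. F is estimated on
synonymous sites *excluding* the ancestry-diagnostic panel: near-fixed
species differences would otherwise inflate F for pure-species individuals
through the Wahlund effect, conflating population structure with
inbreeding.

**Ancestry.** Instead of unsupervised clustering, ancestry q (proportion
from species E) is the fraction of an individual's non-missing alleles at a
diagnostic panel that are E-associated. Panel selection from reference
parental groups applies minor-allele frequency > 0.01, missingness < 30%, a
minimum between-species frequency difference (default 0.8), and keeps at
most one site per gene as a stand-in for linkage pruning. With 500 fully
diagnostic sites the estimator's RMSE is below 0.03.

**Codon genotypes and variant calling.** Individual codon genotypes are
rebuilt from the reference CDS (monomorphic offsets) and SNP calls
(polymorphic offsets). A codon with any missing constituent genotype is
missing — "alleles genotyped" means two per fully genotyped individual.
Unphased data cannot resolve codons with two or more heterozygous SNPs; the
"ref-together" convention (reference alleles on one haplotype) is applied
and flagged. Such codons are vanishingly rare at realistic SNP densities.
Translated positions are filtered: fewer than `min_alleles` alleles
genotyped (`removed_low_call`), any observed stop allele (`removed_stop`),
or a tie for the most frequent allele (`removed_tie`). Every non-major
amino acid at a retained position becomes its own variant, so multi-allelic
positions yield more variants than positions. Codon-polymorphic positions
encoding a single amino acid are recorded as synonymous variants with
codon-level major/minor polarization. To avoid reference bias the reference
residue is replaced by the sample major allele at every retained position
before scoring.

The 500-allele filter presumes several hundred diploids. At simulation
scale the pipeline defaults to the same *fraction* of the maximum —
ceil(0.464 x 2N) alleles, i.e. 500 of 2x539 — so the filter removes the
same tail of poorly genotyped positions; an absolute `min_alleles`
can be passed instead.

**Delta scoring.** A minor allele's score against one homolog is
score(protein-with-minor, homolog) - score(protein-with-major, homolog)
under local (Smith-Waterman) alignment with BLOSUM62 and affine gaps, a gap
of length L costing 10 + L. The variant's score is the mean over the
homolog family (optional greedy clustering at 75% global identity averages
within clusters first; off by default). A variant is classified deleterious
when its score is strictly below -2.282, the threshold that maximizes
balanced accuracy on human disease-variant benchmarks; a score *above*
+2.282 flags the major allele itself as the unusual one. A score exactly at
the threshold is non-deleterious ("below" read strictly); with an integer
matrix and a family of n homologs, scores are multiples of 1/n, so ties at
-2.282 cannot occur. The alignment primitive is Biopython's
`PairwiseAligner`; the test suite verifies it exactly against an exhaustive
enumeration of local alignments for sequences up to length 12. Gap
penalties, the matrix, and local alignment itself are documented
assumptions (configurable), chosen to match common protein-search
defaults.

**Load metrics.** "Polymorphic loci" means retained amino-acid-polymorphic
positions. Per individual, denominators use only the positions genotyped in
that individual: prop_minor_X = (het + 2 hom)/(2 n_positions), prop_het_X
and prop_hom_X are per-locus proportions, and the ratio metrics are
undefined (NaN, excluded from regressions) when their denominator is zero.
An individual carrying two different minor alleles at one position counts
in each allele's tally. Allele-proportion metrics are regressed linearly on
q; homozygosity metrics quadratically (q + q^2), since homozygosity of
species-private alleles is intrinsically convex in q. Binned species
groups — pure E (q >= 0.9), pure W (q <= 0.1), intermediate (0.4-0.6) — are
compared by one-way ANOVA with Tukey HSD contrasts. The uneven-sampling
check counts major alleles more frequent in the W group than the E group
whose two group frequencies sum to less than one (alleles that would have
been minor under even sampling). Lethal equivalents follow 2B = -4 ln R
from the selfed/outcross survival ratio R. The fitness-proxy analysis fits
biomass ~ q + q^2, then the residuals on prop_minor_del and prop_hom_del,
and compares biomass of inbred-flagged individuals to the rest (Welch
t-test).

**Diversity.** Synonymous/nonsynonymous site counts per codon follow
equal-pathway (Nei-Gojobori-style) counting: per position, the fraction of
single-nucleotide changes preserving the amino acid, with changes to stop
codons excluded from numerator and denominator; differences between codons
average each step's classification over all stop-free mutational pathways
(all pathways, in the degenerate case where every pathway crosses a stop).
Per-individual pseudo-haplotypes use the same ref-together convention;
pi_s/pi_n for a region are the mean over unordered haplotype pairs of
differences/sites, using only codons complete in both members, with site
counts averaged over the compared pair. No multiple-hit (Jukes-Cantor)
correction is applied: these are within-species polymorphisms far from
saturation (configurable in principle; deliberately omitted). Regions enter
the comparison only if variable and having more than 100 bp of complete
data in at least 20 individuals of *every* group. Groups are compared with
Kruskal-Wallis and, when significant, Nemenyi all-pairs rank tests on the
studentized range (no tie correction; pi values are effectively continuous).

## The synthetic-data generator

The generator emulates the data properties the analysis depends on, not
any particular genome:

- **Two species with unequal diversity.** Minor-allele frequencies are
  drawn from a truncated exponential on (0, 0.5]; species E has a smaller
  scale (0.06 vs 0.08 — more rare alleles) but a higher segregating
  probability (0.90 vs 0.60), so E carries more variants and higher pi.
- **Hybrids.** Individuals sit on an ancestry grid (default 0, 0.5, 1 with
  60 individuals each); genotypes are drawn per site under Hardy-Weinberg
  at q p_E + (1-q) p_W. No linkage is simulated — no linkage-based
  statistic is computed.
- **Deleterious variants** (default 25% of nonsynonymous) are placed at
  conserved protein positions with probability 0.9, have frequencies
  downweighted by 0.25, and are species-private with probability 0.85
  (weighted 0.6 toward E, encoding E's greater load). A 0.3 minority has
  drifted to a moderate frequency U(0.05, 0.20) within its species — drift
  against weak selection in small local populations; without this class,
  homozygous-deleterious genotypes would be so rare at 180 individuals
  that group contrasts would measure Poisson noise.
- **Conservation-frequency coupling.** Neutral nonsynonymous variants
  avoid conserved codons with probability 0.95, and the few that land
  there have frequencies scaled by 0.4. Both reflect the premise that
  position conservation marks purifying selection; they keep the scorer's
  false positives rare, as observed in real data.
- **Homolog families** (15 per gene) are identical to the reference at
  conserved positions (fraction 0.4) and substituted with probability 0.85
  elsewhere, giving the delta scorer true signal to find.
- **Ancestry panel.** Five synonymous diagnostic sites per gene at
  frequencies 0.99/0.01.
- **Phenotype.** biomass = 10 + 2q - 2q^2 - sum_v s_v (h het + hom)
  - 2.5 F + N(0, 1), with s ~ Exponential(0.03) and h = 0.1 (partial
  recessivity). At these defaults ancestry explains a few percent of
  variance and the exome load penalty is essentially undetectable —
  deliberately so. The 2.5 F term represents genome-wide load outside the
  assayed exome; it gives the handful of selfed individuals (default 4,
  F = 0.5) a real biomass deficit.
- **Annotations** are drawn from passing ranges; missingness (8%) is
  applied uniformly per genotype. Stop codons are never introduced.

Default problem size — 80 genes x 60 codons, 30 SNPs + 5 diagnostic sites
per gene, 180 individuals — was chosen so that a full pipeline run takes
seconds and 20-seed recovery studies stay cheap, while the nonsynonymous
variant count stays above 1000.

What the generator does *not* emulate, and hence what passing tests do not
show about real data: linkage and ancestry tracts, sequencing error,
allele-specific bias in read depth, indels and splice isoforms,
gene-length and expression-level heterogeneity, site-specific substitution
processes in homologs (divergence is i.i.d. per position), and any form of
spatial or environmental structure. Recovery results demonstrate internal
consistency of the method under the stated generative model, not its
accuracy on real exome data.

## Numerical and design choices

- Coordinates: VCF positions are 1-based within each gene's CDS; codon
  indices 0-based internally; protein positions 1-based everywhere.
  CDS are supplied in coding orientation (no reverse-complement logic).
- The callrate percentile cut is computed after site filtering.
- Codons require all constituent SNPs genotyped (no reference imputation).
- Allele-balance ratio is symmetric (max/min of the two allele depths),
  averaged over heterozygotes; a heterozygote with a zero depth counts as
  infinitely unbalanced.
- Degenerate inputs: individuals with no usable sites get NaN F / q and
  are flagged rather than erroring; regions where no haplotype pair shares
  a complete codon raise; empty variant classes skip their contrast with
  a notice.
- Determinism: one `numpy` Generator seeded from the config drives the
  whole simulation; identical config and seed reproduce byte-identical
  output tables (hashed in tests).
- Oracle tolerances: alignment scores exact; pi against the naive oracle
  at 1e-12; statistical recovery properties asserted at >= 18/20 seeds.

## Known limitations

- The delta scorer does not reproduce any external program's numeric
  scores; only the construction (delta of local alignment scores, averaged
  over homologs) and the decision threshold are shared.
- Supervised ancestry estimation requires a diagnostic panel; there is no
  unsupervised fallback.
- The uneven-sampling check and group frequencies use the binned groups
  only; unbinned individuals contribute nothing to those contrasts.
- `pairwise_differences` enumerates k! pathways, which is exact but only
  sensible for codons (k <= 3).
- With fewer than ~300 diploids the paper-scale 500-allele filter removes
  everything; use the fractional default or set `min_alleles` explicitly.
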