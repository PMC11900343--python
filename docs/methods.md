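# Methods

`popsweep` re-implements, as a tested library, the analysis chain used in
two-breed cattle resequencing studies that contrast high- and low-milk-yield
animals: genotype quality control, genetic-diversity statistics, population
structure, and a windowed Fst / θπ-ratio selective-sweep scan with candidate
gene annotation and over-representation testing.  Because such studies'
resequencing data are typically not deposited, the package carries a
first-class synthetic-data generator that reproduces the statistical
structure the analysis assumes; every statistical claim the test suite makes
is made on that generator's output and is qualified accordingly below.

## Genotype model and quality control

All statistics operate on a samples × sites matrix of alternate-allele
dosages {0, 1, 2, missing}.  Phasing is ignored throughout: LD, IBS and
kinship are genotype-based, which is standard for unphased resequencing
panels and avoids imputation or phasing machinery.  Half-missing diploid
genotypes (`./1`) are treated as fully missing — the simplest dosage model
consistent with "dosage = count of alternate alleles".

The site screen applies, in a fixed order: per-genotype GQ masking
(GQ < 10 → missing), biallelic-only, QUAL ≥ 30, site missingness ≤ 5%,
MAF ≥ 0.05, and a Hardy–Weinberg exact test at p > 1e-6; samples with more
than 10% missing calls (strict inequality) are then removed.  The order
matters for the per-criterion removal counts, so it is fixed, documented,
and reported in the `FilterReport`.  GQ is applied as per-genotype masking
rather than a site-level summary; masking happens before missingness and
frequency are computed so a low-quality site fails the screen through its
induced missingness.  The HWE test is the exact conditional test (sum over
same-parity heterozygote counts of all configurations no more probable than
the observed one), the convention of standard QC tooling; a chi-square
variant is available.

## Synthetic panels

Allele frequencies follow the Balding–Nichols model: ancestral frequencies
p ~ Uniform(0.1, 0.9) (the lower bound keeps the MAF filter from destroying
most sites), then population frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F).
The hierarchy is ancestral → breed → within-breed yield group, with defaults
F = 0.10 between breeds (moderate divergence between related cattle breeds)
and F = 0.02 between a breed's high-yield (HY) and low-yield (LY) halves
(weak, mostly drift-level differentiation).  Defaults: 40 diploids per
breed × group (≈80 per breed), 20,000 SNPs on two 5-Mb contigs, 2% missing
calls, QUAL/GQ drawn to pass the default screen.  Genotypes are binomial
draws from the group frequency, so baseline sites are unlinked; an optional
block-copy mode shares one draw across all sites of a physical block,
giving r² = 1 within blocks for LD-decay testing.

Sweeps are injected by pushing the target group's frequencies to at least
`sweep_fixation` (default 0.95) toward the major allele inside chosen
intervals, which lowers that group's heterozygosity (hence π) and raises
group-pair Fst — precisely the signal the scan looks for.  Milk-yield
phenotypes are Normal(group mean, sd) with defaults 7,500/5,500 ± 500 kg, a
4-sd separation under which the quartile grouping recovers the true groups
almost noiselessly; tests that need a harder grouping problem shrink the
gap explicitly.

What the generator does **not** emulate: linkage disequilibrium from real
recombination (block-copy LD is rectangular, not decaying), mutation-rate
heterogeneity, genotyping error correlated with depth, relatedness within
breeds, and ascertainment bias.  Passing tests therefore demonstrate the
estimators' correctness and the scan's sensitivity under idealized
Balding–Nichols conditions, not performance on real herds.

## Diversity statistics

Per site with alt frequency p (q = 1 − p): He = 2pq, Ho = observed
heterozygote fraction, MAF = min(p, q), PIC = 1 − (p² + q²) − 2p²q²
(Botstein's biallelic form, always ≤ He).  Both PIC and He are reported
separately; reports that print PIC equal to He have likely conflated the
two, and the package does not replicate that.  Summary means are unweighted
over sites with at least one call.

LD is the squared Pearson correlation of dosage vectors over jointly called
samples, binned by physical separation (default 1-kb bins to 500 kb).  For
unlinked sites E[r²] ≈ 1/(n−1); the decay-curve tests use that null.  The
"r² at distance d" summary is the mean of the bin containing d.

## Population structure

* **IBS distance**: 1 − mean per-site allele-sharing (1, 0.5, 0 for
  identical, one-shared, opposite-homozygote genotype pairs).
* **Kinship**: VanRaden method 1, G = ZZᵀ / (2Σp(1−p)) with 2p-centering
  and mean-imputation of missing dosages (zero after centering).
* **PCA**: Patterson standardization ((g − 2p)/√(2p(1−p))), eigendecomposition
  of the sample covariance; variance explained is relative to the positive
  eigenvalue sum.  Patterson scaling was chosen over raw covariance because
  it is the population-genetics convention; the two give different
  variance-explained percentages.
* **Neighbor joining**: Saitou–Nei with the Q-criterion, first-minimum
  (lowest-index) tie-breaking, negative branch estimates clamped to zero,
  and the final pair's distance split evenly.  On additive matrices the
  construction is exact, which the tests verify to 1e-10 against random
  trees and against scikit-bio's implementation.
* **Admixture**: the standard binomial mixture g_ij ~ Binomial(2, Σ_k q_ik
  f_kj) fitted by EM from Dirichlet/Uniform initialization, F clipped to
  [1e-6, 1−1e-6], convergence at Δloglik < 1e-6 or 2,000 iterations.  EM
  was chosen over the original software's quasi-Newton block relaxation for
  simplicity; it is slower per digit of precision but ancestry fractions
  are accurate to ~0.01 long before full likelihood convergence, so
  model-selection runs cap iterations (300) and relax the tolerance
  (1e-4) — these fits only need the K ranking, not converged parameters.
  Cross-validation masks a random 10% of observed genotype entries (the
  same mask for every K, making the comparison paired), refits, and scores
  the mean held-out binomial deviance between g and 2ĥ; the original
  software's exact CV formula is not published, so held-out deviance — the
  natural loss for a binomial model — stands in.

## The sweep scan

Phenotyped samples are ranked (descending, ties by sample id) and the top
and bottom ⌈n/4⌉ form the HY and LY groups.  Windows of 50 kb step every
20 kb; trailing windows that would exceed the contig are dropped rather
than truncated, so every window has the same span.

Per window the scan computes:

* **Fst** — Weir & Cockerham (1984) variance components a, b, c per site
  from the two groups' sample sizes, allele frequencies and observed
  heterozygosities, combined as Σa / Σ(a+b+c) over the window
  (ratio-of-sums, the "weighted" convention of the standard windowed
  tools).  Sites need ≥2 called diploids in both groups; negative window
  estimates are retained, not clamped.
* **π per group** — per site 2·c_ref·c_alt/(n(n−1)) over the group's
  called alleles, summed and divided by the window span in bp (per-bp π,
  again the windowed-tool convention; dividing by span rather than SNP
  count changes magnitudes but not ranks at fixed window size).
* **Z(Fst)** — (Fst − mean)/sd over defined windows, population
  (denominator-n) standard deviation.
* **log2(π_HY/π_LY)** — undefined (and excluded from ranking) when either
  π is zero.

Candidates must exceed the empirical 95th percentile of Z(Fst) *and* fall
in a 5% tail of the log2 ratio (linear-interpolation quantiles; selection
by ≥/≤ against the threshold).  Thresholds are always computed from the
data, never hardcoded.  Selected windows merge into maximal regions
(overlap or book-end); a gene is a candidate if it overlaps a merged
region by ≥1 bp under half-open interval arithmetic.  The two tails are
labelled neutrally `high_ratio`/`low_ratio`; an orientation switch maps
them to HY/LY.  The default `reduced-diversity` orientation assigns the
low-ratio tail (diversity loss in HY) to HY-selected loci, the standard
sweep logic; the alternative `paper-figure` orientation inverts the
labels, since published figure legends sometimes map the top ratio tail to
the HY group.  Neither labelling changes the selected windows, only their
names.

SNPs can also be classified against gene models with precedence
exonic > UTR5/UTR3 > splicing (≤2 bp from an exon boundary inside a gene) >
intronic > upstream/downstream (≤1 kb of the gene span, strand-aware) >
intergenic.  Codon-level synonymous/nonsynonymous calls are out of scope
(they need the reference sequence and codon phase).

Coordinates are 0-based half-open internally and in BED output; tabular
reports add 1-based inclusive columns.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) per term,
with an explicit, user-supplied universe (all genes in the provided GFF3 by
default) — proprietary enrichment backgrounds are not reproducible, so the
universe is never implicit.  Benjamini–Hochberg adjusted p-values are
always computed; the default significance rule is raw p < 0.05, matching
common practice in the studies this pipeline mirrors, with the adjusted
option available.

## Numerical and scale choices

* HWE exact probabilities are computed in log space (lgamma) and
  normalized; the two-sided sum uses a 1 + 1e-12 relative guard against
  ties, and agreement with exact rational enumeration is verified to 1e-12
  for all genotype totals ≤ 20.
* Window statistics use per-contig cumulative sums, so a site shared by
  overlapping windows is counted in each.
* Degenerate inputs fail loudly: all-monomorphic panels (GRM), constant
  window Fst (Z-score), pairs with no shared called sites (IBS), empty
  groups, <20 ranked windows (quantile selection).
* Problem sizes in the acceptance runs — 20k SNPs on 5–10 Mb contigs,
  40–50 diploids per group, 3–5 seeds per stochastic claim, LD measured on
  a 6k-site subsample, 400 null-calibration replicates — were chosen as
  the smallest panels at which the binomial/Balding–Nichols sampling error
  is clearly inside each test's tolerance band.
* All randomness flows from explicit integer seeds; the simulator is
  byte-deterministic (identical VCF output for identical configuration),
  and pipeline runs record a config-hash manifest so equal manifests imply
  equal outputs.

## Known limitations

Single-threaded, in-memory design: panels are limited to what fits as an
int8 matrix (~10⁷ genotypes comfortably), far below the 10⁶–10⁷-SNP scale
of real resequencing studies; the estimators are scale-free, only runtime
grows.  The admixture EM can be slow to fully converge for weak structure.
LD decay on dense panels is quadratic in local site density.  The GFF3
reader expects a gene→mRNA→exon/UTR hierarchy and does not handle trans-
splicing or multi-parent features.
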