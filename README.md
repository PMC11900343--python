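# popsweep

Selection-signature scanning for two-population resequencing panels:
genotype QC, genetic-diversity statistics, population structure, and a
sliding-window **Fst / θπ-ratio** selective-sweep scan with candidate-gene
annotation and over-representation analysis.

The package targets the analysis design used in livestock resequencing
studies that compare two breeds and, within each breed, high- versus
low-phenotype animals (e.g. milk yield): after calling and filtering SNPs,
windows showing both elevated between-group differentiation and a loss of
nucleotide diversity in one group mark putative selective sweeps, and the
genes they overlap become trait candidates.  Since the raw data behind such
studies are usually not deposited, `popsweep` ships a Balding–Nichols
simulator that generates two-breed panels with injected sweeps, so the whole
chain is testable end to end.

## The statistics at the core

For each 50-kb window (step 20 kb) over the genome, contrasting the
high-yield (HY) and low-yield (LY) phenotype quartiles:

* **Weir–Cockerham Fst** — per-site variance components *a*, *b*, *c*
  combined as a ratio of sums, Fst = Σa / Σ(a+b+c);
* **Z(Fst)** = (Fst − mean) / sd over all windows;
* **θπ** per group — mean pairwise difference per site,
  2·c_ref·c_alt/(n(n−1)), summed over the window and divided by the span;
* **log₂(θπ ratio)** = log₂(π_HY / π_LY).

Candidate windows exceed the empirical 95th percentile of Z(Fst) **and**
fall in the top or bottom 5% of the log₂ ratio; overlapping candidates are
merged and annotated with the gene models they intersect.  Supporting
analyses: exact Hardy–Weinberg QC, He/Ho/MAF/PIC summaries, LD decay (r²),
IBS distances, VanRaden kinship, Patterson-scaled PCA, neighbor-joining
trees, and a binomial admixture model with EM fitting and cross-validated
choice of K.

## Worked example

Simulate a one-contig, two-breed panel with a 200-kb sweep injected into
breed A's high-yield group, then scan breed A:

```sh
popsweep simulate --outdir demo --n-sites 8000 --n-per-group 20 \
    --n-contigs 1 --contig-length 4000000 \
    --sweep chr1:1500000-1700000:A:HY --seed 42
popsweep scan --vcf demo/panel.vcf --samples demo/samples.tsv \
    --gff demo/genes.gff3 --outdir demo_out --population A --seed 42
```

prints

```
thresholds	{'z_fst_upper': 1.1132564619207475, 'log2_ratio_upper': 0.08263847984792373, 'log2_ratio_lower': -0.5776650739381893}
candidate_genes_HY	5
candidate_genes_LY	0
```

The thresholds are the empirical tail cut-offs computed from this run's
window statistics.  Five genes are HY candidates under the default
reduced-diversity orientation (windows with high Z(Fst) and *low* π ratio,
i.e. diversity lost in the HY group); they are exactly the genes tiled
across the injected 1.5–1.7 Mb sweep (`demo_out/genes_low_ratio_A.tsv`,
`gene_chr1_0030` … `gene_chr1_0034`).  The per-window table
(`demo_out/windows_A.tsv`) shows the signal directly — e.g. the window at
1,500,001–1,550,000 bp has Fst 0.28, Z(Fst) 4.7 and log₂ ratio −2.3,
against a genome background near zero.

The same stages are available programmatically
(`popsweep.pipeline.run_all`, or the individual modules `genotypes`,
`simulate`, `diversity`, `structure`, `sweep`, `enrich`) and as the
subcommands `simulate`, `qc`, `diversity`, `structure`, `scan`, `enrich`,
`all`.

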