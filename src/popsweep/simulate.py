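"""Synthetic two-breed genotype panels with injected selective sweeps.

Allele frequencies follow the Balding–Nichols model: for an ancestral
frequency p and a divergence parameter F (the target Fst), each descendant
population's frequency is drawn from Beta(p(1−F)/F, (1−p)(1−F)/F).  The
hierarchy is ancestral → breed (F = ``fst_between_breeds``) → within-breed
yield group (F = ``fst_between_groups``), giving two breeds each split into
high-yield (HY) and low-yield (LY) subgroups.  Genotypes are then binomial
draws from the group frequency, so baseline sites are unlinked; an optional
block-copy mode shares one draw across all sites of a physical block to
create perfect within-block LD for decay testing.

Sweeps are injected by pushing a target group's frequencies toward fixation
of the major allele inside chosen intervals, which depresses that group's
nucleotide diversity and raises group-pair differentiation — the signal the
scan module is designed to recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    GenotypeMatrix,
    SampleInfo,
    SiteInfo,
    write_sample_table,
    write_vcf,
)

BREEDS = ("A", "B")
GROUPS = ("HY", "LY")


@dataclass
class SweepRegion:
    """Half-open interval [start, end) on ``contig`` swept in one group."""

    contig: str
    start: int
    end: int
    target_breed: str = "A"
    target_group: str = "HY"

    @property
    def target(self) -> str:
        return f"{self.target_breed}_{self.target_group}"


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults emulate the design the pipeline targets: two breeds of ~80
    diploids each (40 per yield group), moderate between-breed divergence
    (F = 0.10), weak within-breed HY/LY differentiation (F = 0.02), a 2%
    missing-call rate, and milk-yield phenotypes separated by four standard
    deviations so the quartile grouping is nearly noiseless.
    """

    n_per_group: int = 40
    n_contigs: int = 2
    contig_length: int = 5_000_000
    n_sites: int = 20_000
    fst_between_breeds: float = 0.10
    fst_between_groups: float = 0.02
    sweep_regions: list[SweepRegion] = field(default_factory=list)
    sweep_fixation: float = 0.95
    missing_rate: float = 0.02
    phenotype_means: tuple[float, float] = (7500.0, 5500.0)  # (HY, LY) kg
    phenotype_sd: float = 500.0
    qc_fail_fraction: float = 0.0
    ld_block_size: int = 0  # bp; 0 disables block-copy LD
    gene_length: int = 20_000
    gene_spacing: int = 50_000
    seed: int = 1234

    def __post_init__(self) -> None:
        for name in ("fst_between_breeds", "fst_between_groups", "missing_rate",
                     "qc_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.5 < self.sweep_fixation <= 1.0:
            raise ValueError("sweep_fixation must lie in (0.5, 1]")
        for r in self.sweep_regions:
            if not (0 <= r.start < r.end <= self.contig_length):
                raise ValueError(
                    f"sweep region {r.contig}:{r.start}-{r.end} outside contig"
                )

    @property
    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_contigs)]

    @property
    def group_labels(self) -> list[str]:
        return [f"{b}_{g}" for b in BREEDS for g in GROUPS]


@dataclass
class TruthRecord:
    """Ground truth behind a simulated panel, for parameter-recovery tests.

    ``group_freq`` columns are the four breed×group labels; ``sweep_site``
    flags sites inside any sweep region; ``sample_groups`` maps sample id to
    its true (breed, group).
    """

    sites: pd.DataFrame  # contig, position (1-based)
    ancestral_freq: np.ndarray
    breed_freq: pd.DataFrame
    group_freq: pd.DataFrame
    sweep_site: np.ndarray
    sample_groups: pd.DataFrame

    def to_tsv(self, path) -> None:
        df = self.sites.copy()
        df["ancestral_freq"] = self.ancestral_freq
        for col in self.group_freq.columns:
            df[f"freq_{col}"] = self.group_freq[col].to_numpy()
        df["sweep_site"] = self.sweep_site.astype(int)
        df.to_csv(path, sep="\t", index=False)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _sample_table_skeleton(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for b in BREEDS:
        for g in GROUPS:
            for i in range(cfg.n_per_group):
                idx = (GROUPS.index(g)) * cfg.n_per_group + i
                rows.append(
                    {
                        "sample_id": f"{b}{idx:03d}",
                        "population": b,
                        "group": g,
                    }
                )
    return pd.DataFrame(rows)


def simulate_frequencies(cfg: SimConfig) -> TruthRecord:
    """Draw site positions and the frequency hierarchy; no sweeps yet."""
    rng = np.random.default_rng([cfg.seed, 0])
    # distribute sites across contigs, positions unique and sorted
    per_contig = np.full(cfg.n_contigs, cfg.n_sites // cfg.n_contigs)
    per_contig[: cfg.n_sites % cfg.n_contigs] += 1
    contigs: list[str] = []
    positions: list[np.ndarray] = []
    for name, k in zip(cfg.contig_names, per_contig):
        pos = rng.choice(cfg.contig_length, size=int(k), replace=False) + 1
        pos.sort()
        contigs.extend([name] * int(k))
        positions.append(pos)
    sites = pd.DataFrame({"contig": contigs, "position": np.concatenate(positions)})

    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_sites)
    breed_freq = {b: _balding_nichols(rng, p_anc, cfg.fst_between_breeds) for b in BREEDS}
    group_freq = {
        f"{b}_{g}": _balding_nichols(rng, breed_freq[b], cfg.fst_between_groups)
        for b in BREEDS
        for g in GROUPS
    }
    return TruthRecord(
        sites=sites,
        ancestral_freq=p_anc,
        breed_freq=pd.DataFrame(breed_freq),
        group_freq=pd.DataFrame(group_freq),
        sweep_site=np.zeros(cfg.n_sites, dtype=bool),
        sample_groups=_sample_table_skeleton(cfg),
    )


def inject_sweep(truth: TruthRecord, cfg: SimConfig) -> TruthRecord:
    """Push the target group's frequencies toward major-allele fixation
    inside each configured sweep region (in place; also returned)."""
    contig = truth.sites["contig"].to_numpy()
    pos0 = truth.sites["position"].to_numpy() - 1
    f = cfg.sweep_fixation
    for region in cfg.sweep_regions:
        in_region = (contig == region.contig) & (pos0 >= region.start) & (pos0 < region.end)
        if not in_region.any():
            warnings.warn(
                f"sweep region {region.contig}:{region.start}-{region.end} "
                "contains no sites; skipped"
            )
            continue
        col = region.target
        if col not in truth.group_freq.columns:
            raise ValueError(f"unknown sweep target group {col!r}")
        p = truth.group_freq[col].to_numpy().copy()
        major = p[in_region] >= 0.5
        swept = p[in_region]
        swept[major] = np.maximum(swept[major], f)
        swept[~major] = np.minimum(swept[~major], 1.0 - f)
        p[in_region] = swept
        truth.group_freq[col] = p
        truth.sweep_site |= in_region
    return truth


def simulate_genotypes(truth: TruthRecord, cfg: SimConfig) -> GenotypeMatrix:
    """Binomial genotypes from the group frequencies, with missingness and
    QUAL/GQ annotations that pass the default QC screen (a configurable
    fraction of sites is given failing QUAL for filter testing)."""
    rng = np.random.default_rng([cfg.seed, 1])
    table = truth.sample_groups
    n_samples = len(table)
    n_sites = len(truth.sites)
    calls = np.empty((n_samples, n_sites), dtype=np.int8)

    if cfg.ld_block_size > 0:
        block = _block_index(truth.sites, cfg.ld_block_size)
        for label in cfg.group_labels:
            rows = np.flatnonzero((table["population"] + "_" + table["group"]) == label)
            freq = truth.group_freq[label].to_numpy()
            for b in np.unique(block):
                sel = block == b
                anchor = np.flatnonzero(sel)[0]
                g = rng.binomial(2, freq[anchor], size=len(rows)).astype(np.int8)
                calls[np.ix_(rows, np.flatnonzero(sel))] = g[:, None]
    else:
        for label in cfg.group_labels:
            rows = np.flatnonzero((table["population"] + "_" + table["group"]) == label)
            freq = truth.group_freq[label].to_numpy()
            calls[rows, :] = rng.binomial(2, freq[None, :], size=(len(rows), n_sites))

    if cfg.missing_rate > 0:
        mask = rng.random((n_samples, n_sites)) < cfg.missing_rate
        calls[mask] = MISSING

    qual = np.round(rng.uniform(30.0, 100.0, size=n_sites), 2)
    if cfg.qc_fail_fraction > 0:
        n_fail = int(round(cfg.qc_fail_fraction * n_sites))
        fail = rng.choice(n_sites, size=n_fail, replace=False)
        qual[fail] = np.round(rng.uniform(0.0, 29.9, size=n_fail), 2)
    gq = rng.integers(10, 100, size=(n_samples, n_sites)).astype(np.int32)

    sites = [
        SiteInfo(
            contig=c,
            position=int(p),
            ref_allele="A",
            alt_allele="G",
            qual=float(q),
        )
        for c, p, q in zip(
            truth.sites["contig"], truth.sites["position"], qual
        )
    ]
    samples = [
        SampleInfo(sample_id=r.sample_id, population=r.population)
        for r in table.itertuples()
    ]
    return GenotypeMatrix(
        calls=calls,
        sites=sites,
        samples=samples,
        gq=gq,
        contig_lengths={c: cfg.contig_length for c in cfg.contig_names},
    )


def _block_index(sites: pd.DataFrame, block_size: int) -> np.ndarray:
    codes, _ = pd.factorize(sites["contig"])
    return codes * (10**9) + (sites["position"].to_numpy() - 1) // block_size


def simulate_phenotypes(cfg: SimConfig, truth: TruthRecord) -> pd.DataFrame:
    """Milk-yield phenotypes: Normal(group mean, sd), HY mean > LY mean.

    Returns the sample table (sample_id, population, phenotype)."""
    rng = np.random.default_rng([cfg.seed, 2])
    table = truth.sample_groups.copy()
    mean_hy, mean_ly = cfg.phenotype_means
    if mean_hy <= mean_ly:
        raise ValueError("HY phenotype mean must exceed LY mean")
    means = np.where(table["group"] == "HY", mean_hy, mean_ly)
    table["phenotype"] = rng.normal(means, cfg.phenotype_sd)
    return table[["sample_id", "population", "phenotype"]]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


def generate_gene_models(cfg: SimConfig, gff_path) -> pd.DataFrame:
    """Tile gene models along each contig and write them as GFF3.

    Genes of ``gene_length`` bp start every ``gene_spacing`` bp, strand
    alternating.  Each gene carries a gene→mRNA→(UTR5, 3 exons, UTR3)
    hierarchy; the UTRs occupy the transcript ends (500 bp each) and the
    exons tile the interior coding span.  Returns the gene interval table
    (gene_id, contig, start, end, strand; 0-based half-open).
    """
    if cfg.gene_length > cfg.gene_spacing:
        raise ValueError("gene_length exceeds gene_spacing: genes would overlap")
    utr_len = 500
    if cfg.gene_length <= 2 * utr_len + 5:
        raise ValueError("gene_length too short for UTR/exon layout")
    lines = ["##gff-version 3"]
    rows = []
    for contig in cfg.contig_names:
        lines.append(f"##sequence-region {contig} 1 {cfg.contig_length}")
    for contig in cfg.contig_names:
        n_genes = cfg.contig_length // cfg.gene_spacing
        for i in range(n_genes):
            start0 = i * cfg.gene_spacing
            end0 = start0 + cfg.gene_length
            strand = "+" if i % 2 == 0 else "-"
            gid = f"gene_{contig}_{i:04d}"
            rows.append(
                {"gene_id": gid, "contig": contig, "start": start0, "end": end0,
                 "strand": strand}
            )
            # transcript layout in gene-local coordinates
            coding = cfg.gene_length - 2 * utr_len
            exon_len = coding // 5
            exons_local = [
                (utr_len, utr_len + exon_len),
                (utr_len + 2 * exon_len, utr_len + 3 * exon_len),
                (utr_len + 4 * exon_len, utr_len + coding),
            ]
            left_utr = (0, utr_len)
            right_utr = (cfg.gene_length - utr_len, cfg.gene_length)
            utr5, utr3 = (left_utr, right_utr) if strand == "+" else (right_utr, left_utr)

            def row(ftype: str, lo: int, hi: int, feat_id: str, parent: str) -> str:
                return "\t".join(
                    [contig, "popsweep_sim", ftype, str(start0 + lo + 1),
                     str(start0 + hi), ".", strand, ".",
                     f"ID={feat_id};Parent={parent}"]
                )

            lines.append(
                "\t".join(
                    [contig, "popsweep_sim", "gene", str(start0 + 1), str(end0),
                     ".", strand, ".", f"ID={gid};Name={gid.upper()}"]
                )
            )
            mid = f"{gid}.t1"
            lines.append(row("mRNA", 0, cfg.gene_length, mid, gid))
            lines.append(row("five_prime_UTR", utr5[0], utr5[1], f"{mid}.utr5", mid))
            for k, (lo, hi) in enumerate(exons_local, start=1):
                lines.append(row("exon", lo, hi, f"{mid}.exon{k}", mid))
            lines.append(row("three_prime_UTR", utr3[0], utr3[1], f"{mid}.utr3", mid))
    Path(gff_path).write_text("\n".join(lines) + "\n")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bundles and QC fixtures
# ---------------------------------------------------------------------------


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, TruthRecord, pd.DataFrame]:
    """Run the full generator: frequencies → sweeps → genotypes → phenotypes.

    Returns (GenotypeMatrix with phenotypes attached, TruthRecord, sample table).
    """
    truth = simulate_frequencies(cfg)
    inject_sweep(truth, cfg)
    gm = simulate_genotypes(truth, cfg)
    table = simulate_phenotypes(cfg, truth)
    by_id = table.set_index("sample_id")["phenotype"]
    for s in gm.samples:
        s.phenotype = float(by_id[s.sample_id])
    return gm, truth, table


def write_bundle(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Write the complete fixture bundle (VCF, GFF3, sample TSV, truth TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, truth, table = simulate_panel(cfg)
    paths = {
        "vcf": outdir / "panel.vcf",
        "gff": outdir / "genes.gff3",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(gm, paths["vcf"])
    generate_gene_models(cfg, paths["gff"])
    write_sample_table(table, paths["samples"])
    truth.to_tsv(paths["truth"])
    return paths


def make_filter_fixture(
    n_sites: int = 1000,
    n_low_maf: int = 100,
    n_low_qual: int = 50,
    n_high_missing: int = 25,
    n_hwe_fail: int = 0,
    n_multiallelic: int = 0,
    n_samples: int = 60,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Genotype matrix with a known number of violations of each site filter.

    Violating site classes are disjoint and constructed deterministically so
    the expected FilterReport counts equal the arguments exactly: low-MAF
    sites carry two alternate alleles in total, low-QUAL sites have QUAL in
    [0, 30), high-missing sites have a 10% missing-call rate, HWE-fail sites
    are entirely heterozygous, and clean sites hold Hardy–Weinberg
    proportions at p = 0.5 with full calls.
    """
    n_bad = n_low_maf + n_low_qual + n_high_missing + n_hwe_fail + n_multiallelic
    if n_bad > n_sites:
        raise ValueError("violation counts exceed n_sites")
    if n_samples % 4:
        raise ValueError("n_samples must be divisible by 4")
    rng = np.random.default_rng(seed)
    calls = np.empty((n_samples, n_sites), dtype=np.int8)
    # clean template: HWE proportions at p = 0.5
    template = np.array(
        [0] * (n_samples // 4) + [1] * (n_samples // 2) + [2] * (n_samples // 4),
        dtype=np.int8,
    )
    for j in range(n_sites):
        calls[:, j] = rng.permutation(template)

    labels = (
        ["maf"] * n_low_maf
        + ["qual"] * n_low_qual
        + ["missing"] * n_high_missing
        + ["hwe"] * n_hwe_fail
        + ["biallelic"] * n_multiallelic
        + ["clean"] * (n_sites - n_bad)
    )
    order = rng.permutation(n_sites)
    qual = np.round(rng.uniform(40.0, 90.0, size=n_sites), 1)
    biallelic = np.ones(n_sites, dtype=bool)
    n_miss = int(np.ceil(0.10 * n_samples))
    for j, lab in zip(order, labels):
        if lab == "maf":
            col = np.zeros(n_samples, dtype=np.int8)
            col[rng.choice(n_samples, 2, replace=False)] = 1  # MAF = 1/n_samples
            calls[:, j] = col
        elif lab == "qual":
            qual[j] = round(float(rng.uniform(0.0, 29.9)), 1)
        elif lab == "missing":
            idx = rng.choice(n_samples, n_miss, replace=False)
            calls[idx, j] = MISSING
        elif lab == "hwe":
            calls[:, j] = 1  # all heterozygous: exact p ≈ 0
        elif lab == "biallelic":
            biallelic[j] = False

    sites = [
        SiteInfo(
            contig="chr1",
            position=1000 * (j + 1),
            ref_allele="A",
            alt_allele="G" if biallelic[j] else "G,T",
            qual=float(qual[j]),
            is_biallelic=bool(biallelic[j]),
        )
        for j in range(n_sites)
    ]
    samples = [SampleInfo(sample_id=f"S{i:03d}") for i in range(n_samples)]
    gm = GenotypeMatrix(calls=calls, sites=sites, samples=samples)
    expected = {
        "biallelic": n_multiallelic,
        "qual": n_low_qual,
        "missing": n_high_missing,
        "maf": n_low_maf,
        "hwe": n_hwe_fail,
    }
    return gm, expected
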