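"""Biallelic genotype matrices, VCF I/O and quality-control filters.

The central container is :class:`GenotypeMatrix`: a samples × sites matrix of
alternate-allele dosages (0, 1, 2, or missing) with per-site and per-sample
metadata.  Every downstream statistic — diversity, kinship, Fst, windowed π —
operates on dosages; phasing is ignored throughout.

QC follows the conventional resequencing screen: per-genotype GQ masking,
biallelic-only, site QUAL, site missingness, minor-allele frequency, and a
Hardy–Weinberg exact test, applied in that fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing dosage in GenotypeMatrix.calls
MISSING: int = -1


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a GenotypeMatrix."""


@dataclass
class SiteInfo:
    """One variant site.  Positions are 1-based, as in VCF."""

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    qual: float = math.nan
    is_biallelic: bool = True


@dataclass
class SampleInfo:
    sample_id: str
    population: str = ""
    phenotype: Optional[float] = None


@dataclass
class FilterConfig:
    """Thresholds for the site/sample screen.

    Defaults: MAF ≥ 0.05, site missingness ≤ 0.05, sample missingness ≤ 0.10,
    HWE exact p > 1e-6, QUAL ≥ 30, GQ ≥ 10, biallelic sites only.
    """

    maf_min: float = 0.05
    site_missing_max: float = 0.05
    sample_missing_max: float = 0.10
    hwe_p_min: float = 1e-6
    qual_min: float = 30.0
    gq_min: int = 10
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_min", "site_missing_max", "sample_missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FilterReport:
    """Removal counts per criterion, in the order the criteria were applied."""

    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    n_genotypes_masked: int = 0

    def __post_init__(self) -> None:
        total = sum(self.removed.values())
        if self.n_input - self.n_output != total:
            raise ValueError(
                f"inconsistent report: {self.n_input} - {self.n_output} != {total}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "n_removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "total_removed", "n_removed": self.n_input - self.n_output})
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class GenotypeMatrix:
    """Samples × biallelic sites with dosage calls in {0, 1, 2, MISSING}.

    ``calls[i, j]`` is the alternate-allele count of sample *i* at site *j*.
    ``gq`` optionally carries per-genotype quality scores of the same shape.
    Sites are kept sorted by (contig, position).
    """

    calls: np.ndarray
    sites: list[SiteInfo]
    samples: list[SampleInfo]
    gq: Optional[np.ndarray] = None
    contig_lengths: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples × sites)")
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)} samples, {len(self.sites)} sites)"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid dosage values {bad.tolist()}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        keys = [(s.contig, s.position) for s in self.sites]
        if keys != sorted(keys):
            raise ValueError("sites not sorted by (contig, position)")
        if self.gq is not None and self.gq.shape != self.calls.shape:
            raise ValueError("gq shape mismatch")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def site_positions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [s.contig for s in self.sites],
                "position": [s.position for s in self.sites],
            }
        )

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosages_float(self) -> np.ndarray:
        """Calls as float with missing encoded as NaN."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    def subset_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            calls=self.calls[:, index],
            sites=[self.sites[j] for j in index],
            samples=list(self.samples),
            gq=None if self.gq is None else self.gq[:, index],
            contig_lengths=self.contig_lengths,
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            calls=self.calls[index, :],
            sites=list(self.sites),
            samples=[self.samples[i] for i in index],
            gq=None if self.gq is None else self.gq[index, :],
            contig_lengths=self.contig_lengths,
        )

    def alt_frequency(self) -> np.ndarray:
        """Per-site alternate-allele frequency from non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypeMatrix:
    """Read a multi-sample VCF into a GenotypeMatrix.

    Diploid GT fields are parsed to alternate-allele dosage regardless of the
    phasing separator.  Half-missing genotypes (``./1``) are treated as fully
    missing.  Multi-allelic records are retained with ``is_biallelic=False``
    (and any genotype carrying an allele index > 1 set missing) so that the
    biallelic filter can drop them.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib reports its own diagnostics
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise VcfParseError(f"VCF {path} has no samples")

    contig_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig="):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            if "ID" in fields and "length" in fields:
                contig_lengths[fields["ID"]] = int(fields["length"])

    rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    sites: list[SiteInfo] = []
    have_gq = False
    for rec_no, var in enumerate(vcf, start=1):
        try:
            gts = var.genotypes
        except Exception as exc:
            raise VcfParseError(f"malformed VCF record #{rec_no} in {path}: {exc}") from exc
        dos = np.full(len(sample_ids), MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            a = g[:-1]  # trailing element is the phased flag
            if len(a) != 2 or min(a) < 0:
                continue  # haploid or (half-)missing
            if max(a) > 1:
                continue  # non-primary alt allele; site flagged below
            dos[i] = a[0] + a[1]
        try:
            gq = var.format("GQ")
        except KeyError:  # GQ not declared in the header
            gq = None
        if gq is not None:
            have_gq = True
            gq = np.asarray(gq).reshape(len(sample_ids)).astype(float)
            gq = np.where(np.isfinite(gq) & (gq >= 0), gq, 0).astype(np.int32)
        else:
            gq = np.zeros(len(sample_ids), dtype=np.int32)
        alts = var.ALT or ["."]
        sites.append(
            SiteInfo(
                contig=var.CHROM,
                position=var.POS,
                ref_allele=var.REF,
                alt_allele=",".join(alts),
                qual=math.nan if var.QUAL is None else float(var.QUAL),
                is_biallelic=len(alts) == 1,
            )
        )
        rows.append(dos)
        gq_rows.append(gq)

    if rows:
        calls = np.stack(rows, axis=1)
        gq_mat = np.stack(gq_rows, axis=1) if have_gq else None
    else:
        calls = np.zeros((len(sample_ids), 0), dtype=np.int8)
        gq_mat = None

    order = sorted(range(len(sites)), key=lambda j: (sites[j].contig, sites[j].position))
    gm = GenotypeMatrix(
        calls=calls[:, order] if sites else calls,
        sites=[sites[j] for j in order],
        samples=[SampleInfo(sample_id=s) for s in sample_ids],
        gq=None if gq_mat is None else gq_mat[:, order],
        contig_lengths=contig_lengths or None,
    )
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF 4.2 with GT:GQ fields.

    Output is deterministic (byte-identical for equal inputs); missing calls
    are emitted as ``./.``.
    """
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
    ]
    contigs: dict[str, int] = {}
    for s in gm.sites:
        contigs[s.contig] = max(contigs.get(s.contig, 0), s.position)
    if gm.contig_lengths:
        for c, ln in gm.contig_lengths.items():
            contigs[c] = max(contigs.get(c, 0), ln)
    for c in sorted(contigs):
        lines.append(f"##contig=<ID={c},length={contigs[c]}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"] + gm.sample_ids))
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    gq = gm.gq
    for j, site in enumerate(gm.sites):
        qual = "." if math.isnan(site.qual) else f"{site.qual:g}"
        cells = []
        for i in range(gm.n_samples):
            g = gt_of[int(gm.calls[i, j])]
            q = int(gq[i, j]) if gq is not None else 99
            cells.append(f"{g}:{q}")
        lines.append(
            "\t".join(
                [
                    site.contig,
                    str(site.position),
                    ".",
                    site.ref_allele,
                    site.alt_allele,
                    qual,
                    "PASS",
                    ".",
                    "GT:GQ",
                ]
                + cells
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test on genotype counts.

    Conditioning on the observed allele counts, the probability of each
    possible heterozygote count (same parity as the observed minor-allele
    count) is computed; the p-value is the sum of probabilities no larger than
    that of the observed configuration.  Returns a value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts zero")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant:
    #   C(n, h) C(n-h, (minor-h)/2) 2^h  /  (multivariate constant)
    lg = math.lgamma

    def log_weight(h: int) -> float:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        return (
            lg(n + 1)
            - lg(h + 1)
            - lg(hom_minor + 1)
            - lg(hom_major + 1)
            + h * math.log(2.0)
        )

    hets = range(n_minor % 2, n_minor + 1, 2)
    logs = np.array([log_weight(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[(n_Aa - n_minor % 2) // 2]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chi2_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-degree-of-freedom chi-square alternative to the exact test."""
    from scipy.stats import chi2

    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all genotype counts zero")
    p = (2 * n_AA + n_Aa) / (2 * n)
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    if (exp == 0).any():
        return 1.0
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    obs = gm.calls != MISSING
    n_aa = ((gm.calls == 0) & obs).sum(axis=0)
    n_ab = ((gm.calls == 1) & obs).sum(axis=0)
    n_bb = ((gm.calls == 2) & obs).sum(axis=0)
    out = np.ones(gm.n_sites)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(gm.n_sites):
        key = (int(n_aa[j]), int(n_ab[j]), int(n_bb[j]))
        if sum(key) == 0:
            out[j] = np.nan
            continue
        if key not in cache:
            cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

#: fixed application order of the site criteria
SITE_FILTER_ORDER = ("biallelic", "qual", "missing", "maf", "hwe")


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the site-level screen in the fixed order
    GQ-masking → biallelic → QUAL → missingness → MAF → HWE.

    Genotypes with GQ below ``cfg.gq_min`` are set missing *before* the
    missingness and frequency criteria are evaluated.  A site is removed at
    the first criterion it fails, so the per-criterion counts in the report
    depend on this order.
    """
    calls = gm.calls.copy()
    n_masked = 0
    if gm.gq is not None and cfg.gq_min > 0:
        mask = (gm.gq < cfg.gq_min) & (calls != MISSING)
        n_masked = int(mask.sum())
        calls[mask] = MISSING
    work = GenotypeMatrix(
        calls=calls,
        sites=list(gm.sites),
        samples=list(gm.samples),
        gq=gm.gq,
        contig_lengths=gm.contig_lengths,
    )

    alive = np.ones(work.n_sites, dtype=bool)
    removed: dict[str, int] = {}

    def drop(name: str, fail: np.ndarray) -> None:
        fail = fail & alive
        removed[name] = int(fail.sum())
        alive[fail] = False

    if cfg.biallelic_only:
        drop("biallelic", np.array([not s.is_biallelic for s in work.sites]))
    else:
        removed["biallelic"] = 0

    quals = np.array([s.qual for s in work.sites])
    with np.errstate(invalid="ignore"):
        drop("qual", ~(quals >= cfg.qual_min))

    # direct count/n keeps boundary fractions (e.g. exactly 5%) exact
    miss_frac = (work.calls == MISSING).mean(axis=0)
    drop("missing", miss_frac > cfg.site_missing_max)

    freq = work.alt_frequency()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    drop("maf", ~(maf >= cfg.maf_min))

    hwe_p = _hwe_pvalues(work)
    with np.errstate(invalid="ignore"):
        drop("hwe", ~(hwe_p > cfg.hwe_p_min))

    out = work.subset_sites(alive)
    report = FilterReport(
        n_input=gm.n_sites,
        n_output=out.n_sites,
        removed=removed,
        n_genotypes_masked=n_masked,
    )
    return out, report


def filter_samples(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove samples whose missing-call fraction strictly exceeds
    ``cfg.sample_missing_max``.  Site filters are not re-applied."""
    if gm.n_sites == 0:
        return gm, FilterReport(n_input=gm.n_samples, n_output=gm.n_samples,
                                removed={"missing": 0})
    miss_frac = (gm.calls == MISSING).mean(axis=1)
    keep = miss_frac <= cfg.sample_missing_max
    if not keep.any():
        raise RuntimeError("sample-missingness filter removed every sample")
    out = gm.subset_samples(keep)
    report = FilterReport(
        n_input=gm.n_samples,
        n_output=out.n_samples,
        removed={"missing": int((~keep).sum())},
    )
    return out, report


# ---------------------------------------------------------------------------
# Sample table I/O
# ---------------------------------------------------------------------------


def read_sample_table(path) -> pd.DataFrame:
    """Read a headered TSV with columns sample_id, population, phenotype."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    required = {"sample_id", "population", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table {path} lacks columns: {sorted(missing)}")
    return df


def write_sample_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def attach_phenotypes(gm: GenotypeMatrix, table: pd.DataFrame) -> GenotypeMatrix:
    """Return a copy of ``gm`` with population labels and phenotypes taken
    from a sample table (rows matched on sample_id)."""
    by_id = table.set_index("sample_id")
    samples = []
    for s in gm.samples:
        if s.sample_id in by_id.index:
            row = by_id.loc[s.sample_id]
            pheno = row["phenotype"]
            samples.append(
                replace(
                    s,
                    population=str(row["population"]),
                    phenotype=None if pd.isna(pheno) else float(pheno),
                )
            )
        else:
            samples.append(s)
    return GenotypeMatrix(
        calls=gm.calls, sites=list(gm.sites), samples=samples,
        gq=gm.gq, contig_lengths=gm.contig_lengths,
    )
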