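"""Sliding-window Fst / θπ-ratio selective-sweep scan.

Samples with milk-yield records are split into high-yield (HY) and low-yield
(LY) quartile groups.  Over 50 kb windows stepped every 20 kb the scan
computes the Weir–Cockerham (1984) fixation index between the groups
(ratio-of-sums over the per-site variance components a, b, c), each group's
per-bp nucleotide diversity π, the genome-standardized Z(Fst), and
log2(π_HY / π_LY).  Candidate windows exceed the empirical 95th percentile of
Z(Fst) *and* fall in a 5% tail of the log2 ratio; selected windows are merged
into candidate regions and annotated with overlapping gene models.

Coordinates are 0-based half-open internally; tabular output adds 1-based
inclusive columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# HY/LY grouping
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    hy: list[str]
    ly: list[str]
    excluded: list[str]

    def label_of(self, sample_id: str) -> str:
        if sample_id in self.hy:
            return "HY"
        if sample_id in self.ly:
            return "LY"
        return "excluded"


def split_hy_ly(sample_table: pd.DataFrame) -> GroupAssignment:
    """Quartile grouping on phenotype: top ⌈n/4⌉ samples → HY, bottom
    ⌈n/4⌉ → LY, the middle half excluded.

    Samples lacking a phenotype are excluded first; the remainder is sorted
    by phenotype descending with ties broken by sample id ascending.
    """
    has = sample_table[sample_table["phenotype"].notna()].copy()
    no_pheno = sample_table.loc[sample_table["phenotype"].isna(), "sample_id"].tolist()
    if len(has) < 4:
        raise RuntimeError(
            f"quartile grouping needs ≥4 phenotyped samples, got {len(has)}"
        )
    has = has.sort_values(
        ["phenotype", "sample_id"], ascending=[False, True], kind="mergesort"
    )
    q = math.ceil(len(has) / 4)
    ids = has["sample_id"].tolist()
    hy = ids[:q]
    ly = ids[-q:]
    middle = ids[q : len(ids) - q]
    return GroupAssignment(hy=hy, ly=ly, excluded=middle + no_pheno)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


@dataclass
class WindowSpec:
    window_size: int = 50_000
    step_size: int = 20_000

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step_size <= 0:
            raise ValueError("window and step sizes must be positive")
        if self.step_size > self.window_size:
            raise ValueError("step size exceeds window size")


def make_windows(contig_lengths: dict[str, int], spec: WindowSpec) -> pd.DataFrame:
    """Sliding windows per contig: starts 0, step, 2·step, … with
    start + window ≤ contig length (no truncated trailing window)."""
    rows = []
    for contig in sorted(contig_lengths):
        length = contig_lengths[contig]
        if length <= 0:
            raise ValueError(f"contig {contig} has non-positive length")
        if length < spec.window_size:
            warnings.warn(
                f"contig {contig} ({length} bp) shorter than the window "
                f"({spec.window_size} bp); no windows emitted"
            )
            continue
        for start in range(0, length - spec.window_size + 1, spec.step_size):
            rows.append({"contig": contig, "start": start,
                         "end": start + spec.window_size})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def _site_window_sums(
    windows: pd.DataFrame,
    site_contig: np.ndarray,
    site_pos0: np.ndarray,
    values: np.ndarray,
) -> np.ndarray:
    """Sum each row of ``values`` (stats × sites) over the sites falling in
    every window, via per-contig cumulative sums."""
    out = np.zeros((values.shape[0], len(windows)))
    for contig, wdf in windows.groupby("contig", sort=False):
        sel = site_contig == contig
        pos = site_pos0[sel]
        vals = values[:, sel]
        csum = np.concatenate(
            [np.zeros((values.shape[0], 1)), np.cumsum(vals, axis=1)], axis=1
        )
        lo = np.searchsorted(pos, wdf["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, wdf["end"].to_numpy(), side="left")
        out[:, wdf.index.to_numpy()] = csum[:, hi] - csum[:, lo]
    return out


# ---------------------------------------------------------------------------
# Weir–Cockerham variance components
# ---------------------------------------------------------------------------


def wc_site_components(
    calls1: np.ndarray, calls2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir–Cockerham (1984) variance components for two groups.

    ``calls1``/``calls2`` are dosage matrices (samples × sites, MISSING
    sentinel allowed).  Returns (a, b, c, eligible) where *a* is the
    among-population component, *b* the between-individual-within-population
    component, *c* the within-individual component, and ``eligible`` marks
    sites with ≥2 called diploids in both groups (components are zeroed
    elsewhere).
    """
    r = 2.0
    stats = []
    for calls in (calls1, calls2):
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)  # called diploids
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2.0 * n, 1e-300)
            h = ((calls == 1) & obs).sum(axis=0) / np.maximum(n, 1e-300)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    eligible = (n1 >= 2) & (n2 >= 2)

    n_bar = (n1 + n2) / r
    n_sum = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (n_sum - (n1**2 + n2**2) / n_sum) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / n_sum
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / n_sum

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - s2 * (r - 1.0) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - s2 * (r - 1.0) / r
            - h_bar * (2.0 * n_bar - 1.0) / (4.0 * n_bar)
        )
        c = h_bar / 2.0

    a = np.where(eligible, a, 0.0)
    b = np.where(eligible, b, 0.0)
    c = np.where(eligible, c, 0.0)
    return a, b, c, eligible


def window_fst(
    gm: GenotypeMatrix, groups: GroupAssignment, windows: pd.DataFrame
) -> pd.DataFrame:
    """Per-window Weir–Cockerham Fst = Σa / Σ(a+b+c) over eligible sites
    (ratio-of-sums weighting).  Adds ``n_sites`` and ``fst`` columns; windows
    with no eligible sites or a zero denominator get NaN and are excluded
    from ranking downstream.  Negative estimates are retained."""
    for name, ids in (("HY", groups.hy), ("LY", groups.ly)):
        if not ids:
            raise RuntimeError(f"group {name} is empty")
    calls1 = gm.calls[gm.sample_index(groups.hy), :]
    calls2 = gm.calls[gm.sample_index(groups.ly), :]
    a, b, c, eligible = wc_site_components(calls1, calls2)

    pos_df = gm.site_positions()
    contig = pos_df["contig"].to_numpy()
    pos0 = pos_df["position"].to_numpy() - 1
    sums = _site_window_sums(
        windows, contig, pos0,
        np.vstack([a, a + b + c, eligible.astype(float)]),
    )
    out = windows.copy()
    out["n_sites"] = sums[2].astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = sums[0] / sums[1]
    fst[(sums[2] == 0) | (sums[1] == 0)] = np.nan
    out["fst"] = fst
    return out


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


def site_pi(calls: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference 2·c_ref·c_alt / (n(n−1)) over the
    group's non-missing alleles (0 where fewer than 2 alleles observed)."""
    obs = calls != MISSING
    n = 2.0 * obs.sum(axis=0)
    c_alt = np.where(obs, calls, 0).sum(axis=0).astype(float)
    c_ref = n - c_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * c_ref * c_alt / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def window_pi(
    gm: GenotypeMatrix,
    group_ids: list[str],
    windows: pd.DataFrame,
    column: str,
) -> pd.DataFrame:
    """Windowed per-bp π for one group: Σ site π over the window divided by
    the window span, stored in ``column``."""
    if not group_ids:
        raise RuntimeError("empty group for windowed π")
    calls = gm.calls[gm.sample_index(group_ids), :]
    pi = site_pi(calls)
    pos_df = gm.site_positions()
    sums = _site_window_sums(
        windows,
        pos_df["contig"].to_numpy(),
        pos_df["position"].to_numpy() - 1,
        pi[None, :],
    )
    out = windows.copy()
    span = (windows["end"] - windows["start"]).to_numpy().astype(float)
    out[column] = sums[0] / span
    return out


def z_fst(windows: pd.DataFrame) -> pd.DataFrame:
    """Standardize window Fst: z = (fst − mean) / sd over defined windows,
    with the population (denominator-n) standard deviation."""
    fst = windows["fst"].to_numpy()
    defined = np.isfinite(fst)
    if defined.sum() < 2:
        raise ValueError("need ≥2 windows with defined Fst")
    mu = fst[defined].mean()
    sd = fst[defined].std(ddof=0)
    if sd == 0.0:
        raise ValueError("window Fst has zero standard deviation")
    out = windows.copy()
    z = np.full_like(fst, np.nan)
    z[defined] = (fst[defined] - mu) / sd
    out["z_fst"] = z
    return out


def log2_pi_ratio(
    windows: pd.DataFrame, hy_col: str = "pi_hy", ly_col: str = "pi_ly"
) -> pd.DataFrame:
    """log2(π_HY / π_LY); windows where either π is zero (or undefined) get
    NaN and are excluded from ranking."""
    hy = windows[hy_col].to_numpy()
    ly = windows[ly_col].to_numpy()
    out = windows.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((hy > 0) & (ly > 0), np.log2(hy / ly), np.nan)
    out["log2_ratio"] = ratio
    return out


# ---------------------------------------------------------------------------
# Candidate selection, merging, annotation
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    windows: pd.DataFrame
    thresholds: dict[str, float]
    high_ratio_windows: pd.DataFrame
    low_ratio_windows: pd.DataFrame
    high_ratio_regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    low_ratio_regions: pd.DataFrame = field(default_factory=pd.DataFrame)
    high_ratio_genes: list[str] = field(default_factory=list)
    low_ratio_genes: list[str] = field(default_factory=list)

    @property
    def gene_union(self) -> list[str]:
        return sorted(set(self.high_ratio_genes) | set(self.low_ratio_genes))

    def oriented_genes(self, orientation: str = "reduced-diversity") -> dict[str, list[str]]:
        """Map the neutral high/low-ratio sets onto HY/LY labels.

        ``reduced-diversity`` (default): diversity loss in HY (low ratio)
        marks HY-selected loci.  ``paper-figure``: the opposite labelling,
        mapping the top log2-ratio tail to HY.
        """
        if orientation == "reduced-diversity":
            return {"HY": self.low_ratio_genes, "LY": self.high_ratio_genes}
        if orientation == "paper-figure":
            return {"HY": self.high_ratio_genes, "LY": self.low_ratio_genes}
        raise ValueError(f"unknown orientation {orientation!r}")


def select_candidates(windows: pd.DataFrame, quantile: float = 0.05) -> SweepResult:
    """Empirical-tail selection.

    Thresholds: the (1 − quantile) percentile of Z(Fst) and the
    (1 − quantile)/quantile percentiles of the log2 θπ ratio
    (linear-interpolation quantiles over defined windows).  The high-ratio
    set needs z ≥ z-threshold and ratio ≥ upper; the low-ratio set z ≥
    z-threshold and ratio ≤ lower.
    """
    if not 0.0 < quantile < 0.5:
        raise ValueError("quantile must lie in (0, 0.5)")
    z = windows["z_fst"].to_numpy()
    ratio = windows["log2_ratio"].to_numpy()
    ranked = np.isfinite(z) & np.isfinite(ratio)
    if ranked.sum() < 20:
        raise ValueError(
            f"only {int(ranked.sum())} windows with both statistics defined; need ≥20"
        )
    z_thr = float(np.quantile(z[np.isfinite(z)], 1.0 - quantile))
    r_hi = float(np.quantile(ratio[np.isfinite(ratio)], 1.0 - quantile))
    r_lo = float(np.quantile(ratio[np.isfinite(ratio)], quantile))
    high = ranked & (z >= z_thr) & (ratio >= r_hi)
    low = ranked & (z >= z_thr) & (ratio <= r_lo)
    return SweepResult(
        windows=windows,
        thresholds={
            "z_fst_upper": z_thr,
            "log2_ratio_upper": r_hi,
            "log2_ratio_lower": r_lo,
        },
        high_ratio_windows=windows[high].reset_index(drop=True),
        low_ratio_windows=windows[low].reset_index(drop=True),
    )


def merge_windows(selected: pd.DataFrame) -> pd.DataFrame:
    """Merge selected windows into maximal regions (overlap or book-end)."""
    if selected.empty:
        return pd.DataFrame(columns=["contig", "start", "end"])
    rows = []
    ordered = selected.sort_values(["contig", "start"])
    cur = None
    for w in ordered.itertuples():
        if cur is not None and w.contig == cur["contig"] and w.start <= cur["end"]:
            cur["end"] = max(cur["end"], w.end)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"contig": w.contig, "start": int(w.start), "end": int(w.end)}
    rows.append(cur)
    return pd.DataFrame(rows)


def merge_and_annotate(result: SweepResult, genes: pd.DataFrame) -> SweepResult:
    """Merge each selected window set into regions and attach candidate genes.

    ``genes`` needs columns gene_id, contig, start, end (0-based half-open).
    A gene is a candidate for a set iff its interval overlaps a merged region
    by ≥1 bp.  Gene contigs absent from the window universe raise an error.
    """
    known = set(result.windows["contig"].unique())
    offenders = sorted(set(genes["contig"].unique()) - known)
    if offenders:
        raise ValueError(
            f"gene contigs absent from the genotype data: {offenders}"
        )
    result.high_ratio_regions = merge_windows(result.high_ratio_windows)
    result.low_ratio_regions = merge_windows(result.low_ratio_windows)

    def overlapping(regions: pd.DataFrame) -> list[str]:
        hits: set[str] = set()
        for contig, rdf in regions.groupby("contig", sort=False):
            gsub = genes[genes["contig"] == contig]
            for reg in rdf.itertuples():
                hit = gsub[(gsub["start"] < reg.end) & (gsub["end"] > reg.start)]
                hits.update(hit["gene_id"])
        return sorted(hits)

    result.high_ratio_genes = overlapping(result.high_ratio_regions)
    result.low_ratio_genes = overlapping(result.low_ratio_regions)
    return result


def common_genes(a: SweepResult, b: SweepResult) -> list[str]:
    """Candidate genes shared by two independent scans (e.g. two breeds)."""
    return sorted(set(a.gene_union) & set(b.gene_union))


def windows_to_table(windows: pd.DataFrame) -> pd.DataFrame:
    """Per-window report with 1-based inclusive coordinates added."""
    out = windows.copy()
    out.insert(1, "start_1based", out["start"] + 1)
    out.insert(2, "end_1based", out["end"])
    return out


# ---------------------------------------------------------------------------
# Genomic-region classification
# ---------------------------------------------------------------------------


@dataclass
class _GeneRecord:
    gene_id: str
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)


class GeneModels:
    """Gene models with interval lookup for region classification."""

    UPSTREAM_BP = 1_000
    SPLICE_BP = 2

    def __init__(self, genes: list[_GeneRecord]):
        self._genes = genes
        self._trees: dict[str, IntervalTree] = {}
        for idx, g in enumerate(genes):
            tree = self._trees.setdefault(g.contig, IntervalTree())
            # envelope includes the flanking regions so one query suffices
            tree.addi(g.start - self.UPSTREAM_BP, g.end + self.UPSTREAM_BP, idx)

    @classmethod
    def from_gff(cls, path) -> "GeneModels":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes: list[_GeneRecord] = []
        for g in db.features_of_type("gene", order_by=("seqid", "start")):
            rec = _GeneRecord(
                gene_id=g.id, contig=g.seqid, start=g.start - 1, end=g.end,
                strand=g.strand if g.strand in "+-" else "+",
            )
            for child in db.children(g.id):
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    rec.exons.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    rec.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    rec.utr3.append(iv)
            genes.append(rec)
        return cls(genes)

    def gene_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"gene_id": g.gene_id, "contig": g.contig, "start": g.start,
                 "end": g.end, "strand": g.strand}
                for g in self._genes
            ]
        )

    def classify(self, contig: str, position: int) -> str:
        """Region label of a 1-based site position.

        Precedence: exonic > UTR5/UTR3 > splicing (within 2 bp of an exon
        boundary inside the gene) > intronic > upstream/downstream (within
        1 kb of the gene span, strand-aware) > intergenic.
        """
        pos0 = position - 1
        tree = self._trees.get(contig)
        if tree is None:
            return "intergenic"
        labels: set[str] = set()
        for iv in tree.at(pos0):
            g = self._genes[iv.data]
            labels.add(self._classify_in_gene(g, pos0))
        for lab in ("exonic", "UTR5", "UTR3", "splicing", "intronic",
                    "upstream", "downstream"):
            if lab in labels:
                return lab
        return "intergenic"

    def _classify_in_gene(self, g: _GeneRecord, pos0: int) -> str:
        if g.start <= pos0 < g.end:
            if any(lo <= pos0 < hi for lo, hi in g.exons):
                return "exonic"
            if any(lo <= pos0 < hi for lo, hi in g.utr5):
                return "UTR5"
            if any(lo <= pos0 < hi for lo, hi in g.utr3):
                return "UTR3"
            for lo, hi in g.exons:
                if abs(pos0 - lo) <= self.SPLICE_BP or abs(pos0 - (hi - 1)) <= self.SPLICE_BP:
                    return "splicing"
            return "intronic"
        if g.strand == "+":
            if g.start - self.UPSTREAM_BP <= pos0 < g.start:
                return "upstream"
            if g.end <= pos0 < g.end + self.UPSTREAM_BP:
                return "downstream"
        else:
            if g.end <= pos0 < g.end + self.UPSTREAM_BP:
                return "upstream"
            if g.start - self.UPSTREAM_BP <= pos0 < g.start:
                return "downstream"
        return "intergenic"

    def classify_sites(self, gm: GenotypeMatrix) -> pd.Series:
        labels = [self.classify(s.contig, s.position) for s in gm.sites]
        return pd.Series(labels, name="region")
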