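"""Per-locus diversity statistics (MAF, He, Ho, PIC) and LD decay.

All statistics are computed from dosages over non-missing calls only.  For a
biallelic site with alternate-allele frequency p (q = 1 − p):

* He  = 2pq                       (expected heterozygosity)
* Ho  = fraction of heterozygous calls
* MAF = min(p, q)
* PIC = 1 − (p² + q²) − 2p²q²     (Botstein's polymorphic information content)

PIC ≤ He at every locus.  Linkage disequilibrium is the squared Pearson
correlation r² between unphased dosage vectors, binned by physical distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix


@dataclass
class DiversitySummary:
    mean_maf: float
    mean_pic: float
    mean_he: float
    mean_ho: float
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


@dataclass
class LDDecayCurve:
    """Mean r² within contiguous distance bins [edge_k, edge_{k+1})."""

    bin_edges: np.ndarray  # length n_bins + 1, starting at 0
    mean_r2: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )

    def r2_at(self, distance_bp: int) -> float:
        """Mean r² of the bin containing ``distance_bp``."""
        k = int(np.searchsorted(self.bin_edges, distance_bp, side="right")) - 1
        if k < 0 or k >= len(self.mean_r2):
            raise ValueError(f"distance {distance_bp} outside curve range")
        return float(self.mean_r2[k])


def allele_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-site alt frequency, MAF, He, Ho and PIC.

    Sites with no non-missing calls get NaN statistics and are excluded from
    downstream means.
    """
    obs = gm.calls != MISSING
    n_called = obs.sum(axis=0)
    p = gm.alt_frequency()
    q = 1.0 - p
    he = 2.0 * p * q
    with np.errstate(invalid="ignore"):
        ho = np.where(n_called > 0,
                      ((gm.calls == 1) & obs).sum(axis=0) / np.maximum(n_called, 1),
                      np.nan)
    pic = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    df = gm.site_positions()
    df["n_called"] = n_called
    df["p_alt"] = p
    df["maf"] = np.fmin(p, q)
    df["he"] = he
    df["ho"] = ho
    df["pic"] = pic
    return df


def diversity_summary(gm: GenotypeMatrix) -> DiversitySummary:
    """Unweighted means of MAF, PIC, He, Ho over sites with ≥1 call."""
    stats = allele_stats(gm)
    defined = stats["n_called"] > 0
    if not defined.any():
        raise ValueError("no site has a non-missing call")
    sub = stats[defined]
    return DiversitySummary(
        mean_maf=float(sub["maf"].mean()),
        mean_pic=float(sub["pic"].mean()),
        mean_he=float(sub["he"].mean()),
        mean_ho=float(sub["ho"].mean()),
        n_sites=int(defined.sum()),
    )


def ld_r2(dosages_a: np.ndarray, dosages_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over jointly
    non-missing samples (missing encoded as the MISSING sentinel or NaN)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~np.isnan(a) & ~np.isnan(b) & (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 jointly non-missing samples")
    a, b = a[ok], b[ok]
    va = a.var()
    vb = b.var()
    if va == 0.0 or vb == 0.0:
        raise ValueError("zero dosage variance at one site")
    cov = ((a - a.mean()) * (b - b.mean())).mean()
    return float(cov * cov / (va * vb))


def ld_decay(
    gm: GenotypeMatrix,
    max_distance_bp: int = 500_000,
    bin_width_bp: int = 1_000,
) -> LDDecayCurve:
    """Mean r² of all intra-contig site pairs separated by ≤ max distance,
    binned by separation.  Pairs where either site is monomorphic among the
    jointly called samples are skipped."""
    n_bins = int(np.ceil(max_distance_bp / bin_width_bp))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    X = gm.dosages_float()
    pos_df = gm.site_positions()
    for contig, idx in pos_df.groupby("contig", sort=False).groups.items():
        idx = np.asarray(idx)
        pos = pos_df.loc[idx, "position"].to_numpy()
        D = X[:, idx]
        V = ~np.isnan(D)
        D0 = np.nan_to_num(D)
        m = len(idx)
        for i in range(m - 1):
            hi = int(np.searchsorted(pos, pos[i] + max_distance_bp, side="right"))
            if hi <= i + 1:
                continue
            sl = slice(i + 1, hi)
            # pairwise r² of column i against columns in sl, masking missing
            vi = V[:, i][:, None] & V[:, sl]
            n = vi.sum(axis=0).astype(float)
            good = n >= 2
            if not good.any():
                continue
            xi = np.where(vi, D0[:, i][:, None], 0.0)
            xj = np.where(vi, D0[:, sl], 0.0)
            si = xi.sum(axis=0)
            sj = xj.sum(axis=0)
            sii = (xi * xi).sum(axis=0)
            sjj = (xj * xj).sum(axis=0)
            sij = (xi * xj).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                var_i = sii - si * si / n
                var_j = sjj - sj * sj / n
                cov = sij - si * sj / n
                r2 = cov * cov / (var_i * var_j)
            good &= (var_i > 1e-12) & (var_j > 1e-12)
            if not good.any():
                continue
            dist = pos[sl] - pos[i]
            bins = np.minimum(dist // bin_width_bp, n_bins - 1).astype(int)
            np.add.at(sums, bins[good], r2[good])
            np.add.at(counts, bins[good], 1)

    if counts.sum() == 0:
        warnings.warn("no eligible site pairs within the distance limit")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(bin_edges=edges, mean_r2=mean_r2, pair_counts=counts)
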