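"""End-to-end orchestration: QC → diversity → structure → sweep scan → ORA.

Each stage writes its tabular outputs to the run directory and records them
in a manifest (inputs, configuration hash, seed, output row counts).  Runs
with equal manifests produce equal outputs: the single configured seed
drives every stochastic stage via deterministically derived sub-seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import diversity, enrich, structure, sweep
from .genotypes import (
    FilterConfig,
    GenotypeMatrix,
    attach_phenotypes,
    read_sample_table,
    read_vcf,
    write_vcf,
)

log = logging.getLogger("popsweep")


@dataclass
class PipelineConfig:
    vcf: str
    sample_table: str
    gff: Optional[str] = None
    outdir: str = "popsweep_out"
    filters: FilterConfig = field(default_factory=FilterConfig)
    window: sweep.WindowSpec = field(default_factory=sweep.WindowSpec)
    quantile: float = 0.05
    orientation: str = "reduced-diversity"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    ld_max_distance: int = 500_000
    ld_bin_width: int = 1_000
    seed: int = 0

    def subseed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class Manifest:
    def __init__(self, cfg: PipelineConfig):
        self.data = {
            "config": asdict(cfg),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "outputs": {},
        }
        self.outdir = Path(cfg.outdir)

    def record(self, name: str, path: Path, n_rows: int) -> None:
        self.data["outputs"][name] = {"path": str(path), "n_rows": int(n_rows)}

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True, default=str) + "\n")
        return path


def _save(df: pd.DataFrame, path: Path, manifest: Manifest, name: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    manifest.record(name, path, len(df))


def run_qc(cfg: PipelineConfig, manifest: Manifest) -> GenotypeMatrix:
    from .genotypes import filter_samples, filter_sites

    gm = read_vcf(cfg.vcf)
    table = read_sample_table(cfg.sample_table)
    gm = attach_phenotypes(gm, table)
    log.info("loaded %d samples × %d sites from %s", gm.n_samples, gm.n_sites, cfg.vcf)
    gm, site_report = filter_sites(gm, cfg.filters)
    log.info("site filter: %d → %d (%s)", site_report.n_input, site_report.n_output,
             site_report.removed)
    gm, sample_report = filter_samples(gm, cfg.filters)
    log.info("sample filter: %d → %d", sample_report.n_input, sample_report.n_output)
    _save(site_report.to_frame(), manifest.outdir / "filter_sites.tsv", manifest,
          "filter_sites")
    _save(sample_report.to_frame(), manifest.outdir / "filter_samples.tsv", manifest,
          "filter_samples")
    write_vcf(gm, manifest.outdir / "filtered.vcf")
    manifest.record("filtered_vcf", manifest.outdir / "filtered.vcf", gm.n_sites)
    return gm


def run_diversity(cfg: PipelineConfig, gm: GenotypeMatrix, manifest: Manifest) -> dict:
    per_site = diversity.allele_stats(gm)
    summary = diversity.diversity_summary(gm)
    curve = diversity.ld_decay(gm, cfg.ld_max_distance, cfg.ld_bin_width)
    _save(per_site, manifest.outdir / "site_stats.tsv", manifest, "site_stats")
    _save(summary.to_frame(), manifest.outdir / "diversity_summary.tsv", manifest,
          "diversity_summary")
    _save(curve.to_frame(), manifest.outdir / "ld_decay.tsv", manifest, "ld_decay")
    return {"summary": summary, "ld_curve": curve}


def run_structure(cfg: PipelineConfig, gm: GenotypeMatrix, manifest: Manifest) -> dict:
    dm = structure.ibs_distance(gm)
    grm = structure.grm_vanraden(gm)
    pc = structure.pca(gm)
    tree = structure.neighbor_joining(dm)
    (manifest.outdir / "nj_tree.nwk").write_text(tree.newick + "\n")
    manifest.record("nj_tree", manifest.outdir / "nj_tree.nwk", len(tree.leaf_names()))
    dm.to_frame().to_csv(manifest.outdir / "ibs_distance.tsv", sep="\t")
    manifest.record("ibs_distance", manifest.outdir / "ibs_distance.tsv", gm.n_samples)
    grm.to_frame().to_csv(manifest.outdir / "grm.tsv", sep="\t")
    manifest.record("grm", manifest.outdir / "grm.tsv", gm.n_samples)
    pc_df = pc.to_frame()
    _save(pc_df, manifest.outdir / "pca.tsv", manifest, "pca")
    _save(
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pc.variance_explained_pct))],
                      "variance_pct": pc.variance_explained_pct}),
        manifest.outdir / "pca_variance.tsv", manifest, "pca_variance",
    )
    cv_errors, best_k = structure.admixture_cv(
        gm, cfg.k_range, seed=cfg.subseed("admixture_cv")
    )
    fit = structure.admixture_em(gm, best_k, seed=cfg.subseed("admixture_em"))
    _save(fit.q_frame(gm.sample_ids), manifest.outdir / "admixture_Q.tsv", manifest,
          "admixture_Q")
    _save(
        pd.DataFrame({"K": list(cv_errors), "cv_error": list(cv_errors.values())}),
        manifest.outdir / "admixture_cv.tsv", manifest, "admixture_cv",
    )
    log.info("admixture: best K = %d (CV errors %s)", best_k, cv_errors)
    return {"pca": pc, "tree": tree, "cv_errors": cv_errors, "best_k": best_k,
            "fit": fit, "ibs": dm, "grm": grm}


def run_scan(
    cfg: PipelineConfig,
    gm: GenotypeMatrix,
    manifest: Manifest,
    population: Optional[str] = None,
) -> sweep.SweepResult:
    """The Fst/θπ scan for one population (or all samples if None)."""
    tag = population or "all"
    if population is not None:
        keep = [i for i, s in enumerate(gm.samples) if s.population == population]
        if not keep:
            raise RuntimeError(f"no samples from population {population!r}")
        gm = gm.subset_samples(np.array(keep))
    table = pd.DataFrame(
        {
            "sample_id": gm.sample_ids,
            "phenotype": [s.phenotype for s in gm.samples],
        }
    )
    groups = sweep.split_hy_ly(table)
    log.info("[%s] HY=%d LY=%d excluded=%d", tag, len(groups.hy), len(groups.ly),
             len(groups.excluded))
    contig_lengths = gm.contig_lengths
    if not contig_lengths:
        pos = gm.site_positions()
        contig_lengths = pos.groupby("contig")["position"].max().to_dict()
    windows = sweep.make_windows(contig_lengths, cfg.window)
    windows = sweep.window_fst(gm, groups, windows)
    windows = sweep.window_pi(gm, groups.hy, windows, "pi_hy")
    windows = sweep.window_pi(gm, groups.ly, windows, "pi_ly")
    windows = sweep.z_fst(windows)
    windows = sweep.log2_pi_ratio(windows)
    result = sweep.select_candidates(windows, cfg.quantile)
    log.info("[%s] thresholds %s", tag, result.thresholds)

    if cfg.gff is not None:
        models = sweep.GeneModels.from_gff(cfg.gff)
        result = sweep.merge_and_annotate(result, models.gene_table())
        region_counts = models.classify_sites(gm).value_counts()
        _save(region_counts.rename_axis("region").reset_index(name="n_sites"),
              manifest.outdir / f"snp_regions_{tag}.tsv", manifest,
              f"snp_regions_{tag}")

    _save(sweep.windows_to_table(result.windows),
          manifest.outdir / f"windows_{tag}.tsv", manifest, f"windows_{tag}")
    for name, wdf, regions, genes in (
        ("high_ratio", result.high_ratio_windows, result.high_ratio_regions,
         result.high_ratio_genes),
        ("low_ratio", result.low_ratio_windows, result.low_ratio_regions,
         result.low_ratio_genes),
    ):
        _save(sweep.windows_to_table(wdf),
              manifest.outdir / f"selected_{name}_{tag}.tsv", manifest,
              f"selected_{name}_{tag}")
        if isinstance(regions, pd.DataFrame) and not regions.empty:
            bed = regions[["contig", "start", "end"]]
            bed.to_csv(manifest.outdir / f"regions_{name}_{tag}.bed", sep="\t",
                       index=False, header=False)
            manifest.record(f"regions_{name}_{tag}",
                            manifest.outdir / f"regions_{name}_{tag}.bed", len(bed))
        if genes:
            gdf = pd.DataFrame({"gene_id": genes})
            _save(gdf, manifest.outdir / f"genes_{name}_{tag}.tsv", manifest,
                  f"genes_{name}_{tag}")
    return result


def run_enrich(
    cfg: PipelineConfig,
    candidates: list[str],
    term_map: enrich.TermMap,
    manifest: Manifest,
    tag: str = "ora",
) -> pd.DataFrame:
    rows = enrich.ora_test(candidates, term_map)
    _save(rows, manifest.outdir / f"{tag}.tsv", manifest, tag)
    return rows


def run_all(cfg: PipelineConfig, term_map: Optional[enrich.TermMap] = None) -> dict:
    """Run every stage; the scan runs per population when two are present."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(cfg)
    gm = run_qc(cfg, manifest)
    div = run_diversity(cfg, gm, manifest)
    struct = run_structure(cfg, gm, manifest)
    populations = sorted({s.population for s in gm.samples if s.population})
    scans: dict[str, sweep.SweepResult] = {}
    if len(populations) >= 2:
        for pop in populations:
            scans[pop] = run_scan(cfg, gm, manifest, population=pop)
        shared = sweep.common_genes(*list(scans.values())[:2])
        pd.DataFrame({"gene_id": shared}).to_csv(
            outdir / "common_genes.tsv", sep="\t", index=False
        )
        manifest.record("common_genes", outdir / "common_genes.tsv", len(shared))
    else:
        scans["all"] = run_scan(cfg, gm, manifest)
    if term_map is not None:
        for tag, res in scans.items():
            run_enrich(cfg, res.gene_union, term_map, manifest, tag=f"ora_{tag}")
    manifest.write()
    return {"genotypes": gm, "diversity": div, "structure": struct,
            "scans": scans, "manifest": manifest}
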