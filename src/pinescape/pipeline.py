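"""End-to-end pipeline driver.

Chains the analysis stages — synthetic data (optional), genotype filtering,
diversity statistics, folded SFS, outlier scans, variance partition, niche
tests — writing each stage's tables plus a provenance log (seed, config
hash, per-stage parameters) into an output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .core import GenotypeMatrix
from .demography import project_folded_sfs
from .outliers import (OutlierRules, env_assoc_scan, pcadapt_scan,
                       neutral_panel, robust_outliers)
from .partition import (mito_constraint, pca_reduce, trend_surface,
                        forward_select, variance_partition)
from .popgen import (FilterSpec, diversity_summary, filter_loci,
                     haplotype_diversity, mask_genotypes, pop_allele_freqs,
                     wc_fst)
from .niche import dn_db_test, niche_axes, reports_frame
from .synthdata import SynthConfig, gen_im_dataset, gen_niche_points

log = logging.getLogger("pinescape")


@dataclass
class PipelineConfig:
    """Configuration of the pipeline driver."""

    outdir: str = "pinescape_out"
    seed: int = 0
    synth: SynthConfig | None = None      # None -> load inputs from data_dir
    data_dir: str | None = None
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    outlier_rules: OutlierRules = field(default_factory=OutlierRules)
    sfs_projection: int = 10              # haploid size per group
    exclude_singletons: bool = False
    n_perm: int = 999
    run_niche: bool = True
    stages: tuple[str, ...] = ("synth", "filter", "stats", "sfs", "scan",
                               "partition", "niche")

    def validate(self) -> None:
        if self.synth is None and self.data_dir is None:
            raise ValueError("either a synth config or a data_dir is required")
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValueError(f"data_dir does not exist: {self.data_dir}")


def _hash_config(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns a report bundle of key outputs.

    Each stage logs its seed and parameters and persists its outputs before
    the next stage starts, so a failure aborts with completed outputs on
    disk and the failing stage named.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = _hash_config(config)
    provenance = {"seed": config.seed, "config_hash": cfg_hash}
    report: dict = {"provenance": provenance}
    stage = "init"
    try:
        # ---- inputs
        stage = "synth"
        if config.synth is not None and "synth" in config.stages:
            t0 = time.time()
            bundle = gen_im_dataset(config.synth)
            pio.save_bundle(bundle, outdir / "synth")
            log.info("synth: seed=%s %.1fs", config.synth.seed, time.time() - t0)
        else:
            bundle = pio.load_bundle(config.data_dir)
        G = bundle.genotypes
        popmap = bundle.popmap
        groups = bundle.truth.get("group_labels", {})
        group_of_ind = ({i: groups[p] for i, p in popmap.items()}
                        if groups else None)

        # ---- filtering
        stage = "filter"
        if "filter" in config.stages:
            spec = config.filter_spec
            G = mask_genotypes(G, spec.gq_min, spec.dp_min) \
                if (G.gq is not None or G.depth is not None) else G
            G, rejections = filter_loci(G, spec, popmap)
            rejections.to_csv(outdir / "rejected_loci.csv", index=False)
            report["n_loci_retained"] = G.n_loci
            log.info("filter: %d loci retained", G.n_loci)

        # ---- diversity statistics
        stage = "stats"
        if "stats" in config.stages:
            stats_df = diversity_summary(G, popmap)
            mito_he = {}
            for pop in stats_df.index:
                haps = [h for i, h in bundle.mitotypes.items()
                        if popmap.get(i) == pop]
                counts = pd.Series(haps).value_counts().to_numpy()
                mito_he[pop] = (haplotype_diversity(counts)
                                if counts.sum() >= 2 else np.nan)
            stats_df["mitotype_he"] = pd.Series(mito_he)
            _, fst_multi, _ = wc_fst(G, popmap)
            stats_df.to_csv(outdir / "diversity.csv")
            report["diversity"] = stats_df
            report["fst_multilocus"] = fst_multi
            log.info("stats: multilocus FST=%.4f", fst_multi)

        # ---- folded SFS
        stage = "sfs"
        if "sfs" in config.stages and group_of_ind is not None:
            gmap = {i: group_of_ind[i] for i in G.individual_ids}
            n_groups = len(set(gmap.values()))
            sfs = project_folded_sfs(
                G, gmap, [config.sfs_projection] * n_groups)
            if config.exclude_singletons:
                sfs = sfs.without_singletons()
            sfs.save(outdir / "folded_sfs.txt")
            report["sfs"] = sfs
            log.info("sfs: %.0f SNPs in spectrum", sfs.n_snps)

        # ---- outlier scans
        stage = "scan"
        if "scan" in config.stages:
            pca_res = pcadapt_scan(G, fdr=config.outlier_rules.fdr)
            neutral_idx = neutral_panel(G, pca_res)
            freqs = pop_allele_freqs(G, popmap)
            freqs_neutral = pop_allele_freqs(G.take_loci(neutral_idx), popmap)
            env_res = env_assoc_scan(freqs, bundle.env,
                                     freqs_neutral=freqs_neutral,
                                     seed=config.seed)
            outset = robust_outliers(pca_res, env_res, config.outlier_rules)
            pd.DataFrame({
                "locus_id": G.locus_ids,
                "pca_stat": pca_res.stat,
                "pca_p": pca_res.pvalues,
                "pca_q": pca_res.qvalues,
                "bf_max": env_res.bf.max(axis=1).to_numpy(),
                "rho_absmax": env_res.rho.abs().max(axis=1).to_numpy(),
            }).to_csv(outdir / "scan_statistics.csv", index=False)
            if outset.attribution is not None:
                outset.attribution.to_csv(outdir / "outlier_attribution.csv",
                                          index=False)
            report["outliers"] = outset
            report["neutral_loci"] = [G.locus_ids[i] for i in neutral_idx]
            log.info("scan: %d pca, %d env, %d robust outliers (K=%d)",
                     len(outset.pca_loci), len(outset.env_loci),
                     len(outset.robust), pca_res.K)

        # ---- variance partition
        stage = "partition"
        if "partition" in config.stages:
            freqs = pop_allele_freqs(G, popmap)
            F = np.nan_to_num(freqs.freqs, nan=np.nanmean(freqs.freqs))
            env_cm, _ = pca_reduce(bundle.env, criterion="fixed", k=2)
            geo_cm = trend_surface(bundle.coords)
            geo_sel = forward_select(F, geo_cm, n_perm=config.n_perm,
                                     seed=config.seed)
            if geo_sel.data.shape[1] == 0:
                geo_sel = geo_cm  # nothing survived: report the full surface
            mito_cm = mito_constraint(bundle.mitotypes, popmap,
                                      freqs.populations)
            tables = {}
            snp_sets = {"all": None}
            if "outliers" in report:
                rob = report["outliers"].robust
                if len(rob) >= 2:
                    snp_sets["robust_outliers"] = [
                        i for i, l in enumerate(freqs.locus_ids) if l in rob]
                neut = set(report.get("neutral_loci", []))
                snp_sets["neutral"] = [
                    i for i, l in enumerate(freqs.locus_ids)
                    if l not in report["outliers"].pca_loci
                    and l not in report["outliers"].env_loci]
            for name, idx in snp_sets.items():
                Fsub = F if idx is None else F[:, idx]
                if Fsub.shape[1] < 2:
                    continue
                tab = variance_partition(Fsub, env_cm, geo_sel, mito_cm,
                                         n_perm=config.n_perm,
                                         seed=config.seed)
                tab.to_frame().to_csv(outdir / f"partition_{name}.csv")
                tables[name] = tab
            report["partition"] = tables
            log.info("partition: %s", {k: round(t.total_explained, 3)
                                       for k, t in tables.items()})

        # ---- niche
        stage = "niche"
        if config.run_niche and "niche" in config.stages:
            group_means = bundle.env.groupby(
                pd.Series({p: groups[p] for p in bundle.env.index})).mean()
            centers = {g: bundle.coords.loc[
                [p for p in bundle.coords.index if groups[p] == g]].mean().to_numpy()
                for g in group_means.index}
            samples, grids = gen_niche_points(centers, spread=1.0,
                                              seed=config.seed)
            axes = niche_axes(list(samples.values()))
            niche_tables = {}
            names = sorted(samples)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    reports = dn_db_test(samples[a], samples[b], axes,
                                         seed=config.seed)
                    df = reports_frame(reports)
                    df.to_csv(outdir / f"niche_{a}_vs_{b}.csv", index=False)
                    niche_tables[f"{a}_vs_{b}"] = df
            report["niche"] = niche_tables
            log.info("niche: %d pairwise tests", len(niche_tables))

        (outdir / "provenance.json").write_text(json.dumps(provenance) + "\n")
        return report
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
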