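"""End-to-end orchestration: Q-Q -> condFDR -> conjFDR -> loci -> concordance.

A :class:`RunConfig` (YAML-serializable) names the inputs and thresholds;
:func:`run_pipeline` executes every stage in the canonical order, writes
one TSV per stage plus a JSON manifest (inputs, version, seed, SNP counts
per stage), and is byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import gene_set_table, map_genes_positional, read_genes, read_gmt
from .fdr import (
    assign_condfdr,
    build_condfdr_grid,
    conjunctional_fdr,
    conjunctional_fdr_corrected,
)
from .ldsc import compute_ld_scores, estimate_rg
from .loci import (
    LocusThresholds,
    define_loci,
    effect_concordance,
    loci_to_bed,
    loci_to_frame,
    merge_unique_loci,
    overlap_loci,
)
from .qq import conditional_qq
from .simulate import LdPanel
from .sumstats import (
    DEFAULT_EXCLUSION_REGIONS,
    ExclusionRegion,
    SumStats,
    apply_exclusions,
    harmonize_pair,
    read_sumstats,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pairwise cross-trait analysis."""

    primary: str = ""
    conditional: str = ""
    label_primary: str = "A"
    label_conditional: str = "B"
    panel_sites: str | None = None
    panel_genotypes: str | None = None
    panel_ar1_r: float | None = None
    genes: str | None = None
    gene_sets: str | None = None
    column_map: dict | None = None
    fdr_threshold: float = 0.05
    candidate_threshold: float = 0.1
    r2_indep: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 250.0
    qq_thresholds: list = field(default_factory=lambda: [1.0, 0.1, 0.01, 0.001])
    gene_window_bp: int = 10_000
    exclusion_regions: list = field(
        default_factory=lambda: [
            dataclasses.asdict(r) for r in DEFAULT_EXCLUSION_REGIONS
        ]
    )
    prune_iters: int = 20
    r2_prune: float = 0.1
    min_stratum: int = 100
    run_rg: bool = True
    seed: int = 0
    outdir: str = "pleiocond_out"

    def __post_init__(self):
        for name, lo, hi in [
            ("fdr_threshold", 0, 1),
            ("candidate_threshold", 0, 1),
            ("r2_indep", 0, 1),
            ("r2_lead", 0, 1),
            ("r2_prune", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.merge_kb < 0 or self.gene_window_bp < 0:
            raise ValueError("distances must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def regions(self) -> tuple[ExclusionRegion, ...]:
        return tuple(ExclusionRegion(**r) for r in self.exclusion_regions)

    def locus_thresholds(self) -> LocusThresholds:
        return LocusThresholds(
            sig=self.fdr_threshold,
            cand=self.candidate_threshold,
            r2_indep=self.r2_indep,
            r2_lead=self.r2_lead,
            merge_kb=self.merge_kb,
        )


def read_panel(
    sites_path, genotypes_path=None, ar1_r: float | None = None
) -> LdPanel:
    """Load an LD panel from a sites TSV plus genotypes TSV or AR(1) model.

    The sites file has columns snp, chrom, pos, block_id; the optional
    genotype file is a TSV matrix (individuals x SNPs) whose header row
    matches the sites' SNP ids.
    """
    sites = pd.read_csv(sites_path, sep="\t", dtype={"chrom": str})
    genotypes = None
    if genotypes_path is not None:
        gdf = pd.read_csv(genotypes_path, sep="\t")
        if list(gdf.columns) != list(sites["snp"]):
            raise ValueError("genotype columns do not match panel sites")
        genotypes = gdf.to_numpy(np.int8)
    return LdPanel(
        snp=sites["snp"].to_numpy(),
        chrom=sites["chrom"].to_numpy(),
        pos=sites["pos"].to_numpy(),
        block_id=sites["block_id"].to_numpy(),
        genotypes=genotypes,
        ar1_r=ar1_r,
    )


def write_panel(panel: LdPanel, sites_path, genotypes_path=None) -> None:
    pd.DataFrame(
        {
            "snp": panel.snp,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "block_id": panel.block_id,
        }
    ).to_csv(sites_path, sep="\t", index=False)
    if genotypes_path is not None and panel.genotypes is not None:
        pd.DataFrame(panel.genotypes, columns=panel.snp).to_csv(
            genotypes_path, sep="\t", index=False
        )


def _grid_frame(grid) -> pd.DataFrame:
    return pd.DataFrame(grid.values, index=grid.nodes, columns=grid.nodes)


def run_pipeline(
    config: RunConfig,
    sumstats_pair: tuple[SumStats, SumStats] | None = None,
    panel: LdPanel | None = None,
) -> dict:
    """Execute the full pairwise analysis and write all stage outputs.

    ``sumstats_pair`` and ``panel`` may be passed in-memory (e.g. straight
    from the simulator); otherwise they are read from the paths in the
    config. Returns the manifest dictionary.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    la, lb = config.label_primary, config.label_conditional
    counts = {}

    if sumstats_pair is None:
        a = read_sumstats(config.primary, config.column_map, trait=la)
        b = read_sumstats(config.conditional, config.column_map, trait=lb)
    else:
        a, b = sumstats_pair
    counts["input"] = {la: len(a), lb: len(b)}

    a, b = harmonize_pair(a, b)
    counts["harmonized"] = len(a)
    regions = config.regions()
    a = apply_exclusions(a, regions)
    b = apply_exclusions(b, regions)
    counts["after_exclusions"] = len(a)

    if panel is None and config.panel_sites:
        panel = read_panel(
            config.panel_sites, config.panel_genotypes, config.panel_ar1_r
        )

    qq_ab = conditional_qq(a, b, config.qq_thresholds)
    qq_ba = conditional_qq(b, a, config.qq_thresholds)
    qq_ab.table.to_csv(out / f"qq_{la}_given_{lb}.tsv", sep="\t", index=False)
    qq_ba.table.to_csv(out / f"qq_{lb}_given_{la}.tsv", sep="\t", index=False)

    grid_kwargs = dict(
        min_stratum=config.min_stratum,
        panel=panel,
        prune_iters=config.prune_iters if panel is not None else 0,
        r2_prune=config.r2_prune,
    )
    grid_ab = build_condfdr_grid(a, b, seed=config.seed + 101, **grid_kwargs)
    grid_ba = build_condfdr_grid(b, a, seed=config.seed + 102, **grid_kwargs)
    cond_ab = assign_condfdr(grid_ab, a, b)
    cond_ba = assign_condfdr(grid_ba, b, a)
    # raw conjunction (max) for the per-SNP table; region-calibrated
    # conjunction for locus discovery
    conj = conjunctional_fdr(cond_ab, cond_ba)
    conj_cal = conjunctional_fdr_corrected(
        grid_ab,
        grid_ba,
        a,
        b,
        panel=panel,
        prune_iters=config.prune_iters if panel is not None else 0,
        r2_prune=config.r2_prune,
        seed=config.seed + 103,
    )
    _grid_frame(grid_ab).to_csv(out / f"grid_{la}_given_{lb}.tsv", sep="\t")
    _grid_frame(grid_ba).to_csv(out / f"grid_{lb}_given_{la}.tsv", sep="\t")

    persnp = a.df[["snp", "chrom", "pos"]].copy()
    persnp["p_" + la] = a.p
    persnp["p_" + lb] = b.p
    persnp["z_" + la] = a.z
    persnp["z_" + lb] = b.z
    persnp["condfdr_" + la] = cond_ab
    persnp["condfdr_" + lb] = cond_ba
    persnp["conjfdr"] = conj
    persnp["conjfdr_calibrated"] = conj_cal
    persnp["neglog10_conjfdr"] = -np.log10(conj_cal)
    persnp.to_csv(out / "persnp_fdr.tsv", sep="\t", index=False)

    manifest = {
        "package": "pleiocond",
        "version": "0.1.0",
        "config": dataclasses.asdict(config),
        "snp_counts": counts,
    }

    if panel is not None:
        th = config.locus_thresholds()
        loci_ab = define_loci(cond_ab, a, panel, th, f"cond_{la}|{lb}")
        loci_ba = define_loci(cond_ba, b, panel, th, f"cond_{lb}|{la}")
        loci_conj = define_loci(
            conj_cal, a, panel, th, f"conj_{la}&{lb}",
            tiebreak=np.maximum(a.p, b.p),
        )
        for name, lst in [
            (f"loci_cond_{la}", loci_ab),
            (f"loci_cond_{lb}", loci_ba),
            ("loci_conj", loci_conj),
        ]:
            loci_to_frame(lst).to_csv(out / f"{name}.tsv", sep="\t", index=False)
            loci_to_bed(lst, out / f"{name}.bed")
        unique = merge_unique_loci([loci_ab, loci_ba, loci_conj])
        loci_to_frame(unique).to_csv(out / "loci_unique.tsv", sep="\t", index=False)
        ov = overlap_loci(loci_ab, loci_ba)
        conc_table, frac, pct = effect_concordance(loci_conj, a, b)
        conc_table.to_csv(out / "concordance.tsv", sep="\t", index=False)
        manifest["loci"] = {
            f"cond_{la}": len(loci_ab),
            f"cond_{lb}": len(loci_ba),
            "conj_shared": len(loci_conj),
            "unique_across_analyses": len(unique),
            "cond_overlap_pairs": ov.n_shared,
        }
        manifest["concordance"] = {
            "fraction": None if np.isnan(frac) else frac,
            "percent": pct,
            "n_evaluable": int(
                (conc_table["status"] != "indeterminate").sum()
            )
            if len(conc_table)
            else 0,
        }

        if config.run_rg:
            scores = compute_ld_scores(panel)
            est = estimate_rg(a, b, scores)
            rg_row = dataclasses.asdict(est)
            pd.DataFrame([rg_row]).to_csv(out / "rg.tsv", sep="\t", index=False)
            manifest["rg"] = rg_row

        if config.genes:
            genes = read_genes(config.genes)
            cand_ids = sorted(
                {s for l in loci_conj for s in l.candidate_snps}
            )
            cand = SumStats(
                a.df[a.df["snp"].isin(cand_ids)], trait=la
            ) if cand_ids else None
            if cand is not None:
                mapping = map_genes_positional(cand, genes, config.gene_window_bp)
                mapping.to_csv(out / "gene_mapping.tsv", sep="\t", index=False)
                if config.gene_sets:
                    sets = read_gmt(config.gene_sets)
                    universe = {g.gene_id for g in genes}
                    tab = gene_set_table(
                        set(mapping["gene_id"]), sets, universe
                    )
                    tab.to_csv(out / "gene_sets.tsv", sep="\t", index=False)
                    manifest["gene_sets_significant"] = int(
                        tab["significant"].sum()
                    )
                manifest["genes_mapped"] = int(mapping["gene_id"].nunique())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
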