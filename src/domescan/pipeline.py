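"""End-to-end stage orchestration: scan, expression pipeline, benchmark.

Every tabular output starts with ``#``-prefixed provenance lines recording
the tool version, the parameters used and MD5 hashes of the inputs, so a
run can be reproduced from its artifacts alone.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import file_md5
from . import expression as expr
from . import popgen
from . import simulate as sim

logger = logging.getLogger(__name__)


def _provenance(params: dict, inputs: dict) -> str:
    lines = [f"# domescan {__version__}"]
    for k, v in params.items():
        lines.append(f"# param {k}={v}")
    for name, path in inputs.items():
        lines.append(f"# input {name}={path} md5={file_md5(path)}")
    return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_selection_scan(vcf, groups, out_dir, *, reference=None, gff=None,
                       window_size: int = 50_000, window_step: int = 25_000,
                       fst_top_q: float = 0.01, pi_low_q: float = 0.05,
                       plot_q: float = 0.05, estimator: str = "wc",
                       focal_group: str = "domestic",
                       other_group: str = "wild",
                       min_called: int = 4, min_snps: int = 10) -> dict:
    """Windowed pi/Fst scan: window TSV, region BED, allele-frequency TSV,
    and (when gene models + reference are given) a SNP-effect TSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(window_size=window_size, window_step=window_step,
                  fst_top_q=fst_top_q, pi_low_q=pi_low_q, plot_q=plot_q,
                  estimator=estimator, focal_group=focal_group,
                  other_group=other_group, min_called=min_called,
                  min_snps=min_snps)
    inputs = {"vcf": vcf, "groups": groups}
    if gff:
        inputs["gff"] = gff
    if reference:
        inputs["reference"] = reference
    header = _provenance(params, inputs)

    table = popgen.read_vcf(vcf)
    popspec = popgen.read_groups(groups)
    stats = popgen.scan_windows(
        table, popspec, focal_group=focal_group, other_group=other_group,
        window_size=window_size, window_step=window_step,
        estimator=estimator, min_called=min_called, min_snps=min_snps,
    )
    stats, cutoffs = popgen.flag_outlier_windows(
        stats, fst_top_q=fst_top_q, pi_low_q=pi_low_q, plot_q=plot_q
    )
    regions = popgen.call_signature_regions(stats, step=window_step)
    logger.info(
        "scan: %d windows, %d signature regions; skipped VCF records: %d; "
        "Fst top-%g cutoff %.4g, plot (top-%g) cutoff %.4g, pi low-%g cutoff %.4g",
        len(stats), len(regions), table.n_skipped,
        fst_top_q, cutoffs["fst_top_cutoff"],
        plot_q, cutoffs["fst_plot_cutoff"],
        pi_low_q, cutoffs["pi_low_cutoff"],
    )

    out_windows = stats.copy()
    out_windows["start"] += 1  # report 1-based inclusive
    _write_tsv(out_windows, out / "windows.tsv", header)

    with open(out / "regions.bed", "w") as fh:
        fh.write(header)
        for r in regions:
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t"
                     f"max_fst={r.max_fst:.4g};min_pi={r.min_focal_pi:.4g}\n")

    focal = popgen.group_samples(popspec, focal_group)
    other = popgen.group_samples(popspec, other_group)
    profiles = []
    for r in regions:
        for label, grp in ((focal_group, focal), (other_group, other)):
            prof = popgen.ref_allele_frequency_profile(
                table, grp, r.contig, r.start - 1, r.end
            )
            prof.insert(0, "group", label)
            profiles.append(prof)
    prof_df = (
        pd.concat(profiles, ignore_index=True) if profiles
        else pd.DataFrame(columns=["group", "contig", "position", "ref", "alt",
                                   "ref_allele_freq", "ref_hom_freq", "n_called"])
    )
    _write_tsv(prof_df, out / "allele_freq.tsv", header)

    result = dict(stats=stats, regions=regions, cutoffs=cutoffs,
                  allele_freq=prof_df)
    if gff and reference:
        genes = popgen.read_gff(gff)
        ref = popgen.read_reference(reference)
        effects, nonsyn = popgen.annotate_snp_effects(table, genes, ref)
        eff_df = pd.DataFrame(
            [dict(contig=e.contig, position=e.position, gene=e.gene_id or ".",
                  effect=e.effect_class, aa_change=e.aa_change or ".")
             for e in effects]
        )
        _write_tsv(eff_df, out / "snp_effects.tsv", header)
        result["effects"] = eff_df
        result["nonsyn_counts"] = nonsyn
    return result


def run_expression_pipeline(stats_a, out_dir, *, stats_b=None, fpkm=None,
                            terms=None, fpkm_min: float = 1.0,
                            q_max: float = 0.05,
                            min_abs_log2fc: float = 1.0,
                            background_samples=None) -> dict:
    """DEG calling, direction asymmetry, optional Venn + enrichment.

    ``stats_a`` (and optionally ``stats_b``) are per-gene stats TSVs with
    columns gene, log2fc, q.  Enrichment needs ``fpkm`` (for the expressed
    background) and ``terms`` (term->gene TSV).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(fpkm_min=fpkm_min, q_max=q_max,
                  min_abs_log2fc=min_abs_log2fc)
    inputs = {"stats_a": stats_a}
    if stats_b:
        inputs["stats_b"] = stats_b
    if fpkm:
        inputs["fpkm"] = fpkm
    if terms:
        inputs["terms"] = terms
    header = _provenance(params, inputs)

    def _load_stats(path):
        return pd.read_csv(path, sep="\t", comment="#")

    degs_a = expr.call_degs(_load_stats(stats_a), q_max, min_abs_log2fc)
    _write_tsv(degs_a, out / "degs_a.tsv", header)
    n_down = int((degs_a["direction"] == "down").sum())
    n_up = int((degs_a["direction"] == "up").sum())
    result = dict(degs_a=degs_a)
    if n_down + n_up:
        stat, p = expr.direction_asymmetry_test(n_down, n_up)
        result["asymmetry"] = dict(n_down=n_down, n_up=n_up,
                                   chi2=stat, p=p)
        logger.info("DEG set A: %d down vs %d up (chi2=%.4f, p=%.3g)",
                    n_down, n_up, stat, p)

    if stats_b:
        degs_b = expr.call_degs(_load_stats(stats_b), q_max, min_abs_log2fc)
        _write_tsv(degs_b, out / "degs_b.tsv", header)
        venn = expr.intersect_deg_sets(degs_a, degs_b)
        venn_df = pd.DataFrame(
            [dict(a_only=venn["a_only"], b_only=venn["b_only"],
                  both=venn["both"],
                  concordant=venn.get("concordant"),
                  discordant=venn.get("discordant"))]
        )
        _write_tsv(venn_df, out / "venn.tsv", header)
        result["degs_b"] = degs_b
        result["venn"] = venn

    if fpkm and terms:
        fpkm_df = pd.read_csv(fpkm, sep="\t", comment="#", index_col=0)
        background = expr.filter_expressed_background(
            fpkm_df, samples=background_samples, fpkm_min=fpkm_min
        )
        deg_genes = set(degs_a["gene"]) & background
        term_map = pd.read_csv(terms, sep="\t", comment="#")
        enr = expr.hypergeometric_enrichment(deg_genes, background, term_map)
        if not enr.empty:
            enr = enr.sort_values(["q", "p"]).reset_index(drop=True)
        _write_tsv(enr, out / "enrichment.tsv", header)
        result["enrichment"] = enr
        result["background_size"] = len(background)
    return result


def run_synthetic_benchmark(seeds, *, sweep_cfg: dict | None = None,
                            expr_cfg: dict | None = None) -> pd.DataFrame:
    """Per-seed recovery benchmark of the whole synthetic pipeline.

    For every seed: does the called signature region overlap the planted
    sweep; what fraction of genes is called DE under a null (no-DE)
    expression simulation; does the planted term attain the minimum q.
    Returns one row per seed plus aggregate rates available via ``mean()``.
    """
    rows = []
    for seed in seeds:
        cfg = sim.SweepSimConfig(seed=seed, **(sweep_cfg or {}))
        table, truth = sim.simulate_two_pop_variants(cfg)
        spec = sim.population_spec(cfg)
        stats = popgen.scan_windows(table, spec)
        stats, _ = popgen.flag_outlier_windows(stats)
        regions = popgen.call_signature_regions(stats, step=25_000)
        _, s0, s1 = truth.sweep
        overlap = any(
            r.contig == cfg.contig and r.start - 1 < s1 and r.end > s0
            for r in regions
        )

        null_cfg = sim.ExprSimConfig(seed=seed, de_fraction=0.0,
                                     **(expr_cfg or {}))
        _, null_stats, _ = sim.simulate_expression_table(null_cfg)
        null_rate = len(expr.call_degs(null_stats)) / null_cfg.n_genes

        de_cfg = sim.ExprSimConfig(seed=seed, **(expr_cfg or {}))
        fpkm, de_stats, de_truth = sim.simulate_expression_table(de_cfg)
        term_map = sim.simulate_term_annotation(
            fpkm.index, de_truth, seed=seed
        )
        background = set(fpkm.index)
        degs = expr.call_degs(de_stats)
        enr = expr.hypergeometric_enrichment(
            set(degs["gene"]) & background, background, term_map
        )
        top = (
            enr.sort_values(["q", "p"]).iloc[0]["term"]
            if not enr.empty else None
        )
        rows.append(dict(seed=seed, sweep_recovered=overlap,
                         null_deg_rate=null_rate,
                         planted_term_top=top == de_truth.enriched_term))
    return pd.DataFrame(rows)
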