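"""End-to-end orchestration and the headline report.

Runs the full chain — synthetic cohort (or user tables) -> guide filtering
and scoring -> mixture binarization -> paralogy annotation -> category
enrichment battery -> synthetic-lethality calling with follow-ups — and
collects the headline numbers in one JSON-serializable report. All
randomness flows from the single config seed, and a rerun with an identical
config produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import essentiality as ess
from . import guide_processing as gp
from . import paralog_annotation as pa
from . import stats_core as sc
from . import synthetic_data as sd
from . import synthetic_lethality as sl


@dataclass
class RunConfig:
    mode: str = "synthetic"  # synthetic | tables
    cohort: sd.CohortConfig = field(default_factory=sd.CohortConfig)
    with_genome: bool = False
    table_paths: dict = field(default_factory=dict)
    threshold_override: float | None = None
    fdr_level: float = 0.10
    sl_modes: tuple[str, ...] = ("closest", "all")
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables"):
            raise ValueError("mode must be 'synthetic' or 'tables'")
        if self.mode == "tables":
            required = {"scores", "expression", "paralogs"}
            missing = required - set(self.table_paths)
            if missing:
                raise ValueError(f"tables mode missing paths: {sorted(missing)}")


def percentage(numerator: float, denominator: float, digits: int = 1) -> float:
    """100*numerator/denominator, rounded half-up at ``digits`` decimals."""
    if denominator == 0:
        return math.nan
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-digits)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def or_from_proportions(p1: float, p2: float) -> float:
    """Odds ratio implied by two proportions."""
    if not (0 < p1 < 1 and 0 < p2 < 1):
        return math.nan
    return (p1 / (1 - p1)) / (p2 / (1 - p2))


def _genome_config_for(cohort: sd.CohortConfig) -> sd.GenomeConfig:
    # size the toy genome to hold the cohort's genes with room for guides
    gene_length = 400
    n_chrom = 2
    per_chrom = math.ceil(cohort.n_genes / n_chrom)
    length = max(per_chrom * (gene_length + 100) + 1000, 20_000)
    return sd.GenomeConfig(
        n_chromosomes=n_chrom,
        chromosome_length=length,
        n_genes=cohort.n_genes,
        gene_length=gene_length,
        n_duplicate_pairs=max(cohort.n_genes // 50, 1),
        duplication_mutation_rate=0.02,
    )


def _score_stage(config: RunConfig) -> dict:
    """Synthetic-mode inputs: cohort tables plus gene scores."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    stage: dict = {}
    if config.with_genome:
        gcfg = _genome_config_for(cohort_cfg)
        genome, genes_bed, dupmap = sd.generate_toy_genome(gcfg, seed=config.seed)
        guides, warnings_ = sd.generate_guide_library(
            genome, genes_bed, cohort_cfg.guides_per_gene, seed=config.seed
        )
        bundle = sd.generate_cohort(cohort_cfg, guide_table=guides, genome=genome)
        hit_lists = {
            rec.guide_id: gp.align_guide(rec.protospacer, genome)
            for rec in guides.itertuples()
        }
        gmap = gp.build_guide_gene_map(guides, hit_lists, genes_bed)
        retained_genes, dropped_genes = gp.gate_genes_by_guide_count(gmap)
        scores = gp.score_genes(bundle.lfc, gmap, retained_genes)
        stage.update(
            genome=genome, genes_bed=genes_bed, duplication_map=dupmap,
            guide_map=gmap, dropped_genes=dropped_genes,
            guide_warnings=warnings_,
        )
    else:
        bundle = sd.generate_cohort(cohort_cfg)
        by_gene = bundle.guide_map.set_index("sgRNA")["gene"]
        lfc = bundle.lfc.copy()
        lfc.index = by_gene.loc[lfc.index].to_numpy()
        scores = lfc.groupby(level=0).mean()
    stage.update(bundle=bundle, scores=scores)
    return stage


def _load_tables(paths: dict) -> dict:
    scores = pd.read_csv(paths["scores"], index_col=0)
    expression = pd.read_csv(paths["expression"], index_col=0)
    paralogs = pd.read_csv(paths["paralogs"])
    cn = (
        pd.read_csv(paths["copy_number"], index_col=0)
        if "copy_number" in paths
        else pd.DataFrame()
    )
    mutations = (
        pd.read_csv(paths["mutations"])
        if "mutations" in paths
        else pd.DataFrame(columns=["gene", "cell_line", "Variant_Classification"])
    )
    complexes = (
        pd.read_csv(paths["complexes"])
        if "complexes" in paths
        else pd.DataFrame(columns=["complex_id", "gene"])
    )
    return dict(
        scores=scores, expression=expression, paralogs=paralogs,
        copy_number=cn, mutations=mutations, complexes=complexes,
    )


def _category_battery(summaries: pd.DataFrame, gene_summary: pd.DataFrame) -> dict:
    """Fig 2-4 style enrichments: paralogy vs essentiality category."""
    merged = summaries.merge(gene_summary, on="gene", how="left")
    merged["is_paralog"] = merged["n_paralogs"].fillna(0) > 0
    out: dict = {}

    def safe_or(flag_a: pd.Series, flag_b: pd.Series) -> dict:
        t = sc.ContingencyTable2x2(
            a=int((flag_a & flag_b).sum()), b=int((flag_a & ~flag_b).sum()),
            c=int((~flag_a & flag_b).sum()), d=int((~flag_a & ~flag_b).sum()),
        )
        res = sc.fisher_exact_or(t)
        return {"or": res.statistic, "p": res.p_value}

    never = merged["category"] == "never"
    broadly = merged["category"] == "broadly"
    out["never_vs_paralog"] = safe_or(never, merged["is_paralog"])
    out["broadly_vs_singleton"] = safe_or(broadly, ~merged["is_paralog"])

    # paralog-count bins x category
    ct = pd.crosstab(merged["paralog_bin"].fillna("0"), merged["category"])
    try:
        out["paralog_bins_vs_category_chi2"] = {
            "chi2": sc.chi_squared(ct.to_numpy()).statistic,
            "p": sc.chi_squared(ct.to_numpy()).p_value,
        }
    except ValueError:
        out["paralog_bins_vs_category_chi2"] = {"chi2": math.nan, "p": math.nan}

    # closest-paralog identity by category (paralogs only)
    with_id = merged.dropna(subset=["max_identity"])
    ids = {
        cat: with_id.loc[with_id["category"] == cat, "max_identity"].to_numpy()
        for cat in ("never", "sometimes", "broadly")
    }
    if len(ids["broadly"]) >= 1 and len(ids["sometimes"]) >= 1:
        res = sc.mann_whitney_u(
            ids["broadly"], np.concatenate([ids["never"], ids["sometimes"]])
        )
        out["identity_broadly_vs_rest_mwu"] = {
            "U": res.statistic, "p": res.p_value,
            "median_broadly": float(np.median(ids["broadly"])) if len(ids["broadly"]) else math.nan,
            "median_rest": float(np.median(np.concatenate([ids["never"], ids["sometimes"]]))),
        }

    # WGD vs SSD category odds ratios (gene-level duplication mode)
    wgd = merged["duplication_mode"] == "WGD"
    ssd = merged["duplication_mode"] == "SSD"
    dup = merged[wgd | ssd]
    if len(dup):
        for cat in ("never", "sometimes", "broadly"):
            out[f"wgd_vs_ssd_{cat}"] = safe_or(
                dup["category"] == cat, dup["duplication_mode"] == "WGD"
            )
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return {report, artifacts}."""
    artifacts: dict = {}
    if config.mode == "synthetic":
        stage = _score_stage(config)
        bundle: sd.CohortBundle = stage["bundle"]
        scores = stage["scores"]
        expression = bundle.expression
        copy_number = bundle.copy_number
        mutations = bundle.mutations
        raw_pairs = bundle.paralogs
        complexes = bundle.complexes
        artifacts.update(stage)
    else:
        tables = _load_tables(config.table_paths)
        scores = tables["scores"]
        expression = tables["expression"]
        copy_number = tables["copy_number"]
        mutations = tables["mutations"]
        raw_pairs = tables["paralogs"]
        complexes = tables["complexes"]
        artifacts.update(tables)

    # ---- binarization
    fit_meta: dict = {}
    if config.threshold_override is not None:
        tau = float(config.threshold_override)
        fit_meta["threshold_source"] = "override"
    else:
        fit = ess.fit_score_mixture(
            scores.to_numpy(), seed=config.seed, n_restarts=5
        )
        tau = ess.essentiality_threshold(fit)
        fit_meta = {
            "threshold_source": "mixture boundary",
            "k": fit.k,
            "means": fit.means,
            "weights": fit.weights,
            "sds": fit.sds,
            "aic": fit.aic,
            "boundary_rule": fit.boundary_rule,
        }
        artifacts["mixture_fit"] = fit
    binary = ess.binarize(scores, tau)
    summary = ess.summarize_genes(binary)
    summaries = summary["genes"]
    artifacts.update(binary=binary, gene_summaries=summaries, tau=tau)

    # ---- paralog annotation
    coding = set(scores.index) | set(raw_pairs["A1"]) | set(raw_pairs["A2"])
    filtered, removed = pa.filter_paralog_pairs(raw_pairs, coding)
    wgd_pairs = [
        (r.A1, r.A2) for r in filtered.itertuples()
        if getattr(r, "wgd_flag", False)
    ]
    annotated, gene_modes = pa.classify_duplication(filtered, wgd_pairs)
    annotated = pa.annotate_complexes(annotated, complexes)
    gene_summary = pa.summarize_all_genes(
        sorted(set(scores.index)), annotated, gene_modes
    )
    artifacts.update(pair_table=annotated, paralogy=gene_summary,
                     pair_filter_removed=removed)

    # ---- category battery
    battery = _category_battery(summaries, gene_summary)

    # ---- complex enrichment of broadly essential genes
    complexes_map = {
        cid: set(g["gene"]) for cid, g in complexes.groupby("complex_id")
    } if len(complexes) else {}
    broadly_genes = set(summaries.loc[summaries["category"] == "broadly", "gene"])
    background = set(summaries["gene"])
    enrichment_table = (
        sc.complex_enrichment(broadly_genes, background, complexes_map)
        if complexes_map and broadly_genes
        else pd.DataFrame()
    )
    artifacts["broadly_complex_enrichment"] = enrichment_table

    # ---- synthetic lethality per mode
    expressed = set(expression.index)
    sl_reports: dict = {}
    for mode in config.sl_modes:
        testable, n_no_expr = sl.select_testable_pairs(
            summaries, annotated, expressed, mode=mode
        )
        results = []
        for row in testable.itertuples():
            if row.A1 not in binary.index:
                continue
            res = sl.sl_expression_test(
                row.A1, row.A2, binary.loc[row.A1], expression.loc[row.A2],
                is_closest=bool(row.is_closest_pair),
            )
            if res is not None:
                results.append(res)
        if not results:
            sl_reports[mode] = {"n_tested": 0, "n_flagged": 0}
            continue
        calls = sl.call_sl(results, fdr_level=config.fdr_level)
        if len(copy_number):
            calls = sl.cn_followup(calls, copy_number, binary)
        calls, n_excl = sl.nonsense_followup(calls, mutations, binary)
        ann = calls.merge(
            annotated[
                ["A1", "A2", "identity_A1_in_A2", "identity_A2_in_A1",
                 "duplication_mode", "either_in_complex", "same_complex"]
            ],
            on=["A1", "A2"], how="left",
        )
        # unordered pairs: fill the reversed-direction annotation rows
        rev = calls.merge(
            annotated.rename(columns={
                "A1": "A2", "A2": "A1",
                "identity_A1_in_A2": "identity_A2_in_A1",
                "identity_A2_in_A1": "identity_A1_in_A2",
            })[
                ["A1", "A2", "identity_A1_in_A2", "identity_A2_in_A1",
                 "duplication_mode", "either_in_complex", "same_complex"]
            ],
            on=["A1", "A2"], how="left",
        )
        for col in ("identity_A1_in_A2", "identity_A2_in_A1",
                    "duplication_mode", "either_in_complex", "same_complex"):
            ann[col] = ann[col].where(ann[col].notna(), rev[col])
        ann = ann.dropna(subset=["duplication_mode"])
        enr = sl.sl_enrichment(ann) if len(ann) else {}
        flagged = calls[calls["is_putative_SL"]]
        sl_reports[mode] = {
            "n_tested": int(len(calls)),
            "n_flagged": int(len(flagged)),
            "n_unique_A1_tested": int(calls["A1"].nunique()),
            "n_unique_A1_flagged": int(flagged["A1"].nunique()),
            "pct_pairs_flagged": percentage(len(flagged), len(calls)),
            "pct_unique_A1_flagged": percentage(
                flagged["A1"].nunique(), calls["A1"].nunique()
            ),
            "n_cn_driven": int(calls["cn_driven"].sum()),
            "n_nonsense_driven": int(calls["nonsense_driven"].sum()),
            "n_cn_or_nonsense": int(
                (calls["cn_driven"] | calls["nonsense_driven"]).sum()
            ),
            "n_A1_without_expressed_paralog": n_no_expr,
            "n_excluded_nonsense_followup": n_excl,
            "enrichment": enr,
        }
        artifacts[f"sl_calls_{mode}"] = calls
        artifacts[f"sl_annotated_{mode}"] = ann

    # ---- headline report
    counts = summaries["category"].value_counts().to_dict()
    n_genes = int(len(summaries))
    is_paralog = gene_summary["n_paralogs"] > 0
    report = {
        "n_genes": n_genes,
        "n_cell_lines": int(binary.shape[1]),
        "threshold": tau,
        "fit": fit_meta,
        "category_counts": {
            c: int(counts.get(c, 0)) for c in ("never", "sometimes", "broadly")
        },
        "category_percentages": {
            c: percentage(counts.get(c, 0), n_genes)
            for c in ("never", "sometimes", "broadly")
        },
        "n_paralog_genes": int(is_paralog.sum()),
        "n_singleton_genes": int((~is_paralog).sum()),
        "pct_paralog_genes": percentage(int(is_paralog.sum()), len(gene_summary)),
        "median_essential_per_line": summary["median_essential_per_line"],
        "decile_bins": {
            str(interval): int(count)
            for interval, count in summary["decile_bins"].items()
        },
        "category_battery": battery,
        "synthetic_lethality": sl_reports,
        "pair_filter_removed": removed,
        "fdr_level": config.fdr_level,
        "seed": config.seed,
    }

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scores.to_csv(outdir / "gene_scores.csv")
        binary.to_csv(outdir / "binary_essentiality.csv")
        summaries.to_csv(outdir / "gene_summaries.csv", index=False)
        annotated.to_csv(outdir / "pair_table.csv", index=False)
        for mode in config.sl_modes:
            key = f"sl_calls_{mode}"
            if key in artifacts:
                artifacts[key].to_csv(outdir / f"{key}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float)
        )

    return {"report": report, "artifacts": artifacts}
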