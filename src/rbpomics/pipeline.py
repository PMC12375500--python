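"""End-to-end orchestration: simulate -> dbp -> de -> prot -> cetsa -> integrate.

Stages communicate only through files, so any stage can be re-run from the
cached outputs of the previous ones.  A JSON run report records thresholds,
seeds and the headline summary counts of each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import binding, expression, integration, iolib, meltcurve, proteomics
from .synthdata import SimConfig, write_fixture

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("rbpomics")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "rbpomics_out"
    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None  # where stage inputs live if not simulating
    # binding thresholds
    p_max: float = 0.05
    delta_min: float = 0.5
    enrich_log2_min: float = 3.0
    peak_p_max: float = 0.001
    pseudocount: float = 1.0
    epsilon: float = 0.1
    # expression
    padj_max: float = 0.05
    # proteomics
    q_max: float = 0.05
    s0: float = 0.0
    n_permutations: int = 250
    # integration
    fdr_max: float = 0.05
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        for name in ("p_max", "peak_p_max", "padj_max", "q_max", "fdr_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.delta_min < 0 or self.epsilon < 0 or self.pseudocount < 0:
            raise ValueError("delta_min, epsilon and pseudocount must be >= 0")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serialisable run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package": "rbpomics",
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "p_max", "delta_min", "enrich_log2_min", "peak_p_max",
                "pseudocount", "epsilon", "padj_max", "q_max", "fdr_max",
            )
        },
        "stages": {},
    }

    if config.simulate:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        in_dir = out / "inputs"
        _stage("simulate")(write_fixture)(in_dir, sim_cfg)
        report["stages"]["simulate"] = {"dir": str(in_dir)}
    else:
        if not config.input_dir:
            raise PipelineError("stage 'inputs' failed: no input_dir and simulate=False")
        in_dir = Path(config.input_dir)
    for required in ("clusters.bed", "eclip_counts.tsv", "eclip_design.tsv"):
        if not (in_dir / required).exists():
            raise PipelineError(f"stage 'inputs' failed: missing {in_dir / required}")

    report["stages"]["dbp"] = _stage("dbp")(_run_dbp)(config, in_dir, out)
    report["stages"]["de"] = _stage("de")(_run_de)(config, in_dir, out)
    report["stages"]["prot"] = _stage("prot")(_run_prot)(config, in_dir, out)
    report["stages"]["cetsa"] = _stage("cetsa")(_run_cetsa)(config, in_dir, out)
    report["stages"]["integrate"] = _stage("integrate")(_run_integrate)(config, out)

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_dbp(config: PipelineConfig, in_dir: Path, out: Path) -> dict:
    clusters = iolib.read_bed(in_dir / "clusters.bed")
    counts, design = iolib.read_count_matrix(
        in_dir / "eclip_counts.tsv", in_dir / "eclip_design.tsv"
    )
    annotation = iolib.read_annotation(in_dir / "annotation.tsv")
    clusters = binding.annotate_regions(clusters, annotation)
    gene_of = {c.cluster_id: c.gene_id for c in clusters}

    bound: dict[str, set[str]] = {}
    sig_ids: dict[str, list[str]] = {}
    for treatment in ("untreated", "treated"):
        calls = binding.call_significant_peaks(
            counts, design,
            enrich_log2_min=config.enrich_log2_min,
            p_max=config.peak_p_max,
            pseudocount=config.pseudocount,
            treatment=treatment,
        )
        sig_ids[treatment] = [c.cluster_id for c in calls if c.significant]
        bound[treatment] = {
            gene_of[c] for c in sig_ids[treatment] if gene_of.get(c)
        }
    ov = binding.overlap_summary(bound["untreated"], bound["treated"])
    dist = binding.region_distribution(clusters, sig_ids["untreated"])

    rpm = binding.rpm_normalize(counts, design)
    dbps = binding.call_dbps(
        rpm, design, p_max=config.p_max, delta_min=config.delta_min,
        epsilon=config.epsilon,
    )
    summaries = binding.aggregate_genes(dbps, clusters)

    iolib.write_tsv(binding.dbp_table(dbps), out / "dbp_results.tsv")
    iolib.write_tsv(binding.gene_summary_table(summaries), out / "gene_summary.tsv")
    iolib.write_tsv(
        pd.DataFrame([{
            "n_shared": ov.n_shared, "n_lost": ov.n_lost, "n_new": ov.n_new,
            "shared_pct_of_untreated": ov.shared_fraction_of_untreated,
        }]),
        out / "overlap_summary.tsv",
    )
    iolib.write_tsv(
        pd.DataFrame(sorted(dist.items()), columns=["region", "proportion"]),
        out / "region_distribution.tsv",
    )
    n_up = sum(1 for d in dbps if d.direction == "up")
    n_down = sum(1 for d in dbps if d.direction == "down")
    return {
        "n_significant_peaks_untreated": len(sig_ids["untreated"]),
        "n_significant_peaks_treated": len(sig_ids["treated"]),
        "n_dbps_up": n_up,
        "n_dbps_down": n_down,
        "n_genes_with_dbps": len(summaries),
        "overlap": {"shared": ov.n_shared, "lost": ov.n_lost, "new": ov.n_new},
    }


def _run_de(config: PipelineConfig, in_dir: Path, out: Path) -> dict:
    counts, _ = _read_rna(in_dir)
    groups = _read_groups(in_dir)
    counts = expression.prefilter_low_counts(counts)
    records = expression.de_test(counts, groups, padj_max=config.padj_max)
    iolib.write_tsv(expression.deg_table(records), out / "deg_table.tsv")
    n_sig = sum(r.passes_filter for r in records)
    return {"n_genes_tested": len(records), "n_degs": int(n_sig)}


def _read_rna(in_dir: Path):
    df = iolib.read_tsv(in_dir / "rnaseq_counts.tsv", index_col=0)
    cm = iolib.CountMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns],
        df.to_numpy().astype("int64"),
    )
    return cm, df


def _read_groups(in_dir: Path) -> dict[str, str]:
    gdf = iolib.read_tsv(in_dir / "rnaseq_groups.tsv")
    return dict(zip(gdf["sample_id"], gdf["group"]))


def _run_prot(config: PipelineConfig, in_dir: Path, out: Path) -> dict:
    table = iolib.read_tsv(in_dir / "proteomics.tsv")
    g1 = [c for c in table.columns if c.startswith("lfq_treated_")]
    g2 = [c for c in table.columns if c.startswith("lfq_control_")]
    filtered = proteomics.filter_lfq(table, g1, g2)
    stats_table = proteomics.perm_t_test(
        filtered, g1, g2,
        proteomics.PermTestConfig(
            n_permutations=config.n_permutations, s0=config.s0, seed=config.seed,
            q_max=config.q_max,
        ),
    )
    n_down, n_up, _ = proteomics.summarize_hits(stats_table, q_max=config.q_max)
    iolib.write_tsv(stats_table, out / "protein_stats.tsv")
    return {
        "n_quantified": len(table),
        "n_after_filter": len(filtered),
        "n_proteins_down": n_down,
        "n_proteins_up": n_up,
    }


def _run_cetsa(config: PipelineConfig, in_dir: Path, out: Path) -> dict:
    df = iolib.read_melt_csv(in_dir / "meltcurves.csv")
    fits = meltcurve.fit_melt_table(df)
    rows = [
        {
            "condition": cond, "replicate": rep, "tm": fit.tm,
            "tm_ci_low": fit.tm_ci[0], "tm_ci_high": fit.tm_ci[1],
            "top": fit.top, "bottom": fit.bottom, "slope": fit.slope,
            "r2": fit.r2,
        }
        for cond, rep, fit in fits
    ]
    iolib.write_tsv(pd.DataFrame(rows), out / "melt_fits.tsv")

    conditions = sorted({cond for cond, _, _ in fits})
    # the vehicle arm, when recognisable, is the baseline (condition_a)
    vehicle_names = ("vehicle", "dmso", "control", "untreated")
    conditions.sort(key=lambda c: (c.lower() not in vehicle_names, c))
    comparison: dict = {}
    if len(conditions) == 2:
        a = [f for c, _, f in fits if c == conditions[0]]
        b = [f for c, _, f in fits if c == conditions[1]]
        delta, overlap, stab = meltcurve.compare_tm(a[0], b[0])
        comparison = {
            "condition_a": conditions[0], "condition_b": conditions[1],
            "delta_tm_first_replicate": delta,
            "ci_overlap": overlap, "stabilized": stab,
        }
        iolib.write_tsv(pd.DataFrame([comparison]), out / "melt_comparison.tsv")
    return {"n_fits": len(fits), **comparison}


def _run_integrate(config: PipelineConfig, out: Path) -> dict:
    gene_df = iolib.read_tsv(out / "gene_summary.tsv")
    summaries = [
        binding.GeneBindingSummary(
            r.gene_id, int(r.n_dbps), int(r.n_up), int(r.n_down),
            r.direction_class, float(r.mean_delta_lfc),
        )
        for r in gene_df.itertuples()
    ]
    deg_df = iolib.read_tsv(out / "deg_table.tsv")
    records = [
        expression.DegRecord(
            r.gene_id, float(r.baseMean), float(r.log2fc), float(r.p),
            float(r.padj), bool(r.passes_filter),
        )
        for r in deg_df.itertuples()
    ]
    prot_path = out / "protein_stats.tsv"
    prot = iolib.read_tsv(prot_path) if prot_path.exists() else None
    merged = integration.merge_omics(summaries, records, prot,
                                     protein_q_max=config.q_max)
    iolib.write_tsv(merged, out / "integration_table.tsv")
    result = {"n_genes_merged": len(merged)}
    try:
        conc = integration.concordance_stats(merged)
    except ValueError as exc:
        result["concordance"] = {"error": str(exc)}
    else:
        result["concordance"] = {
            "quadrants": conc.quadrant_table.tolist(),
            "chi2": conc.chi2, "chi2_p": conc.chi2_p, "mw_p": conc.mw_p,
            "n_concordant": conc.n_concordant,
            "n_discordant": conc.n_discordant,
        }
        iolib.write_tsv(
            pd.DataFrame([{
                "chi2": conc.chi2, "chi2_p": conc.chi2_p, "mw_p": conc.mw_p,
                "n_concordant": conc.n_concordant,
                "n_discordant": conc.n_discordant,
            }]),
            out / "concordance.tsv",
        )
    return result
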