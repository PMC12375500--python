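"""eCLIP differential-binding analysis.

The workflow mirrors standard input-normalised eCLIP processing followed by
a differential step between treated and untreated conditions:

1. RPM-normalise cluster read counts (reads / library size x 1e6).
2. Call significant peaks per condition against the size-matched input
   (SMInput) with an exact one-sided 2x2 test and a log2-enrichment cutoff.
3. Assign each cluster to the gene and transcript region (5'UTR / CDS /
   3'UTR / intron) with maximal overlap.
4. For each cluster, test the assay x treatment interaction with a classical
   two-way fixed-effects ANOVA on RPM values, compute the IP-vs-input log2
   fold change per treatment arm and their difference (dLFC), and call
   differentially bound peaks (DBPs) at interaction p < 0.05 and
   |dLFC| > 0.5.
5. Aggregate DBPs per gene and summarise direction coordination and
   bound-gene overlap between conditions.

The interaction ANOVA is computed on raw RPM values (not log-RPM) by
default; pass ``log=True`` to test on log2(RPM + epsilon) instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iolib import (
    ClusterRecord,
    CountMatrix,
    GeneAnnotation,
    SampleDesign,
)

__all__ = [
    "PeakCall",
    "DbpResult",
    "GeneBindingSummary",
    "OverlapSummary",
    "CoordinationStats",
    "rpm_normalize",
    "call_significant_peaks",
    "annotate_regions",
    "region_distribution",
    "dbp_anova",
    "dbp_effect",
    "call_dbps",
    "aggregate_genes",
    "coordination_stats",
    "overlap_summary",
    "dbp_table",
    "gene_summary_table",
]

# Region precedence used only to break exact overlap-length ties.
_REGION_ORDER = ("3UTR", "5UTR", "CDS", "intron", "other")


@dataclass(frozen=True)
class PeakCall:
    cluster_id: str
    log2_enrichment: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class DbpResult:
    cluster_id: str
    p_interaction: float
    lfc_treated: float
    lfc_untreated: float
    delta_lfc: float
    direction: str  # "up", "down" or "none"


@dataclass(frozen=True)
class GeneBindingSummary:
    gene_id: str
    n_dbps: int
    n_up: int
    n_down: int
    direction_class: str  # "up", "down" or "mixed"
    mean_delta_lfc: float


@dataclass(frozen=True)
class OverlapSummary:
    n_shared: int
    n_lost: int
    n_new: int
    shared_fraction_of_untreated: float  # percent


@dataclass(frozen=True)
class CoordinationStats:
    n_genes: int
    n_multi: int
    n_coordinated: int
    n_mixed: int
    pct_coordinated_of_multi: float
    pct_mixed_of_all: float


# ---------------------------------------------------------------------------
# Normalisation


def rpm_normalize(
    counts: CountMatrix, design: Sequence[SampleDesign]
) -> CountMatrix:
    """Reads-per-million normalisation: count / library_size x 1e6."""
    by_id = {d.sample_id: d for d in design}
    missing = [c for c in counts.col_ids if c not in by_id]
    if missing:
        raise ValueError(f"no library size for samples: {missing}")
    libs = np.array([by_id[c].library_size for c in counts.col_ids], dtype=float)
    rpm = counts.values / libs[None, :] * 1e6
    return CountMatrix(list(counts.row_ids), list(counts.col_ids), rpm)


# ---------------------------------------------------------------------------
# Input-normalised peak significance


def call_significant_peaks(
    counts: CountMatrix,
    design: Sequence[SampleDesign],
    enrich_log2_min: float = 3.0,
    p_max: float = 0.001,
    pseudocount: float = 1.0,
    treatment: str | None = None,
) -> list[PeakCall]:
    """Call clusters enriched in IP over the size-matched input.

    Reads are pooled across the IP libraries and across the input libraries
    (optionally restricted to one ``treatment`` arm).  Per cluster,

    ``log2_enrichment = log2(((ip + pc) / ip_lib) / ((inp + pc) / inp_lib))``

    and the p-value is the one-sided exact (hypergeometric / Fisher) tail of
    the 2x2 table of in-peak vs out-of-peak reads in IP vs input.  A cluster
    is significant when ``log2_enrichment >= enrich_log2_min`` and
    ``p <= p_max``.
    """
    sel = [d for d in design if treatment is None or d.treatment == treatment]
    ip_cols = [d.sample_id for d in sel if d.assay == "IP"]
    in_cols = [d.sample_id for d in sel if d.assay == "input"]
    if not ip_cols or not in_cols:
        raise ValueError("need at least one IP and one input sample")
    by_id = {d.sample_id: d for d in sel}
    df = counts.to_frame()
    ip = df[ip_cols].sum(axis=1).to_numpy(dtype=np.int64)
    inp = df[in_cols].sum(axis=1).to_numpy(dtype=np.int64)
    ip_lib = int(sum(by_id[c].library_size for c in ip_cols))
    in_lib = int(sum(by_id[c].library_size for c in in_cols))
    if (ip > ip_lib).any() or (inp > in_lib).any():
        raise ValueError("peak read counts exceed library totals")

    enr = np.log2(((ip + pseudocount) / ip_lib) / ((inp + pseudocount) / in_lib))
    # One-sided enrichment p: P(X >= ip) for X ~ Hypergeom(N, K, n) with
    # N = both libraries, K = total in-peak reads, n = IP library size.
    p = stats.hypergeom.sf(ip - 1, ip_lib + in_lib, ip + inp, ip_lib)
    sig = (enr >= enrich_log2_min) & (p <= p_max)
    return [
        PeakCall(cid, float(e), float(pv), bool(s))
        for cid, e, pv, s in zip(counts.row_ids, enr, p, sig)
    ]


# ---------------------------------------------------------------------------
# Region annotation


def annotate_regions(
    clusters: Sequence[ClusterRecord],
    annotation: Sequence[GeneAnnotation],
) -> list[ClusterRecord]:
    """Assign each cluster to the gene, then region, with maximal overlap.

    A cluster with no overlapping gene feature (including clusters on
    chromosomes absent from the annotation) is intergenic.  Equal-overlap
    gene ties go to the lexicographically smallest gene id; equal-overlap
    region ties within a gene follow a fixed precedence (3'UTR first).
    """
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        for feat in gene.features:
            iv = feat.interval
            trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, (gene.gene_id, feat.region, iv.strand)
            )

    out: list[ClusterRecord] = []
    for rec in clusters:
        iv = rec.interval
        tree = trees.get(iv.chrom)
        gene_overlap: dict[str, int] = {}
        region_overlap: dict[tuple[str, str], int] = {}
        if tree is not None:
            for hit in tree.overlap(iv.start, iv.end):
                gene_id, region, strand = hit.data
                if "." not in (strand, iv.strand) and strand != iv.strand:
                    continue
                ol = min(iv.end, hit.end) - max(iv.start, hit.begin)
                gene_overlap[gene_id] = gene_overlap.get(gene_id, 0) + ol
                key = (gene_id, region)
                region_overlap[key] = region_overlap.get(key, 0) + ol
        if not gene_overlap:
            out.append(
                ClusterRecord(iv, rec.cluster_id, "", "intergenic",
                              rec.score, rec.extra)
            )
            continue
        best_gene = min(gene_overlap, key=lambda g: (-gene_overlap[g], g))
        best_region = min(
            (r for (g, r) in region_overlap if g == best_gene),
            key=lambda r: (
                -region_overlap[(best_gene, r)],
                _REGION_ORDER.index(r) if r in _REGION_ORDER else len(_REGION_ORDER),
            ),
        )
        out.append(
            ClusterRecord(iv, rec.cluster_id, best_gene, best_region,
                          rec.score, rec.extra)
        )
    return out


def region_distribution(
    clusters: Sequence[ClusterRecord],
    cluster_ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Proportion of clusters per region (optionally restricted to a subset).

    Proportions sum to 1 over the region categories present.
    """
    if cluster_ids is not None:
        wanted = set(cluster_ids)
        clusters = [c for c in clusters if c.cluster_id in wanted]
    if not clusters:
        raise ValueError("no clusters to summarise")
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.region] = counts.get(c.region, 0) + 1
    n = len(clusters)
    return {region: counts[region] / n for region in sorted(counts)}


# ---------------------------------------------------------------------------
# Differential binding (two-way ANOVA + dLFC)


def _cell_columns(
    col_ids: Sequence[str], design: Sequence[SampleDesign]
) -> dict[tuple[str, str], list[int]]:
    by_id = {d.sample_id: d for d in design}
    cells: dict[tuple[str, str], list[int]] = {
        (a, t): [] for a in ("IP", "input") for t in ("treated", "untreated")
    }
    for j, c in enumerate(col_ids):
        if c not in by_id:
            raise ValueError(f"sample {c!r} missing from design")
        d = by_id[c]
        cells[(d.assay, d.treatment)].append(j)
    for key, idx in cells.items():
        if not idx:
            raise ValueError(f"empty design cell {key}")
    return cells


def dbp_anova(
    rpm: CountMatrix,
    design: Sequence[SampleDesign],
    log: bool = False,
    epsilon: float = 0.1,
) -> np.ndarray:
    """Per-cluster interaction p-value from a two-way fixed-effects ANOVA.

    Factors are assay (IP/input) and treatment; the returned p-value is for
    the interaction term.  Computed as a model-comparison F between the
    additive model and the full cell-means model, which reduces to the
    classical two-way ANOVA interaction test in the balanced case and
    remains well-defined for unbalanced replication.

    Clusters with zero residual variance and zero interaction sum of squares
    (e.g. all values identical) get p = 1 by convention; zero residual
    variance with a non-zero interaction effect gives p = 0.
    """
    cells = _cell_columns(rpm.col_ids, design)
    for key, idx in cells.items():
        if len(idx) < 2:
            raise ValueError(f"need >=2 replicates per cell, cell {key} has {len(idx)}")
    y = np.asarray(rpm.values, dtype=float)
    if log:
        y = np.log2(y + epsilon)
    n_total = y.shape[1]
    df_err = n_total - 4

    # Residual SS of the full (cell-means) model: within-cell deviations.
    rss_full = np.zeros(y.shape[0])
    for idx in cells.values():
        block = y[:, idx]
        rss_full += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

    # Residual SS of the additive model via a common projection matrix.
    assay_ind = np.zeros(n_total)
    treat_ind = np.zeros(n_total)
    for (assay, treat), idx in cells.items():
        if assay == "IP":
            assay_ind[idx] = 1.0
        if treat == "treated":
            treat_ind[idx] = 1.0
    x = np.column_stack([np.ones(n_total), assay_ind, treat_ind])
    hat = x @ np.linalg.solve(x.T @ x, x.T)
    resid_add = y - y @ hat.T
    rss_add = (resid_add**2).sum(axis=1)

    ss_int = np.maximum(rss_add - rss_full, 0.0)
    scale = np.maximum((y**2).sum(axis=1), 1.0)
    tiny = 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_int / (rss_full / df_err)
        p = stats.f.sf(f, 1, df_err)
    degenerate = rss_full <= tiny
    p = np.where(degenerate & (ss_int <= tiny), 1.0, p)
    p = np.where(degenerate & (ss_int > tiny), 0.0, p)
    return p


def dbp_effect(
    rpm: CountMatrix,
    design: Sequence[SampleDesign],
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Per-cluster IP-vs-input log2 fold changes per arm and their difference.

    ``lfc = log2((mean IP RPM + eps) / (mean input RPM + eps))`` within each
    treatment arm; ``delta_lfc = lfc_treated - lfc_untreated``.  The epsilon
    floor keeps all-zero clusters finite (they get delta 0, with a warning).
    """
    cells = _cell_columns(rpm.col_ids, design)
    y = np.asarray(rpm.values, dtype=float)
    means = {key: y[:, idx].mean(axis=1) for key, idx in cells.items()}
    lfc_t = np.log2(
        (means[("IP", "treated")] + epsilon) / (means[("input", "treated")] + epsilon)
    )
    lfc_u = np.log2(
        (means[("IP", "untreated")] + epsilon)
        / (means[("input", "untreated")] + epsilon)
    )
    all_zero = sum(means.values()) == 0
    if all_zero.any():
        warnings.warn(
            f"{int(all_zero.sum())} cluster(s) have zero RPM in every sample; "
            "their delta_lfc is 0 by the epsilon floor",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "cluster_id": rpm.row_ids,
            "lfc_treated": lfc_t,
            "lfc_untreated": lfc_u,
            "delta_lfc": lfc_t - lfc_u,
        }
    )


def call_dbps(
    rpm: CountMatrix,
    design: Sequence[SampleDesign],
    p_max: float = 0.05,
    delta_min: float = 0.5,
    epsilon: float = 0.1,
    log: bool = False,
    bh_adjust: bool = False,
) -> list[DbpResult]:
    """Compose the interaction ANOVA and effect sizes into DBP calls.

    direction = "up"   iff p < p_max and delta_lfc > +delta_min
    direction = "down" iff p < p_max and delta_lfc < -delta_min
    otherwise "none".

    ``bh_adjust=True`` thresholds Benjamini-Hochberg-adjusted interaction
    p-values instead of raw ones (the procedure of record uses raw p-values;
    the flag is a conservative extra, not part of it).
    """
    p = dbp_anova(rpm, design, log=log, epsilon=epsilon)
    if bh_adjust:
        p_for_call = multipletests(p, method="fdr_bh")[1]
    else:
        p_for_call = p
    eff = dbp_effect(rpm, design, epsilon=epsilon)
    out: list[DbpResult] = []
    for i, row in enumerate(eff.itertuples()):
        direction = "none"
        if p_for_call[i] < p_max:
            if row.delta_lfc > delta_min:
                direction = "up"
            elif row.delta_lfc < -delta_min:
                direction = "down"
        out.append(
            DbpResult(
                cluster_id=row.cluster_id,
                p_interaction=float(p[i]),
                lfc_treated=float(row.lfc_treated),
                lfc_untreated=float(row.lfc_untreated),
                delta_lfc=float(row.delta_lfc),
                direction=direction,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gene-level aggregation and summaries


def aggregate_genes(
    dbps: Sequence[DbpResult],
    clusters: Sequence[ClusterRecord],
) -> list[GeneBindingSummary]:
    """Summarise directional DBPs per gene.

    Only clusters with a gene assignment and a directional call contribute.
    ``direction_class`` is "up"/"down" when every DBP of the gene agrees and
    "mixed" otherwise; ``mean_delta_lfc`` averages the gene's DBP deltas.
    """
    gene_of = {c.cluster_id: c.gene_id for c in clusters}
    per_gene: dict[str, list[DbpResult]] = {}
    for dbp in dbps:
        if dbp.direction == "none":
            continue
        gene = gene_of.get(dbp.cluster_id, "")
        if not gene:
            continue
        per_gene.setdefault(gene, []).append(dbp)
    out = []
    for gene in sorted(per_gene):
        hits = per_gene[gene]
        n_up = sum(1 for h in hits if h.direction == "up")
        n_down = sum(1 for h in hits if h.direction == "down")
        if n_up and n_down:
            cls = "mixed"
        elif n_up:
            cls = "up"
        else:
            cls = "down"
        out.append(
            GeneBindingSummary(
                gene_id=gene,
                n_dbps=n_up + n_down,
                n_up=n_up,
                n_down=n_down,
                direction_class=cls,
                mean_delta_lfc=float(np.mean([h.delta_lfc for h in hits])),
            )
        )
    return out


def coordination_stats(
    summaries: Sequence[GeneBindingSummary],
) -> CoordinationStats:
    """Direction coordination among genes with multiple DBPs.

    Reports how many multi-DBP genes are fully coordinated (all up or all
    down) and what fraction of all DBP-containing genes is mixed.
    """
    if not summaries:
        raise ValueError("no gene summaries")
    n_genes = len(summaries)
    multi = [s for s in summaries if s.n_dbps > 1]
    n_mixed = sum(1 for s in summaries if s.direction_class == "mixed")
    n_coord = sum(1 for s in multi if s.direction_class != "mixed")
    return CoordinationStats(
        n_genes=n_genes,
        n_multi=len(multi),
        n_coordinated=n_coord,
        n_mixed=n_mixed,
        pct_coordinated_of_multi=(100.0 * n_coord / len(multi)) if multi else float("nan"),
        pct_mixed_of_all=100.0 * n_mixed / n_genes,
    )


def overlap_summary(
    bound_genes_untreated: set[str],
    bound_genes_treated: set[str],
) -> OverlapSummary:
    """Set arithmetic on bound-gene sets between conditions.

    "Bound" means owning at least one significant peak in that condition.
    The shared fraction is reported as a percent of the untreated set.
    """
    if not bound_genes_untreated:
        raise ValueError("untreated bound-gene set is empty")
    shared = bound_genes_untreated & bound_genes_treated
    return OverlapSummary(
        n_shared=len(shared),
        n_lost=len(bound_genes_untreated - bound_genes_treated),
        n_new=len(bound_genes_treated - bound_genes_untreated),
        shared_fraction_of_untreated=100.0 * len(shared) / len(bound_genes_untreated),
    )


# ---------------------------------------------------------------------------
# Tabular views


def dbp_table(dbps: Sequence[DbpResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [d.cluster_id for d in dbps],
            "p_interaction": [d.p_interaction for d in dbps],
            "lfc_treated": [d.lfc_treated for d in dbps],
            "lfc_untreated": [d.lfc_untreated for d in dbps],
            "delta_lfc": [d.delta_lfc for d in dbps],
            "direction": [d.direction for d in dbps],
        }
    )


def gene_summary_table(summaries: Sequence[GeneBindingSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "n_dbps": [s.n_dbps for s in summaries],
            "n_up": [s.n_up for s in summaries],
            "n_down": [s.n_down for s in summaries],
            "direction_class": [s.direction_class for s in summaries],
            "mean_delta_lfc": [s.mean_delta_lfc for s in summaries],
        }
    )
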