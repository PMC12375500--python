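"""Synthetic multi-omic data with planted ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis is testable end-to-end without any download:

* eCLIP: a 2x2 (IP/input x treated/untreated) replicated design of
  negative-binomial cluster counts.  Each cluster has a base abundance
  (RPM in the input libraries), an IP enrichment, and — for a planted
  fraction of differentially bound clusters — an interaction effect applied
  to the treated-IP cell only.
* a matching gene annotation with 5'UTR / CDS / intron / 3'UTR features,
  with clusters placed inside features according to a planted region mix
  (default 72% 3'UTR / 20% CDS / 5% 5'UTR / 3% intron, the regime seen for
  3'UTR-binding RBPs);
* RNA-seq counts whose true log2 fold change is a linear function of the
  gene's planted binding change;
* LFQ proteomics intensities whose true log2 fold change follows the RNA
  effect, with optional missingness encoded as zero intensity;
* Boltzmann melt curves per condition.

All generators are pure functions of the configuration (which carries the
seed); repeated calls give byte-identical output.  Counts are negative
binomial parameterised by mean mu and dispersion alpha with
Var = mu + alpha mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .iolib import (
    ClusterRecord,
    CountMatrix,
    GeneAnnotation,
    GeneFeature,
    GenomicInterval,
    SampleDesign,
    write_annotation,
    write_bed,
    write_count_matrix,
    write_design,
    write_melt_csv,
    write_tsv,
)
from .meltcurve import boltzmann

__all__ = [
    "SimConfig",
    "GroundTruth",
    "EclipSim",
    "simulate_eclip",
    "simulate_rnaseq",
    "simulate_proteomics",
    "simulate_meltcurve",
    "write_fixture",
]

# Internal stream indices so each stage draws from an independent,
# reproducible stream derived from the one seed.
_STREAM_ECLIP, _STREAM_RNA, _STREAM_PROT, _STREAM_MELT = 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic multi-omic experiment.

    Defaults follow the design of the emulated study: duplicate eCLIP
    (2 IP + 2 input libraries per treatment), triplicate RNA-seq, 4-vs-4
    proteomics, a thermal gradient from 37 to 58 degrees C, ~25% of
    clusters differentially bound with |dLFC| between 2 and 5 — site-level
    near-on/off switching of binding, 60% of the switches losing binding —
    and a predominantly 3'UTR region mix.
    """

    seed: int = 0
    # eCLIP
    n_genes: int = 500
    n_clusters: int | None = None  # truncate/extend gene sampling to hit exactly
    clusters_per_gene_pois: float = 3.3  # clusters/gene ~ 1 + Poisson(lambda)
    region_composition: Mapping[str, float] = field(
        default_factory=lambda: {"3UTR": 0.72, "CDS": 0.20, "5UTR": 0.05, "intron": 0.03}
    )
    n_replicates: int = 2  # per (assay x treatment) cell
    nb_dispersion: float = 0.05
    frac_dbp: float = 0.25
    dbp_delta_lfc_range: tuple[float, float] = (2.0, 5.0)  # |dLFC| ~ Uniform
    dbp_frac_down: float = 0.6
    base_rpm_median: float = 20.0
    base_rpm_sdlog: float = 1.0
    ip_log2_enrichment_mean: float = 4.0
    ip_log2_enrichment_sd: float = 1.0
    library_size_range: tuple[int, int] = (1_500_000, 2_500_000)
    # RNA-seq
    rna_replicates: int = 3
    coupling_rna: float = 1.0
    rna_base_median: float = 200.0
    rna_base_sdlog: float = 1.2
    rna_size_factors: tuple[float, ...] | None = None  # planted, default all 1
    # Proteomics
    prot_replicates: int = 4
    coupling_protein: float = 0.8
    prot_fraction: float = 0.3
    lfq_noise_sd: float = 0.3  # log2 units
    lfq_missing_frac: float = 0.1
    lfq_base_mean: float = 25.0  # log2 intensity
    lfq_base_sd: float = 2.0
    peptide_count_mean: float = 5.0
    # CETSA
    melt_top: float = 1.0
    melt_bottom: float = 0.0
    melt_tm: Mapping[str, float] = field(
        default_factory=lambda: {"vehicle": 45.6, "treated": 47.7}
    )
    melt_slope: float = 1.5
    melt_temperatures: tuple[float, ...] = (37, 40, 43, 46, 49, 52, 55, 58)
    melt_noise_sd: float = 0.0
    melt_replicates: int = 3

    def __post_init__(self) -> None:
        probs = np.array(list(self.region_composition.values()), dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ValueError("region composition probabilities must sum to 1")
        if not 0.0 <= self.frac_dbp <= 1.0:
            raise ValueError("frac_dbp must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates < 1 or self.rna_replicates < 1 or self.prot_replicates < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth: per-cluster binding effects and per-gene omic effects."""

    clusters: pd.DataFrame  # cluster_id, gene_id, region, base_rpm,
    #                         ip_log2_enrichment, is_dbp, delta_lfc
    genes: pd.DataFrame  # gene_id, binding_delta, rna_log2fc, protein_log2fc


@dataclass
class EclipSim:
    clusters: list[ClusterRecord]
    counts: CountMatrix
    design: list[SampleDesign]
    truth: GroundTruth
    annotation: list[GeneAnnotation]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial with Var = mu + alpha mu^2 (mu may be an array)."""
    mu = np.asarray(mu, dtype=float)
    r = 1.0 / alpha
    p = r / (r + mu)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


# Gene model used for synthetic annotation: contiguous blocks per gene.
_GENE_FEATURES = (
    ("5UTR", 0, 200),
    ("CDS", 200, 700),
    ("intron", 700, 1200),
    ("CDS", 1200, 1700),
    ("3UTR", 1700, 2500),
)
_GENE_SPAN = 2500
_GENE_GAP = 7500
_N_CHROMS = 5
_CLUSTER_LEN = 50


def _gene_annotation(gene_ids: list[str]) -> list[GeneAnnotation]:
    genes = []
    offsets = [0] * _N_CHROMS
    for i, gid in enumerate(gene_ids):
        ci = i % _N_CHROMS
        chrom = f"chr{ci + 1}"
        start = offsets[ci]
        offsets[ci] += _GENE_SPAN + _GENE_GAP
        feats = [
            GeneFeature(GenomicInterval(chrom, start + a, start + b, "+"), region)
            for region, a, b in _GENE_FEATURES
        ]
        genes.append(GeneAnnotation(gid, feats))
    return genes


def simulate_eclip(config: SimConfig) -> EclipSim:
    """Generate the 2x2 replicated eCLIP experiment with planted DBPs.

    Cluster counts are negative binomial with mean
    ``library_size/1e6 x base_rpm x enrichment(assay, treatment)``; the
    planted interaction multiplies the treated-IP mean (and only it) by
    ``2**delta_lfc``.  Exactly ``round(frac_dbp x n_clusters)`` clusters are
    flagged as differentially bound.
    """
    rng = np.random.default_rng([_STREAM_ECLIP, config.seed])

    # Assign clusters to genes.
    per_gene = 1 + rng.poisson(config.clusters_per_gene_pois, size=config.n_genes)
    if config.n_clusters is not None:
        while per_gene.sum() < config.n_clusters:
            per_gene = np.concatenate(
                [per_gene, 1 + rng.poisson(config.clusters_per_gene_pois, size=50)]
            )
        keep = np.searchsorted(per_gene.cumsum(), config.n_clusters) + 1
        per_gene = per_gene[:keep]
    n_genes = len(per_gene)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    annotation = _gene_annotation(gene_ids)
    gene_of_cluster = np.repeat(np.arange(n_genes), per_gene)
    if config.n_clusters is not None:
        gene_of_cluster = gene_of_cluster[: config.n_clusters]
    n = len(gene_of_cluster)

    # Regions and coordinates.
    regions = list(config.region_composition)
    probs = np.array([config.region_composition[r] for r in regions])
    region_idx = rng.choice(len(regions), size=n, p=probs)
    cluster_region = [regions[i] for i in region_idx]

    feature_lookup: dict[str, list[GeneFeature]] = {}
    clusters: list[ClusterRecord] = []
    for k in range(n):
        gi = int(gene_of_cluster[k])
        gene = annotation[gi]
        region = cluster_region[k]
        feats = feature_lookup.setdefault(
            f"{gi}:{region}", [f for f in gene.features if f.region == region]
        )
        feat = feats[int(rng.integers(len(feats)))] if len(feats) > 1 else feats[0]
        lo = feat.interval.start
        hi = feat.interval.end - _CLUSTER_LEN
        start = int(rng.integers(lo, hi))
        clusters.append(
            ClusterRecord(
                GenomicInterval(feat.interval.chrom, start, start + _CLUSTER_LEN, "+"),
                cluster_id=f"clu{k:06d}",
                gene_id=gene.gene_id,
                region=region,
            )
        )

    # Planted effects.
    base_rpm = rng.lognormal(np.log(config.base_rpm_median), config.base_rpm_sdlog, n)
    ip_enr = np.maximum(
        rng.normal(config.ip_log2_enrichment_mean, config.ip_log2_enrichment_sd, n),
        0.5,
    )
    n_dbp = round(config.frac_dbp * n)
    is_dbp = np.zeros(n, dtype=bool)
    is_dbp[rng.choice(n, size=n_dbp, replace=False)] = True
    lo, hi = config.dbp_delta_lfc_range
    magnitude = rng.uniform(lo, hi, n)
    sign = np.where(rng.random(n) < config.dbp_frac_down, -1.0, 1.0)
    delta = np.where(is_dbp, sign * magnitude, 0.0)

    # Design and counts.
    design: list[SampleDesign] = []
    for assay in ("IP", "input"):
        for treatment in ("treated", "untreated"):
            for rep in range(1, config.n_replicates + 1):
                design.append(
                    SampleDesign(
                        sample_id=f"{assay}_{treatment}_{rep}",
                        assay=assay,
                        treatment=treatment,
                        replicate=rep,
                        library_size=int(rng.integers(*config.library_size_range)),
                    )
                )
    cols = []
    for d in design:
        mu = base_rpm * d.library_size / 1e6
        if d.assay == "IP":
            mu = mu * 2.0**ip_enr
            if d.treatment == "treated":
                mu = mu * 2.0**delta
        cols.append(_nb_draw(rng, mu, config.nb_dispersion))
    counts = CountMatrix(
        [c.cluster_id for c in clusters],
        [d.sample_id for d in design],
        np.column_stack(cols),
    )

    truth_clusters = pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "gene_id": [c.gene_id for c in clusters],
            "region": cluster_region,
            "base_rpm": base_rpm,
            "ip_log2_enrichment": ip_enr,
            "is_dbp": is_dbp,
            "delta_lfc": delta,
        }
    )
    gene_delta = truth_clusters.groupby("gene_id")["delta_lfc"].mean()
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_delta.index,
            "binding_delta": gene_delta.to_numpy(),
        }
    )
    truth_genes["rna_log2fc"] = config.coupling_rna * truth_genes["binding_delta"]
    truth_genes["protein_log2fc"] = (
        config.coupling_protein * truth_genes["rna_log2fc"]
    )
    truth = GroundTruth(clusters=truth_clusters, genes=truth_genes.reset_index(drop=True))
    return EclipSim(clusters, counts, design, truth, annotation)


def simulate_rnaseq(
    config: SimConfig, truth: GroundTruth
) -> tuple[CountMatrix, dict[str, str]]:
    """RNA-seq counts whose true log2FC tracks the planted binding change.

    Triplicate (by default) treated vs control negative-binomial counts;
    the treated mean of gene g is ``base_g x 2**rna_log2fc_g``; planted size
    factors multiply each sample's means.  Returns the count matrix and the
    sample-to-group mapping.
    """
    rng = np.random.default_rng([_STREAM_RNA, config.seed])
    genes = truth.genes["gene_id"].tolist()
    lfc = truth.genes["rna_log2fc"].to_numpy()
    n_genes = len(genes)
    base = rng.lognormal(np.log(config.rna_base_median), config.rna_base_sdlog, n_genes)

    n_per = config.rna_replicates
    sample_ids = [f"control_{i + 1}" for i in range(n_per)] + [
        f"treated_{i + 1}" for i in range(n_per)
    ]
    groups = {s: ("control" if s.startswith("control") else "treated") for s in sample_ids}
    sf = (
        np.ones(2 * n_per)
        if config.rna_size_factors is None
        else np.asarray(config.rna_size_factors, dtype=float)
    )
    if sf.size != 2 * n_per:
        raise ValueError("rna_size_factors must have one entry per sample")
    cols = []
    for j, s in enumerate(sample_ids):
        mu = base * sf[j]
        if groups[s] == "treated":
            mu = mu * 2.0**lfc
        cols.append(_nb_draw(rng, mu, config.nb_dispersion))
    return (
        CountMatrix(genes, sample_ids, np.column_stack(cols)),
        groups,
    )


def simulate_proteomics(config: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """LFQ intensity table for a random subset of genes.

    Log2 intensities are Gaussian around planted means (treated mean offset
    by the gene's true protein log2FC); a configurable fraction of entries
    is zeroed to emulate missing quantifications, and peptide counts are
    drawn >= 1.  Column order: treated then control replicates.
    """
    rng = np.random.default_rng([_STREAM_PROT, config.seed])
    genes = truth.genes["gene_id"].to_numpy()
    lfc = truth.genes["protein_log2fc"].to_numpy()
    n_prot = max(1, round(config.prot_fraction * len(genes)))
    pick = np.sort(rng.choice(len(genes), size=n_prot, replace=False))
    genes, lfc = genes[pick], lfc[pick]

    n_per = config.prot_replicates
    t_cols = [f"lfq_treated_{i + 1}" for i in range(n_per)]
    c_cols = [f"lfq_control_{i + 1}" for i in range(n_per)]
    base = rng.normal(config.lfq_base_mean, config.lfq_base_sd, n_prot)
    log_t = base[:, None] + lfc[:, None] + rng.normal(
        0, config.lfq_noise_sd, (n_prot, n_per)
    )
    log_c = base[:, None] + rng.normal(0, config.lfq_noise_sd, (n_prot, n_per))
    inten = np.column_stack([2.0**log_t, 2.0**log_c])
    if config.lfq_missing_frac > 0:
        inten[rng.random(inten.shape) < config.lfq_missing_frac] = 0.0

    df = pd.DataFrame(inten, columns=t_cols + c_cols)
    df.insert(0, "protein_id", [f"P_{g}" for g in genes])
    df.insert(1, "gene_id", genes)
    df.insert(2, "peptide_count", 1 + rng.poisson(config.peptide_count_mean, n_prot))
    return df


def simulate_meltcurve(config: SimConfig) -> pd.DataFrame:
    """Boltzmann melt curves per condition and replicate.

    ``fraction(T) = bottom + (top - bottom) / (1 + exp((T - Tm)/slope))``
    evaluated at the configured temperatures, plus optional Gaussian noise.
    """
    rng = np.random.default_rng([_STREAM_MELT, config.seed])
    t = np.asarray(config.melt_temperatures, dtype=float)
    rows = []
    for condition in config.melt_tm:
        tm = config.melt_tm[condition]
        for rep in range(1, config.melt_replicates + 1):
            frac = boltzmann(t, config.melt_top, config.melt_bottom, tm, config.melt_slope)
            if config.melt_noise_sd > 0:
                frac = frac + rng.normal(0, config.melt_noise_sd, t.size)
            for ti, fi in zip(t, frac):
                rows.append((float(ti), float(fi), condition, rep))
    return pd.DataFrame(rows, columns=["temperature", "fraction", "condition", "replicate"])


def write_fixture(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Write the full synthetic fixture directory from one configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_eclip(config)
    rna, groups = simulate_rnaseq(config, sim.truth)
    prot = simulate_proteomics(config, sim.truth)
    melt = simulate_meltcurve(config)

    paths = {
        "clusters_bed": out / "clusters.bed",
        "eclip_counts": out / "eclip_counts.tsv",
        "eclip_design": out / "eclip_design.tsv",
        "annotation": out / "annotation.tsv",
        "rnaseq_counts": out / "rnaseq_counts.tsv",
        "rnaseq_groups": out / "rnaseq_groups.tsv",
        "proteomics": out / "proteomics.tsv",
        "meltcurves": out / "meltcurves.csv",
        "truth_clusters": out / "truth_clusters.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
    write_bed(sim.clusters, paths["clusters_bed"])
    write_count_matrix(sim.counts, paths["eclip_counts"])
    write_design(sim.design, paths["eclip_design"])
    write_annotation(sim.annotation, paths["annotation"])
    write_count_matrix(rna, paths["rnaseq_counts"])
    write_tsv(
        pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}),
        paths["rnaseq_groups"],
    )
    write_tsv(prot, paths["proteomics"])
    write_melt_csv(melt, paths["meltcurves"])
    write_tsv(sim.truth.clusters, paths["truth_clusters"])
    write_tsv(sim.truth.genes, paths["truth_genes"])
    return paths
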