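"""RNA-seq differential expression with a baseMean-dependent significance filter.

The module provides a small, self-contained negative-binomial differential
expression test: median-of-ratios size factors, a method-of-moments
dispersion estimate per gene, and a Wald test on the log2 fold change with
the standard error propagated from the NB variance.  It is intentionally
minimal — no dispersion shrinkage, no outlier replacement, no independent
filtering — and makes no claim of numerical agreement with full-featured DE
packages.  The bespoke significance filter can also be applied to an
externally produced (baseMean, log2FC, padj) table.

The filter requires, besides an adjusted p-value below threshold,

    baseMean > 5   and   |log2FC| > 5 / sqrt(baseMean) + 0.6

so lowly expressed genes need up to a ~7-fold change while highly expressed
genes need ~1.5-fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .iolib import CountMatrix

__all__ = [
    "DegRecord",
    "DeModel",
    "prefilter_low_counts",
    "estimate_size_factors",
    "de_test",
    "significance_filter",
    "lfc_threshold",
    "implied_min_fold_change",
    "pca_qc",
    "deg_table",
]

DISPERSION_FLOOR = 1e-8
LFC_PSEUDOCOUNT = 0.5  # pseudo normalized count guarding log2 ratios


@dataclass
class DegRecord:
    gene_id: str
    base_mean: float
    log2fc: float
    p: float
    padj: float
    passes_filter: bool = False


@dataclass
class DeModel:
    size_factors: np.ndarray  # per sample, geometric mean 1
    dispersions: np.ndarray  # per gene, >= DISPERSION_FLOOR


def prefilter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count over all samples is below ``min_total``.

    The comparison is strict: a gene summing to exactly ``min_total`` is kept.
    """
    totals = counts.values.sum(axis=1)
    keep = totals >= min_total
    return CountMatrix(
        [r for r, k in zip(counts.row_ids, keep) if k],
        list(counts.col_ids),
        counts.values[keep, :],
    )


def estimate_size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each gene with strictly positive counts in every sample, the ratio
    of each sample's count to the gene's geometric mean is formed; the size
    factor of a sample is the median of these ratios.  Genes containing any
    zero are excluded from the reference.
    """
    vals = np.asarray(counts.values, dtype=float)
    all_pos = (vals > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "add a pseudocount or filter samples"
        )
    ref = vals[all_pos, :]
    log_gm = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_gm)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def de_test(
    counts: CountMatrix,
    groups: Mapping[str, str] | Sequence[str],
    size_factors: np.ndarray | None = None,
    padj_max: float = 0.05,
) -> list[DegRecord]:
    """Two-group NB Wald test per gene, with BH adjustment and the filter flag.

    ``groups`` maps each sample (column) to one of exactly two labels, each
    with at least two replicates.  The log2 fold change is reported for the
    lexicographically larger label over the smaller one.

    Per gene: counts are size-factor normalised; the NB dispersion alpha in
    Var = mu + alpha mu^2 is estimated by method of moments from the pooled
    within-group variance (floored at ``DISPERSION_FLOOR``); the Wald
    statistic log2FC / SE(log2FC) is referred to a t distribution with
    n1 + n2 - 2 degrees of freedom as a small-sample correction.
    """
    if isinstance(groups, Mapping):
        labels = [groups[c] for c in counts.col_ids]
    else:
        labels = list(groups)
        if len(labels) != len(counts.col_ids):
            raise ValueError("one group label per sample required")
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    g1 = np.array([l == uniq[0] for l in labels])
    g2 = ~g1
    n1, n2 = int(g1.sum()), int(g2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 replicates")

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    sf = np.asarray(size_factors, dtype=float)
    norm = counts.values / sf[None, :]

    base_mean = norm.mean(axis=1)
    m1 = norm[:, g1].mean(axis=1)
    m2 = norm[:, g2].mean(axis=1)

    # Pooled within-group variance of normalised counts.
    ss = ((norm[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss += ((norm[:, g2] - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / (n1 + n2 - 2)

    # Method-of-moments dispersion: on the normalised scale the NB model
    # gives Var(K_j / s_j) = mu / s_j + alpha mu^2.
    inv_sf = 1.0 / sf
    mu_bar = np.where(g1, m1[:, None], m2[:, None])  # per-sample group mean
    pois_part = (mu_bar * inv_sf[None, :]).mean(axis=1)
    mu2_part = (mu_bar**2).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - pois_part) / mu2_part
    alpha = np.where(np.isfinite(alpha), alpha, DISPERSION_FLOOR)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    def mean_var(m: np.ndarray, mask: np.ndarray, n: int) -> np.ndarray:
        per_sample = m[:, None] * inv_sf[None, mask] + alpha[:, None] * m[:, None] ** 2
        return per_sample.sum(axis=1) / n**2

    v1 = mean_var(m1, g1, n1)
    v2 = mean_var(m2, g2, n2)

    a1 = m1 + LFC_PSEUDOCOUNT
    a2 = m2 + LFC_PSEUDOCOUNT
    log2fc = np.log2(a2 / a1)
    ln2sq = np.log(2.0) ** 2
    var_lfc = (v1 / a1**2 + v2 / a2**2) / ln2sq
    se = np.sqrt(np.maximum(var_lfc, 1e-300))
    stat = log2fc / se
    p = 2.0 * stats.t.sf(np.abs(stat), df=n1 + n2 - 2)
    padj = multipletests(p, method="fdr_bh")[1]

    records = [
        DegRecord(gid, float(b), float(l), float(pv), float(pa))
        for gid, b, l, pv, pa in zip(counts.row_ids, base_mean, log2fc, p, padj)
    ]
    return significance_filter(records, padj_max=padj_max)


def lfc_threshold(base_mean: float | np.ndarray) -> float | np.ndarray:
    """The baseMean-dependent |log2FC| threshold t(b) = 5/sqrt(b) + 0.6."""
    return 5.0 / np.sqrt(base_mean) + 0.6


def implied_min_fold_change(base_mean: float) -> float:
    """Minimum fold change a gene at the given baseMean must show: 2**t(b)."""
    return float(2.0 ** lfc_threshold(base_mean))


def significance_filter(
    records: Sequence[DegRecord],
    padj_max: float = 0.05,
    base_mean_min: float = 5.0,
) -> list[DegRecord]:
    """Set ``passes_filter`` on each record.

    A gene passes iff padj < padj_max, baseMean > base_mean_min, and
    |log2FC| > 5/sqrt(baseMean) + 0.6.
    """
    out = []
    for r in records:
        ok = (
            r.padj < padj_max
            and r.base_mean > base_mean_min
            and abs(r.log2fc) > lfc_threshold(r.base_mean)
        )
        out.append(
            DegRecord(r.gene_id, r.base_mean, r.log2fc, r.p, r.padj, bool(ok))
        )
    return out


def pca_qc(
    counts: CountMatrix,
    size_factors: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """PCA of samples on log2(normalised counts + 1) for quality control.

    Returns the variance fraction per component (summing to 1) and the
    per-sample scores.
    """
    from sklearn.decomposition import PCA

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    x = np.log2(counts.values / np.asarray(size_factors)[None, :] + 1.0).T
    pca = PCA()
    scores = pca.fit_transform(x)
    ratios = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return ratios, pd.DataFrame(scores, index=counts.col_ids, columns=cols)


def deg_table(records: Sequence[DegRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "baseMean": [r.base_mean for r in records],
            "log2fc": [r.log2fc for r in records],
            "p": [r.p for r in records],
            "padj": [r.padj for r in records],
            "passes_filter": [r.passes_filter for r in records],
        }
    )
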