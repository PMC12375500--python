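"""Label-free quantification (LFQ) filtering and permutation-FDR testing.

Proteins are kept only when quantified (non-zero LFQ intensity) in every
sample with at least three peptides and no reverse / contaminant /
identified-by-site flag.  Group differences are then tested on log2
intensities with a two-sample statistic

    d_i = (mean_1 - mean_2) / (pooled SE + s0)

which for s0 = 0 is exactly the classical equal-variance t statistic.  The
false discovery rate is estimated SAM-style from balanced label
permutations: for each protein the q-value is the median, over
permutations, of the count of permuted |d| values at least as large as
|d_i|, divided by the observed count, clipped to [0, 1] and monotonised so
q never decreases as |d| decreases.  When at most 1000 distinct balanced
relabelings exist they are enumerated exhaustively, making the procedure
deterministic regardless of seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermTestConfig",
    "filter_lfq",
    "perm_t_test",
    "summarize_hits",
]

_FLAG_COLS = ("reverse", "contaminant", "only_identified_by_site")


@dataclass(frozen=True)
class PermTestConfig:
    n_permutations: int = 250
    s0: float = 0.0
    seed: int = 0
    q_max: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")


def filter_lfq(
    table: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    min_peptides: int = 3,
) -> pd.DataFrame:
    """Keep proteins quantified in all samples with enough peptide evidence.

    A row survives iff every intensity in ``group1 + group2`` is > 0, its
    ``peptide_count`` is at least ``min_peptides``, and none of the optional
    flag columns (reverse, contaminant, only_identified_by_site) is set.
    """
    cols = list(group1) + list(group2)
    keep = (table[cols] > 0).all(axis=1)
    keep &= table["peptide_count"] >= min_peptides
    for flag in _FLAG_COLS:
        if flag in table.columns:
            keep &= ~table[flag].astype(bool)
    return table.loc[keep].reset_index(drop=True)


def _stat(
    x1: np.ndarray, x2: np.ndarray, s0: float
) -> np.ndarray:
    """Moderated two-sample statistic on rows of log2 intensities."""
    n1, n2 = x1.shape[1], x2.shape[1]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    sp = np.sqrt(ss / (n1 + n2 - 2))
    se = sp * np.sqrt(1.0 / n1 + 1.0 / n2)
    return (m1 - m2) / (se + s0)


def _balanced_permutations(
    n: int, k: int, n_permutations: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets of size k (new group 1) out of n samples.

    Exhaustive when the number of distinct relabelings is at most 1000,
    otherwise ``n_permutations`` draws without replacement requirements.
    """
    from math import comb

    total = comb(n, k)
    if total <= 1000:
        return [np.array(c) for c in combinations(range(n), k)]
    perms = []
    for _ in range(n_permutations):
        perms.append(rng.choice(n, size=k, replace=False))
    return perms


def perm_t_test(
    table: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    config: PermTestConfig = PermTestConfig(),
    method: str = "sam",
) -> pd.DataFrame:
    """Two-sample test with permutation-based FDR on log2 LFQ intensities.

    Returns a copy of the (filtered) table with columns ``log2fc`` (group1
    over group2), ``t_stat``, ``p`` (pooled permutation p-value) and ``q``.
    ``method="sam"`` uses the SAM-style median-ratio FDR described in the
    module docstring; ``method="bh"`` applies Benjamini-Hochberg to the
    permutation p-values instead.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 samples")
    if method not in ("sam", "bh"):
        raise ValueError("method must be 'sam' or 'bh'")
    cols = list(group1) + list(group2)
    x = np.log2(table[cols].to_numpy(dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-positive intensity after filtering")
    n1 = len(group1)
    n = len(cols)
    m = x.shape[0]

    d_obs = _stat(x[:, :n1], x[:, n1:], config.s0)
    abs_obs = np.abs(d_obs)

    rng = np.random.default_rng(config.seed)
    perms = _balanced_permutations(n, n1, config.n_permutations, rng)
    b = len(perms)

    # counts_perm[b_i, i] = #{j : |d_perm_b(j)| >= |d_i|}
    counts_perm = np.empty((b, m), dtype=np.int64)
    for bi, idx1 in enumerate(perms):
        mask = np.zeros(n, dtype=bool)
        mask[idx1] = True
        d_b = np.abs(_stat(x[:, mask], x[:, ~mask], config.s0))
        d_b.sort()
        counts_perm[bi] = m - np.searchsorted(d_b, abs_obs, side="left")

    sorted_obs = np.sort(abs_obs)
    n_obs_ge = m - np.searchsorted(sorted_obs, abs_obs, side="left")

    p = counts_perm.mean(axis=0) / m

    if method == "sam":
        med = np.median(counts_perm, axis=0)
        q = np.clip(med / n_obs_ge, 0.0, 1.0)
    else:
        q = multipletests(p, method="fdr_bh")[1]
    # Monotonise: q must not decrease as |d| decreases.
    order = np.argsort(-abs_obs, kind="stable")
    q[order] = np.maximum.accumulate(q[order])

    out = table.copy()
    out["log2fc"] = x[:, :n1].mean(axis=1) - x[:, n1:].mean(axis=1)
    out["t_stat"] = d_obs
    out["p"] = p
    out["q"] = q
    return out


def summarize_hits(
    stats_table: pd.DataFrame,
    q_max: float = 0.05,
    lfc_min: float = 0.0,
) -> tuple[int, int, pd.DataFrame]:
    """Count down- and up-regulated proteins among significant hits.

    Returns (n_down, n_up, hits) where hits satisfy ``q <= q_max`` and
    ``|log2fc| >= lfc_min``.
    """
    if len(stats_table) == 0:
        return 0, 0, stats_table
    hits = stats_table[
        (stats_table["q"] <= q_max) & (stats_table["log2fc"].abs() >= lfc_min)
    ]
    n_down = int((hits["log2fc"] < 0).sum())
    n_up = int((hits["log2fc"] > 0).sum())
    return n_down, n_up, hits.reset_index(drop=True)
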