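"""Cross-omic integration: binding change vs RNA change vs protein change.

Gene-level eCLIP binding deltas, RNA-seq log2 fold changes and proteomics
log2 fold changes are outer-joined on gene id (missing layers stay missing,
never imputed).  Concordance between binding and expression is quantified
two ways, on the genes with an unambiguous binding direction:

* a chi-square test (1 df, no continuity correction) on the 2x2 quadrant
  table of binding direction x RNA fold-change sign, and
* a Mann-Whitney U (Wilcoxon rank-sum) test comparing the RNA log2FC
  distributions of binding-up vs binding-down genes.

Pathway-level signal in a differentially expressed gene list is assessed by
hypergeometric over-representation analysis (ORA) against a GMT gene-set
collection with Benjamini-Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binding import GeneBindingSummary
from .expression import DegRecord
from .iolib import GeneSet

__all__ = [
    "ConcordanceStats",
    "merge_omics",
    "concordance_stats",
    "ora_enrichment",
]


@dataclass(frozen=True)
class ConcordanceStats:
    quadrant_table: np.ndarray  # rows: binding up/down; cols: RNA up/down
    chi2: float
    chi2_p: float
    mw_p: float
    n_concordant: int
    n_discordant: int


def merge_omics(
    gene_binding: Sequence[GeneBindingSummary],
    deg_records: Sequence[DegRecord],
    protein_stats: pd.DataFrame | None = None,
    protein_q_max: float = 0.05,
) -> pd.DataFrame:
    """Outer-join the three omic layers on gene id.

    Returns one row per gene present in any layer with columns
    ``binding_delta``, ``binding_class``, ``rna_log2fc``, ``rna_sig``,
    ``protein_log2fc``, ``protein_sig`` and ``concordant``.  ``concordant``
    is defined only for genes with a directional binding class and a
    significant RNA change, and is True when the signs agree.
    """
    bind = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in gene_binding],
            "binding_delta": [s.mean_delta_lfc for s in gene_binding],
            "binding_class": [s.direction_class for s in gene_binding],
        }
    )
    rna = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in deg_records],
            "rna_log2fc": [r.log2fc for r in deg_records],
            "rna_sig": [r.passes_filter for r in deg_records],
        }
    )
    merged = bind.merge(rna, on="gene_id", how="outer")
    if protein_stats is not None and len(protein_stats):
        prot = protein_stats.loc[:, ["gene_id", "log2fc", "q"]].rename(
            columns={"log2fc": "protein_log2fc"}
        )
        prot["protein_sig"] = prot.pop("q") <= protein_q_max
        merged = merged.merge(prot, on="gene_id", how="outer")
    else:
        merged["protein_log2fc"] = np.nan
        merged["protein_sig"] = pd.Series(pd.NA, index=merged.index, dtype="boolean")
    merged["binding_class"] = merged["binding_class"].fillna("none")
    merged["rna_sig"] = merged["rna_sig"].astype("boolean")

    directional = merged["binding_class"].isin(["up", "down"])
    defined = directional & merged["rna_sig"].fillna(False).astype(bool)
    sign_agree = np.sign(merged["binding_delta"].fillna(0.0)) == np.sign(
        merged["rna_log2fc"].fillna(0.0)
    )
    merged["concordant"] = pd.Series(pd.NA, index=merged.index, dtype="boolean")
    merged.loc[defined, "concordant"] = sign_agree[defined]
    return merged.sort_values("gene_id").reset_index(drop=True)


def concordance_stats(
    records: pd.DataFrame,
    sig_only: bool = False,
) -> ConcordanceStats:
    """Quadrant counts and the two concordance tests.

    Uses genes with binding_class in {up, down} and an observed RNA log2FC
    (restricted to significant RNA changes when ``sig_only``).  Raises if a
    margin of the quadrant table is empty.
    """
    sub = records[
        records["binding_class"].isin(["up", "down"])
        & records["rna_log2fc"].notna()
        & (records["rna_log2fc"] != 0)
    ]
    if sig_only:
        sub = sub[sub["rna_sig"].fillna(False).astype(bool)]
    bind_up = sub["binding_class"] == "up"
    rna_up = sub["rna_log2fc"] > 0
    table = np.array(
        [
            [int((bind_up & rna_up).sum()), int((bind_up & ~rna_up).sum())],
            [int((~bind_up & rna_up).sum()), int((~bind_up & ~rna_up).sum())],
        ]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(
            "empty margin in the binding x RNA quadrant table; "
            "need genes in both binding directions with non-zero RNA change"
        )
    chi2, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
    mw = stats.mannwhitneyu(
        sub.loc[bind_up, "rna_log2fc"],
        sub.loc[~bind_up, "rna_log2fc"],
        alternative="two-sided",
    )
    n_conc = int(table[0, 0] + table[1, 1])
    n_disc = int(table[0, 1] + table[1, 0])
    return ConcordanceStats(
        quadrant_table=table,
        chi2=float(chi2),
        chi2_p=float(chi2_p),
        mw_p=float(mw.pvalue),
        n_concordant=n_conc,
        n_discordant=n_disc,
    )


def ora_enrichment(
    selected_genes: Iterable[str],
    universe: Iterable[str],
    gene_sets: Sequence[GeneSet],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in a selection.

    Sets are intersected with the universe; the p-value is the upper tail
    P(overlap >= observed) of the hypergeometric distribution; BH adjustment
    runs across all sets; a set is enriched when padj <= fdr_max.
    """
    universe = set(universe)
    selected = set(selected_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    n_universe = len(universe)
    n_selected = len(selected)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        overlap = len(members & selected)
        if members:
            p = float(
                stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_selected)
            )
        else:
            p = 1.0
        rows.append((gs.name, len(members), overlap, p))
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    if len(df):
        df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["padj"] = []
    df["enriched"] = df["padj"] <= fdr_max
    return df
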