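"""Gene commanding height (GCH) and gene master regulator (GMR) ranking.

A gene's prominence in a chamber combines how tightly its expression is
controlled (REC) with how strongly it is coordinated with the rest of
the transcriptome:

    GCH = (REC + 1) * exp( 4 * mean of rho_ij^2 over all partners j != i ).

The squared correlation makes the score sign-blind: strong antagonism
counts as much as strong synergism. Since mean rho^2 is in [0, 1], GCH
is bounded by (REC + 1) e^4. The chamber's top-GCH gene is its GMR.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from gfabric.coordination import correlation_matrix
from gfabric.fabric_stats import FabricSummary
from gfabric.io_model import ExpressionSet


def compute_gch(rec: float, rhos: list[float] | np.ndarray) -> float:
    """GCH from a gene's REC and its correlations with all partners.

    Undefined correlations (NaN, from zero-variance partners) are
    excluded from the mean; an empty or all-undefined partner list is an
    error.
    """
    if rec <= -1:
        raise ValueError("REC must exceed -1")
    rhos = np.asarray(rhos, dtype=float)
    if rhos.size == 0:
        raise ValueError("partner list is empty")
    if np.any(np.abs(rhos[~np.isnan(rhos)]) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    valid = rhos[~np.isnan(rhos)]
    if valid.size == 0:
        raise ValueError("no defined partner correlation")
    return (rec + 1.0) * math.exp(4.0 * float(np.mean(valid**2)))


def rank_genes(records: pd.DataFrame) -> pd.DataFrame:
    """Order a chamber's GCH records descending; rank 1 is the GMR.

    Ties on GCH break by higher REC, then lexicographic gene symbol, so
    ranks are a deterministic permutation of 1..n.
    """
    ordered = records.sort_values(
        by=["gch", "rec", "gene"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    return ordered


def gch_table(
    expr: ExpressionSet,
    summary: FabricSummary,
    chamber: str,
    partners: list[str] | None = None,
) -> pd.DataFrame:
    """GCH scores and ranks for every gene in one chamber.

    The partner universe defaults to all other quantified genes;
    ``partners`` restricts it to a gene set for exploratory runs.
    Columns: gene, chamber, rec, mean_sq_cor, gch, rank.
    """
    genes = expr.genes
    universe = genes if partners is None else [g for g in partners if g in set(genes)]
    rho, _ = correlation_matrix(expr, chamber, universe)
    rho_sq = rho.to_numpy() ** 2
    np.fill_diagonal(rho_sq, np.nan)  # exclude self-correlation

    rows = []
    for gene in genes:
        if gene in rho.index:
            row = rho_sq[rho.index.get_loc(gene)]
        else:
            # gene outside a restricted partner set: correlate it against the set
            sub, _ = correlation_matrix(expr, chamber, [gene] + list(rho.index))
            row = (sub.to_numpy()[0, 1:]) ** 2
        valid = row[~np.isnan(row)]
        if valid.size == 0:
            continue
        mean_sq = float(np.mean(valid))
        rec = float(summary.rec.loc[gene, chamber])
        rows.append(
            {
                "gene": gene,
                "chamber": chamber,
                "rec": rec,
                "mean_sq_cor": mean_sq,
                "gch": (rec + 1.0) * math.exp(4.0 * mean_sq),
            }
        )
    return rank_genes(pd.DataFrame(rows))


def top_genes(table: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The chamber's k most prominent (highest-GCH) genes."""
    return table.nsmallest(k, "rank")


def pathway_mean_gch(
    table: pd.DataFrame, members: list[str]
) -> float:
    """Arithmetic mean GCH over a pathway's quantified members."""
    sub = table[table["gene"].isin(members)]
    if sub.empty:
        raise ValueError("pathway has no quantified member with a GCH score")
    return float(sub["gch"].mean())
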