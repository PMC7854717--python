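"""Two-chamber differential expression with per-gene adaptive cut-offs.

Instead of a uniform fold-change threshold, each gene gets its own
cut-off combining the expression variabilities measured in both
compared chambers:

    CUT = 1 + sqrt( 2 ( REV_A^2 + REV_B^2 ) ),

with the REVs as fractions (percent / 100). The signed expression ratio
x is the ratio of the gene's summed spot means, oriented so |x| >= 1
and x < 0 means lower expression in the referred chamber B than in the
reference chamber A. A gene is called regulated when |x| > CUT and the
two-tail heteroscedastic (Welch) t-test of the replica means gives
p < 0.05. Pathway alteration is summarized both as the percentage of
regulated members and as the Weighted Pathway Regulation

    WPR = mean over members of  AVE_A (|x| - CUT)(1 - p)  [0 if |x| <= CUT],

which weights each gene's contribution by its reference expression
level, its excess fold change and its statistical confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gfabric.io_model import ExpressionSet, GeneSetCollection, IntegrityError


@dataclass(frozen=True)
class RegulationCall:
    """One gene's differential-expression call for an ordered chamber pair A->B."""

    gene: str
    comparison: tuple[str, str]
    x: float
    cut: float
    p: float
    regulated: bool
    wpr_term: float


@dataclass(frozen=True)
class PathwayRegulation:
    """Pathway-level alteration for one ordered comparison."""

    name: str
    comparison: tuple[str, str]
    n_quantified: int
    percent_regulated: float
    wpr: float


def _signed_ratio(sum_a: np.ndarray, sum_b: np.ndarray) -> np.ndarray:
    if np.any(sum_a <= 0) or np.any(sum_b <= 0):
        raise ZeroDivisionError("non-positive spot-mean sum; normalize first")
    with np.errstate(divide="ignore"):
        up = sum_b / sum_a
        down = -sum_a / sum_b
    return np.where(sum_b >= sum_a, up, down)


def expression_ratio(expr: ExpressionSet, gene: str, chamber_a: str, chamber_b: str) -> float:
    """Signed expression ratio x of one gene between reference A and referred B.

    x = sum_k mu_k(B) / sum_k mu_k(A) when B >= A, else the negative
    reciprocal, so |x| >= 1 always and x(A->B) = -x(B->A) away from 1.
    """
    mu_a = expr.spot_values(gene, chamber_a).mean(axis=1).to_numpy()
    mu_b = expr.spot_values(gene, chamber_b).mean(axis=1).to_numpy()
    return float(_signed_ratio(np.array([mu_a.sum()]), np.array([mu_b.sum()]))[0])


def compute_cut(rev_a: float | np.ndarray, rev_b: float | np.ndarray) -> float | np.ndarray:
    """Adaptive fold-change cut-off from the two chambers' fractional REVs.

    Both REVs are fractions (percent / 100). CUT >= 1, equals 1 only
    when both variabilities vanish, and is symmetric in its arguments.
    """
    rev_a = np.asarray(rev_a, dtype=float)
    rev_b = np.asarray(rev_b, dtype=float)
    if np.any(rev_a < 0) or np.any(rev_b < 0):
        raise ValueError("REV must be non-negative")
    cut = 1.0 + np.sqrt(2.0 * (rev_a**2 + rev_b**2))
    return float(cut) if cut.ndim == 0 else cut


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-tail Welch p-values for rows of a vs rows of b."""
    p = stats.ttest_ind(a, b, axis=-1, equal_var=False).pvalue
    p = np.atleast_1d(np.asarray(p, dtype=float))
    # zero variance in both groups: p = 1 when the means agree, else 0
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=-1), b.mean(axis=-1))
        p[degenerate] = np.where(np.atleast_1d(equal)[degenerate], 1.0, 0.0)
    return p


def test_means(expr: ExpressionSet, gene: str, chamber_a: str, chamber_b: str) -> float:
    """Two-tail heteroscedastic (Welch) test of mean equality between chambers.

    Operates on the gene's per-replica spot means (linear scale),
    treating the two chambers' replicas as unpaired samples of size 4.
    """
    a = expr.spot_values(gene, chamber_a).mean(axis=0).to_numpy()
    b = expr.spot_values(gene, chamber_b).mean(axis=0).to_numpy()
    return float(_welch_p(a[None, :], b[None, :])[0])


def call_regulation(
    gene: str,
    comparison: tuple[str, str],
    x: float,
    cut: float,
    p: float,
    ave_reference: float,
    alpha: float = 0.05,
) -> RegulationCall:
    """Combine ratio, cut-off and p-value into a regulation call.

    regulated <=> |x| > CUT and p < alpha; the WPR term is
    AVE_A (|x| - CUT)(1 - p) when |x| > CUT (note: the weight does not
    require p < alpha, only the excess over CUT), else 0.
    """
    exceeds = abs(x) > cut
    wpr_term = ave_reference * (abs(x) - cut) * (1.0 - p) if exceeds else 0.0
    return RegulationCall(
        gene=gene,
        comparison=comparison,
        x=x,
        cut=cut,
        p=p,
        regulated=bool(exceeds and p < alpha),
        wpr_term=wpr_term,
    )


def regulation_table(
    expr: ExpressionSet,
    chamber_a: str,
    chamber_b: str,
    rev: pd.DataFrame,
    ave: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Differential-expression calls for every gene, reference A -> referred B.

    ``rev`` and ``ave`` are the genes x chambers tables from
    :func:`gfabric.fabric_stats.fabric_summary` (REV in percent). Columns:
    gene, x, CUT, p, regulated, wpr_term. ``fdr=True`` additionally gates
    the regulated flag on Benjamini-Hochberg adjusted p-values (off by
    default: the method as defined applies no multiple-testing
    correction).
    """
    genes = expr.genes
    means_a = expr.replica_means(chamber_a).loc[genes]
    means_b = expr.replica_means(chamber_b).loc[genes]
    x = _signed_ratio(
        _spot_mean_sums(expr, chamber_a).loc[genes].to_numpy(),
        _spot_mean_sums(expr, chamber_b).loc[genes].to_numpy(),
    )
    cut = compute_cut(
        rev.loc[genes, chamber_a].to_numpy() / 100.0,
        rev.loc[genes, chamber_b].to_numpy() / 100.0,
    )
    p = _welch_p(means_a.to_numpy(), means_b.to_numpy())
    exceeds = np.abs(x) > cut
    regulated = exceeds & (p < alpha)
    if fdr:
        regulated = exceeds & (_bh_adjust(p) < alpha)
    wpr_term = np.where(
        exceeds, ave.loc[genes, chamber_a].to_numpy() * (np.abs(x) - cut) * (1.0 - p), 0.0
    )
    return pd.DataFrame(
        {
            "gene": genes,
            "x": x,
            "CUT": cut,
            "p": p,
            "regulated": regulated,
            "wpr_term": wpr_term,
        }
    )


def _spot_mean_sums(expr: ExpressionSet, chamber: str) -> pd.Series:
    """Per-gene sum over spots of the replica-mean of each spot."""
    mu = expr.chamber_matrix(chamber).mean(axis=1)
    return mu.groupby(level="gene", sort=False).sum()


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty_like(ranked)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def compute_wpr(
    calls: pd.DataFrame,
    name: str,
    comparison: tuple[str, str],
    members: list[str],
) -> PathwayRegulation:
    """Pathway regulation from its quantified members' calls.

    WPR is the arithmetic mean of the members' wpr terms; the percentage
    counts members with regulated = True.
    """
    sub = calls[calls["gene"].isin(members)]
    if sub.empty:
        raise IntegrityError(f"pathway {name!r} has no quantified member")
    return PathwayRegulation(
        name=name,
        comparison=comparison,
        n_quantified=len(sub),
        percent_regulated=100.0 * float(sub["regulated"].mean()),
        wpr=float(sub["wpr_term"].mean()),
    )


def pathway_regulation(
    calls: pd.DataFrame,
    comparison: tuple[str, str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Percent regulated and WPR for every gene set, one comparison.

    Returns a table: set, comparison, n_quantified, percent_regulated, WPR.
    """
    genes = list(calls["gene"])
    rows = []
    for set_name in gene_sets.names():
        present, _ = gene_sets.quantified(set_name, genes)
        reg = compute_wpr(calls, set_name, comparison, present)
        rows.append(
            {
                "set": reg.name,
                "comparison": f"{comparison[0]}:{comparison[1]}",
                "n_quantified": reg.n_quantified,
                "percent_regulated": reg.percent_regulated,
                "WPR": reg.wpr,
            }
        )
    return pd.DataFrame(rows)
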