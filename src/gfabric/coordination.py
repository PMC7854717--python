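"""Expression coordination: pairwise correlation, classification, synchrony.

Coordination between two genes in one chamber is the Pearson
product-moment correlation of their log2 expressions across the
biological replicas. When both genes are probed by the same number of
spots R, the 4R (replica, spot) points are paired in spot-index order
within each replica and the test uses df = 4R - 2; when the spot counts
differ, each gene's spots are averaged per replica (linear scale) and
the 4 replica values give df = 2. Significance is the two-tail t-test

    t = rho sqrt( df / (1 - rho^2) ).

Significantly positive pairs are *synergistic*, significantly negative
*antagonistic*; near-zero correlations (|rho| within a small band) are
*independent*; everything else is *undecided*. The same machinery,
pairing replicas by animal, measures the *synchrony* of one gene's
expression across two chambers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gfabric.io_model import ExpressionSet, IntegrityError

#: |rho| at or below which a pair is classified independent
INDEPENDENCE_BAND = 0.05


@dataclass(frozen=True)
class CoordinationEdge:
    """One gene pair's (or one gene's cross-chamber) correlation and class."""

    gene_a: str
    gene_b: str
    chamber: str  # "LA" for within-chamber pairs, "LA-RA" for synchrony edges
    rho: float
    df: int
    p: float
    category: str


def df_rule(r_a: int, r_b: int, n_replicas: int = 4) -> int:
    """Degrees of freedom for the correlation significance test.

    With equal spot redundancy R the correlated vectors hold
    n_replicas x R paired points, so df = 4R - 2 for four replicas
    (R = 1 -> 2, R = 2 -> 6, R = 3 -> 10). With unequal redundancy the
    spots are averaged per replica and df = n_replicas - 2.
    """
    if r_a < 1 or r_b < 1:
        raise ValueError("spot counts must be >= 1")
    if r_a == r_b:
        return n_replicas * r_a - 2
    return n_replicas - 2


def _paired_log2(expr: ExpressionSet, gene: str, chamber: str, equal_r: bool) -> np.ndarray:
    """Gene's log2 observation vector in one chamber.

    With matching redundancy: the 4R values in (replica-major, spot
    index) order. Otherwise: log2 of the per-replica spot averages.
    """
    spots = expr.spot_values(gene, chamber).to_numpy()  # spots x replicas
    if equal_r:
        return np.log2(spots.T.ravel())  # replica-major, spots in index order
    return np.log2(spots.mean(axis=0))


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = u.std(), v.std()
    if su == 0 or sv == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def pairwise_cor(
    expr: ExpressionSet, gene_a: str, gene_b: str, chamber: str
) -> tuple[float, int]:
    """Pearson correlation of two genes' log2 expressions in one chamber.

    Returns (rho, df) per the redundancy-aware df rule. rho is NaN (with
    a warning) when either vector has zero variance.
    """
    r_a = int(expr.redundancy[gene_a])
    r_b = int(expr.redundancy[gene_b])
    equal_r = r_a == r_b
    u = _paired_log2(expr, gene_a, chamber, equal_r)
    v = _paired_log2(expr, gene_b, chamber, equal_r)
    rho = _pearson(u, v)
    if np.isnan(rho):
        warnings.warn(
            f"zero log-variance for pair ({gene_a}, {gene_b}) in {chamber}: rho undefined"
        )
    return rho, df_rule(r_a, r_b, expr.n_replicas)


def cor_significance(rho: float | np.ndarray, df: int | np.ndarray) -> float | np.ndarray:
    """Two-tail p-value of a Pearson correlation at the given df.

    t = rho sqrt(df / (1 - rho^2)); |rho| = 1 gives p = 0, NaN rho
    propagates to NaN p.
    """
    rho_arr = np.asarray(rho, dtype=float)
    df_arr = np.asarray(df, dtype=float)
    if np.any(df_arr < 1):
        raise ValueError("df must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt(df_arr / (1.0 - rho_arr**2))
    p = 2.0 * stats.t.sf(np.abs(t), df_arr)
    p = np.where(np.abs(rho_arr) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho_arr), np.nan, p)
    return float(p) if np.isscalar(rho) or np.ndim(rho) == 0 else p


def classify_pair(
    rho: float,
    p: float,
    independence_band: float = INDEPENDENCE_BAND,
    alpha: float = 0.05,
) -> str:
    """Classify a correlation as synergistic / antagonistic / independent / undecided.

    Significant positive -> synergistic; significant negative ->
    antagonistic; |rho| inside the independence band -> independent;
    anything else (including undefined rho) -> undecided. Non-significant
    pairs are never counted as independent unless nearly zero.
    """
    if np.isnan(rho) or np.isnan(p):
        return "undecided"
    if p < alpha and rho > 0:
        return "synergistic"
    if p < alpha and rho < 0:
        return "antagonistic"
    if abs(rho) <= independence_band:
        return "independent"
    return "undecided"


# ---------------------------------------------------------------------------
# chamber-wide machinery (vectorized; identical results to pairwise_cor)
# ---------------------------------------------------------------------------


def correlation_matrix(
    expr: ExpressionSet, chamber: str, genes: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs rho and df matrices for one chamber.

    Same-redundancy pairs use the 4R paired-point correlation
    (df = 4R - 2); mixed-redundancy pairs use per-replica spot averages
    (df = 2). Deterministic regardless of tiling or gene order; the
    diagonal is 1 by construction. Zero-variance genes yield NaN rows.
    """
    if genes is None:
        genes = expr.genes
    n = len(genes)
    redundancy = expr.redundancy.loc[genes]

    # mixed-redundancy baseline: log2 of per-replica spot means
    avg = np.log2(expr.replica_means(chamber).loc[genes].to_numpy())
    rho = _safe_corrcoef(avg)
    df = np.full((n, n), expr.n_replicas - 2, dtype=int)

    # same-R blocks: correlate the 4R paired points
    pos = {g: i for i, g in enumerate(genes)}
    for r_val, group in redundancy.groupby(redundancy):
        members = list(group.index)
        idx = np.array([pos[g] for g in members])
        mats = np.stack(
            [_paired_log2(expr, g, chamber, equal_r=True) for g in members]
        )
        block = _safe_corrcoef(mats)
        df[np.ix_(idx, idx)] = expr.n_replicas * int(r_val) - 2
        rho[np.ix_(idx, idx)] = block
    np.fill_diagonal(rho, 1.0)
    return (
        pd.DataFrame(rho, index=genes, columns=genes),
        pd.DataFrame(df, index=genes, columns=genes),
    )


def _safe_corrcoef(rows: np.ndarray) -> np.ndarray:
    """corrcoef with zero-variance rows mapped to NaN instead of warnings."""
    sd = rows.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(rows)
    c = np.atleast_2d(c)
    bad = sd == 0
    c[bad, :] = np.nan
    c[:, bad] = np.nan
    return c


def coordination_table(
    expr: ExpressionSet,
    chamber: str,
    genes: list[str] | None = None,
    independence_band: float = INDEPENDENCE_BAND,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Edge list over all n(n-1)/2 gene pairs of one chamber.

    Columns: gene_a, gene_b, chamber, rho, df, p, category.
    """
    if genes is None:
        genes = expr.genes
    rho_m, df_m = correlation_matrix(expr, chamber, genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    rho = rho_m.to_numpy()[iu, ju]
    df = df_m.to_numpy()[iu, ju]
    p = cor_significance(rho, df)
    garr = np.asarray(genes, dtype=object)
    cats = [
        classify_pair(r, pv, independence_band, alpha) for r, pv in zip(rho, p)
    ]
    return pd.DataFrame(
        {
            "gene_a": garr[iu],
            "gene_b": garr[ju],
            "chamber": chamber,
            "rho": rho,
            "df": df,
            "p": p,
            "category": cats,
        }
    )


def synchrony(
    expr: ExpressionSet, gene: str, chamber_a: str, chamber_b: str
) -> CoordinationEdge:
    """Cross-chamber synchrony of one gene, replicas paired by animal.

    Correlates the gene's log2 values in the two chambers; with matching
    spot redundancy the spots are paired too (df = 4R - 2). A gene is
    synchronous when the edge is synergistic.
    """
    for chamber in (chamber_a, chamber_b):
        if chamber not in expr.chambers:
            raise IntegrityError(f"unknown chamber {chamber!r}")
    r = int(expr.redundancy[gene])
    u = _paired_log2(expr, gene, chamber_a, equal_r=True)
    v = _paired_log2(expr, gene, chamber_b, equal_r=True)
    rho = _pearson(u, v)
    df = df_rule(r, r, expr.n_replicas)
    p = cor_significance(rho, df) if not np.isnan(rho) else np.nan
    return CoordinationEdge(
        gene_a=gene,
        gene_b=gene,
        chamber=f"{chamber_a}-{chamber_b}",
        rho=rho,
        df=df,
        p=p,
        category=classify_pair(rho, p) if not np.isnan(rho) else "undecided",
    )


#: the four adjacent chamber pairings of a four-chamber heart
ADJACENT_PAIRS = (("LA", "RA"), ("LV", "RV"), ("LA", "LV"), ("RA", "RV"))


def synchrony_table(
    expr: ExpressionSet,
    chamber_pairs: tuple[tuple[str, str], ...] = ADJACENT_PAIRS,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Synchrony edges for every gene in every requested chamber pairing.

    For n genes and the four adjacent pairings this enumerates 4n
    evaluations. Vectorized per pairing and per redundancy group;
    results equal per-gene :func:`synchrony` calls.
    """
    if genes is None:
        genes = expr.genes
    redundancy = expr.redundancy.loc[genes]
    frames = []
    for ca, cb in chamber_pairs:
        for r_val, group in redundancy.groupby(redundancy):
            members = list(group.index)
            mats_a = np.stack(
                [_paired_log2(expr, g, ca, equal_r=True) for g in members]
            )
            mats_b = np.stack(
                [_paired_log2(expr, g, cb, equal_r=True) for g in members]
            )
            rho = _rowwise_pearson(mats_a, mats_b)
            df = expr.n_replicas * int(r_val) - 2
            p = cor_significance(rho, np.full(len(members), df))
            frames.append(
                pd.DataFrame(
                    {
                        "gene": members,
                        "chambers": f"{ca}-{cb}",
                        "rho": rho,
                        "df": df,
                        "p": p,
                        "category": [
                            classify_pair(r_, p_) for r_, p_ in zip(rho, p)
                        ],
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out["synchronous"] = out["category"] == "synergistic"
    return out


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a_c**2).sum(axis=1) * (b_c**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (a_c * b_c).sum(axis=1) / denom
    rho[denom == 0] = np.nan
    return rho


def partner_profile(
    expr: ExpressionSet,
    hub: str,
    partners: list[str],
    chamber: str,
    independence_band: float = INDEPENDENCE_BAND,
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """Percent of a hub's quantified partners synergistically expressed with it.

    Returns (percent, edges) with one edge row per quantified partner.
    """
    quantified = [g for g in partners if g in expr.redundancy.index and g != hub]
    if not quantified:
        raise IntegrityError(f"hub {hub!r}: no quantified partner")
    rows = []
    for partner in quantified:
        rho, df = pairwise_cor(expr, hub, partner, chamber)
        p = cor_significance(rho, df) if not np.isnan(rho) else np.nan
        rows.append(
            {
                "gene_a": hub,
                "gene_b": partner,
                "chamber": chamber,
                "rho": rho,
                "df": df,
                "p": p,
                "category": classify_pair(rho, p, independence_band, alpha)
                if not np.isnan(rho)
                else "undecided",
            }
        )
    edges = pd.DataFrame(rows)
    percent = 100.0 * float((edges["category"] == "synergistic").mean())
    return percent, edges


# ---------------------------------------------------------------------------
# enumeration arithmetic
# ---------------------------------------------------------------------------


def n_within_pairs(n_genes: int) -> int:
    """Number of distinct within-chamber gene pairs: n(n-1)/2."""
    if n_genes < 0:
        raise ValueError("gene count must be non-negative")
    return n_genes * (n_genes - 1) // 2


def n_cross_evaluations(n_genes: int, n_chamber_pairings: int = 4) -> int:
    """Number of same-gene cross-chamber synchrony evaluations.

    One per gene per adjacent chamber pairing; the four-chamber heart
    has four adjacencies (LA-RA, LV-RV, LA-LV, RA-RV), giving 4n.
    """
    if n_genes < 0 or n_chamber_pairings < 0:
        raise ValueError("counts must be non-negative")
    return n_genes * n_chamber_pairings


def enumerate_pairs(genes: list[str]) -> list[tuple[str, str]]:
    """Explicit enumeration backing the pair-count arithmetic."""
    return list(itertools.combinations(genes, 2))
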