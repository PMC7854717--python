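"""Per-gene expression level (AVE), variability (REV) and control (REC/PREC).

AVE is the gene's mean normalized expression: the four-replica mean of
each spot, averaged over the gene's R_i redundant spots, in units of
the median gene. REV is a redundancy-corrected coefficient of
variation, in percent: the per-spot CVs are pooled in quadrature and
multiplied by the mid-interval chi-square correction

    1/2 ( sqrt(r / chi2(r; 0.975)) + sqrt(r / chi2(r; 0.025)) ),
    r = 4 R_i - 1,

which widens the estimate for poorly replicated (low-R) genes and tends
to 1 as redundancy grows. REC compares a gene's REV to the
transcriptome median (REC = median_REV / REV - 1; 0 is the baseline,
positive = more tightly controlled), and PREC does the same for the
median REV of a pathway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from gfabric.io_model import ExpressionSet, GeneSetCollection, IntegrityError, NumericError

#: multiplier applied to a chamber's largest finite REC to cap zero-variance genes
ZERO_VARIANCE_REC_CAP = 10.0


def chi2_correction(R: int | np.ndarray) -> float | np.ndarray:
    """Redundancy correction coefficient for a gene probed by R spots.

    Uses the central 95% chi-square interval at r = 4R - 1 degrees of
    freedom; the sum of the two tail terms makes the value invariant to
    which quantile is labelled upper or lower. Strictly decreasing in R,
    always > 1, -> 1 as R -> infinity.
    """
    R_arr = np.asarray(R)
    if np.any(R_arr < 1) or not np.issubdtype(R_arr.dtype, np.integer) and np.any(
        R_arr != np.floor(R_arr)
    ):
        raise ValueError("spot count R must be an integer >= 1")
    r = 4 * R_arr.astype(float) - 1
    coef = 0.5 * (np.sqrt(r / chi2.ppf(0.975, r)) + np.sqrt(r / chi2.ppf(0.025, r)))
    return float(coef) if np.isscalar(R) else coef


def compute_ave(expr: ExpressionSet, gene: str, chamber: str) -> float:
    """Average expression level of one gene in one chamber (median-gene units)."""
    spots = expr.spot_values(gene, chamber)
    return float(spots.mean(axis=1).mean())


def compute_rev(expr: ExpressionSet, gene: str, chamber: str) -> float:
    """Relative expression variability of one gene in one chamber, in percent."""
    spots = expr.spot_values(gene, chamber).to_numpy()
    mu = spots.mean(axis=1)
    if np.any(mu <= 0):
        raise NumericError(f"gene {gene!r}: non-positive spot mean in {chamber}")
    s = spots.std(axis=1, ddof=1)
    pooled_cv = math.sqrt(float(np.mean((s / mu) ** 2)))
    return chi2_correction(spots.shape[0]) * pooled_cv * 100.0


def compute_rec(rev_i: float, median_rev_all: float) -> float:
    """Relative expression control: median REV over the gene's REV, minus 1."""
    if rev_i < 0:
        raise ValueError("REV must be non-negative")
    if rev_i == 0:
        warnings.warn("zero REV: REC is unbounded; returning +inf sentinel")
        return math.inf
    return median_rev_all / rev_i - 1.0


def compute_prec(revs: pd.Series | np.ndarray, median_rev_all: float) -> float:
    """Pathway relative expression control from its members' REVs.

    Uses the median REV over the pathway's quantified members; the whole
    transcriptome has PREC = 0 by construction.
    """
    revs = np.asarray(revs, dtype=float)
    if revs.size == 0:
        raise IntegrityError("pathway has no quantified member")
    return median_rev_all / float(np.median(revs)) - 1.0


# ---------------------------------------------------------------------------
# chamber-wide tables
# ---------------------------------------------------------------------------


@dataclass
class FabricSummary:
    """Per-gene AVE/REV/REC tables (genes x chambers) and chamber median REVs."""

    ave: pd.DataFrame
    rev: pd.DataFrame
    rec: pd.DataFrame
    median_rev: pd.Series
    #: genes whose REC was capped because their REV was exactly zero
    capped_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Long-form TSV layout: gene, chamber, AVE, REV, REC."""
        rows = []
        for chamber in self.ave.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.ave.index,
                        "chamber": chamber,
                        "AVE": self.ave[chamber].to_numpy(),
                        "REV": self.rev[chamber].to_numpy(),
                        "REC": self.rec[chamber].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _rev_column(expr: ExpressionSet, chamber: str) -> pd.Series:
    matrix = expr.chamber_matrix(chamber)
    mu = matrix.mean(axis=1)
    if (mu <= 0).any():
        raise NumericError(f"non-positive spot mean in chamber {chamber}")
    s = matrix.std(axis=1, ddof=1)
    cv2 = (s / mu) ** 2
    pooled = np.sqrt(cv2.groupby(level="gene", sort=False).mean())
    coef = chi2_correction(expr.redundancy.to_numpy())
    return pooled * coef * 100.0


def fabric_summary(expr: ExpressionSet) -> FabricSummary:
    """Compute AVE, REV and REC for every gene in every chamber.

    Zero-variance genes (REV = 0) receive a capped REC sentinel — the
    chamber's largest finite REC times 10 — with a warning, so rankings
    stay finite.
    """
    ave = pd.DataFrame(
        {c: expr.replica_means(c).mean(axis=1) for c in expr.chambers}
    )
    rev = pd.DataFrame({c: _rev_column(expr, c) for c in expr.chambers})
    median_rev = rev.median(axis=0)

    rec = median_rev / rev - 1.0
    capped: dict[str, list[str]] = {}
    for chamber in expr.chambers:
        zero = rev[chamber] == 0
        if zero.any():
            finite = rec.loc[~zero, chamber]
            cap = (
                float(finite.max()) * ZERO_VARIANCE_REC_CAP
                if len(finite) and np.isfinite(finite.max())
                else ZERO_VARIANCE_REC_CAP
            )
            rec.loc[zero, chamber] = cap
            capped[chamber] = list(rev.index[zero])
            warnings.warn(
                f"{int(zero.sum())} zero-REV gene(s) in {chamber}: REC capped at {cap:g}"
            )
    return FabricSummary(ave=ave, rev=rev, rec=rec, median_rev=median_rev, capped_genes=capped)


def pathway_control(
    summary: FabricSummary,
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """PREC of each gene set in each chamber.

    Returns a long table: set, chamber, n_quantified, median_REV, PREC.
    Sets with no quantified member raise :class:`IntegrityError`.
    """
    genes = list(summary.rev.index)
    rows = []
    for name in gene_sets.names():
        present, _ = gene_sets.quantified(name, genes)
        if not present:
            raise IntegrityError(f"gene set {name!r} has no quantified member")
        for chamber in summary.rev.columns:
            revs = summary.rev.loc[present, chamber]
            rows.append(
                {
                    "set": name,
                    "chamber": chamber,
                    "n_quantified": len(present),
                    "median_REV": float(revs.median()),
                    "PREC": compute_prec(revs, float(summary.median_rev[chamber])),
                }
            )
    return pd.DataFrame(rows)
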