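"""Independent brute-force oracles used to cross-check the package's statistics.

These re-derive every quantity from its defining formula using only
low-level numerical primitives (bisection on the chi-square CDF, the
raw Welch statistic, explicit covariance sums), deliberately avoiding
the code paths the package itself uses.
"""

import math

import numpy as np
from scipy.special import gammainc
from scipy.stats import t as t_dist


def chi2_quantile_bisect(df: float, q: float) -> float:
    """Chi-square quantile by bisection on the regularized gamma CDF."""
    lo, hi = 0.0, 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if gammainc(df / 2.0, mid / 2.0) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def correction_oracle(R: int) -> float:
    r = 4 * R - 1
    return 0.5 * (
        math.sqrt(r / chi2_quantile_bisect(r, 0.975))
        + math.sqrt(r / chi2_quantile_bisect(r, 0.025))
    )


def ave_oracle(spots: np.ndarray) -> float:
    """Mean over spots of the mean over replicas (spots x replicas array)."""
    return float(np.mean([np.mean(row) for row in spots]))


def rev_oracle(spots: np.ndarray) -> float:
    """Redundancy-corrected pooled CV, percent, from the defining formula."""
    spots = np.atleast_2d(spots)
    cv_sq = [
        (np.std(row, ddof=1) / np.mean(row)) ** 2 for row in spots
    ]
    pooled = math.sqrt(sum(cv_sq) / len(cv_sq))
    return correction_oracle(spots.shape[0]) * pooled * 100.0


def ratio_oracle(spots_a: np.ndarray, spots_b: np.ndarray) -> float:
    sum_a = sum(np.mean(row) for row in np.atleast_2d(spots_a))
    sum_b = sum(np.mean(row) for row in np.atleast_2d(spots_b))
    return sum_b / sum_a if sum_b >= sum_a else -sum_a / sum_b


def cut_oracle(rev_a_frac: float, rev_b_frac: float) -> float:
    return 1.0 + math.sqrt(2.0 * (rev_a_frac**2 + rev_b_frac**2))


def welch_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tail Welch p from the raw statistic and Satterthwaite df."""
    na, nb = len(a), len(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    se_sq = va / na + vb / nb
    if se_sq == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    t = (np.mean(a) - np.mean(b)) / math.sqrt(se_sq)
    df = se_sq**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * float(t_dist.sf(abs(t), df))


def wpr_term_oracle(ave_a: float, x: float, cut: float, p: float) -> float:
    return ave_a * (abs(x) - cut) * (1.0 - p) if abs(x) > cut else 0.0


def pearson_oracle(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson rho from explicit centered sums."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    uc, vc = u - u.mean(), v - v.mean()
    return float((uc * vc).sum() / math.sqrt((uc**2).sum() * (vc**2).sum()))


def cor_p_oracle(rho: float, df: int) -> float:
    """Two-tail p of a correlation via the t transform, recomputed directly."""
    if abs(rho) >= 1:
        return 0.0
    t = rho * math.sqrt(df / (1.0 - rho**2))
    return 2.0 * float(t_dist.sf(abs(t), df))


def permutation_cor_p(u: np.ndarray, v: np.ndarray) -> float:
    """Exact two-sided permutation p-value over all orderings of v (n = 4)."""
    import itertools

    observed = abs(pearson_oracle(u, v))
    count, total = 0, 0
    for perm in itertools.permutations(range(len(v))):
        total += 1
        if abs(pearson_oracle(u, v[list(perm)])) >= observed - 1e-12:
            count += 1
    return count / total


def gch_oracle(rec: float, rhos: np.ndarray) -> float:
    rhos = np.asarray(rhos, float)
    valid = rhos[~np.isnan(rhos)]
    return (rec + 1.0) * math.exp(4.0 * float(np.mean(valid**2)))
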