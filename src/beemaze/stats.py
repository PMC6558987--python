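"""Nonparametric test battery and helpers for the occupancy pipeline.

Implements the signed-rank and rank-sum tests in the z-statistic form
used throughout the occupancy tables (midrank ties, tie-corrected
normal approximation, configurable zero handling), Benjamini-Hochberg
FDR adjustment, fixed-effects ANOVA with Tukey HSD post hoc (via
statsmodels), and 1.5*IQR outlier flagging.

Both rank tests also offer an exact permutation mode (full enumeration
of sign assignments / group labelings) for small samples; the exact
two-sided p-value is defined symmetrically as the probability of a
statistic at least as far from its null mean as the observed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RankTestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "fdr_adjust",
    "anova_with_tukey",
    "outlier_flags",
]


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a rank test."""

    statistic: float  # W+ (signed rank) or U1 (rank sum)
    z: float
    p: float
    n: int
    method: str

    def __iter__(self):
        # allow ``z, p = result`` unpacking alongside attribute access
        return iter((self.z, self.p))


def _signed_rank_stat(d: np.ndarray) -> tuple[float, float, float]:
    """W+ plus the null mean and sd of W+ for given |d| (midranks)."""
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(((counts**3 - counts) / 48.0).sum())
    return w_plus, mu, math.sqrt(var) if var > 0 else 0.0


def wilcoxon_signed_rank(
    x,
    y=None,
    method: str = "approx",
    zero_method: str = "wilcox",
) -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Parameters
    ----------
    x, y
        Paired samples (or ``x`` the differences directly).
    method
        ``"approx"``: tie-corrected normal approximation, reported as a
        signed z (positive when ``x`` tends to exceed ``y``).
        ``"exact"``: full enumeration of the 2^n sign assignments of
        the absolute-difference ranks; feasible for n up to ~20.
    zero_method
        ``"wilcox"`` drops zero differences before ranking (the
        default); ``"pratt"`` ranks them but removes their
        contribution from the statistic.

    With every difference zero there is no evidence either way and the
    convention ``z = 0, p = 1`` applies.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    if zero_method == "wilcox":
        d = d[d != 0]
    if d.size == 0 or np.all(d == 0):
        return RankTestResult(0.0, 0.0, 1.0, 0, method)
    if zero_method == "pratt":
        ranks = sps.rankdata(np.abs(d))
        keep = d != 0
        w_plus = float(ranks[d > 0].sum())
        n = d.size
        n_zero = int((~keep).sum())
        mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
        var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
        _, counts = np.unique(ranks[keep], return_counts=True)
        var -= float(((counts**3 - counts) / 48.0).sum())
        sd = math.sqrt(var) if var > 0 else 0.0
    else:
        w_plus, mu, sd = _signed_rank_stat(d)
        n = d.size
    if method == "approx":
        z = (w_plus - mu) / sd if sd > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        return RankTestResult(w_plus, z, min(p, 1.0), n, "approx")
    if method != "exact":
        raise ValueError("method must be 'approx' or 'exact'")
    # exact enumeration over sign assignments of the ranked |d|
    if zero_method == "pratt":
        ranks = sps.rankdata(np.abs(d))
        ranks = ranks[d != 0]  # zeros contribute to ranking only
    else:
        ranks = sps.rankdata(np.abs(d))
    m = ranks.size
    if m > 20:
        raise ValueError("exact enumeration limited to 20 non-zero pairs")
    obs_dev = abs(w_plus - mu)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=m):
        w = float(np.dot(signs, ranks))
        if abs(w - mu) >= obs_dev - 1e-12:
            count += 1
    p = count / 2**m
    z = (w_plus - mu) / sd if sd > 0 else 0.0
    return RankTestResult(w_plus, z, p, n, "exact")


def mann_whitney_u(x, y, method: str = "approx") -> RankTestResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    ``method="approx"`` uses the tie-corrected normal approximation
    with a signed z (positive when ``x`` tends to exceed ``y``);
    ``"exact"`` enumerates all group labelings (feasible for small
    n1 + n2) with the symmetric two-sided definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    sd = math.sqrt(var) if var > 0 else 0.0
    if method == "approx":
        z = (u1 - mu) / sd if sd > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z)) if sd > 0 else 1.0
        return RankTestResult(u1, z, min(p, 1.0), n, "approx")
    if method != "exact":
        raise ValueError("method must be 'approx' or 'exact'")
    if math.comb(n, n1) > 500_000:
        raise ValueError("exact enumeration infeasible for these sizes")
    obs_dev = abs(u1 - mu)
    offset = n1 * (n1 + 1) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        u = float(ranks[list(idx)].sum()) - offset
        total += 1
        if abs(u - mu) >= obs_dev - 1e-12:
            count += 1
    z = (u1 - mu) / sd if sd > 0 else 0.0
    return RankTestResult(u1, z, count / total, n, "exact")


def fdr_adjust(p_values, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``families`` optionally assigns each p-value to a correction
    family (e.g. one trained group's test battery); adjustment is then
    applied within each family independently.  Output is monotone in
    the input order of each family, capped at 1, and invariant under
    permutation of the inputs.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.empty_like(p)
    if families is None:
        families = np.zeros(p.size)
    families = np.asarray(families)
    for fam in pd.unique(families):
        mask = families == fam
        if mask.sum() == 1:
            out[mask] = p[mask]
        elif mask.any():
            out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def anova_with_tukey(
    data: pd.DataFrame,
    value: str,
    factors: list[str] | str,
    tukey_on: str | None = None,
):
    """Fixed-effects ANOVA with an optional Tukey HSD post hoc.

    Fits an additive model ``value ~ C(f1) + C(f2) + ...`` (no
    interactions, matching the pipeline's speed-by-season-and-phase
    use), returns the type-II ANOVA table and, when ``tukey_on`` (or a
    single factor) is given, the pairwise Tukey HSD table for that
    factor's level means.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if isinstance(factors, str):
        factors = [factors]
    if not factors:
        raise ValueError("at least one factor is required")
    for f in factors:
        levels = data[f].unique()
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
        if data.groupby(f)[value].count().min() < 2:
            raise ValueError(f"factor {f!r} needs >=2 observations per level")
    formula = f"{value} ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    tukey_factor = tukey_on or (factors[0] if len(factors) == 1 else None)
    tukey = None
    if tukey_factor is not None:
        res = pairwise_tukeyhsd(data[value], data[tukey_factor])
        tukey = pd.DataFrame(
            res.summary().data[1:], columns=res.summary().data[0]
        )
    return table, tukey


def outlier_flags(values) -> np.ndarray:
    """Flag values beyond 1.5*IQR from the quartiles.

    Quartiles use linear interpolation (numpy's default quantile
    rule).  Fences are strict: a value exactly on a fence is kept, so
    a constant vector (IQR = 0) flags nothing.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for quartile fences")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
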