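"""Shared statistical kernel.

Rank tests, correlation with p-values, Benjamini-Hochberg FDR control, a
moderated-t differential-expression test with empirical-Bayes variance
shrinkage, and hypergeometric over-representation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    p_value: float
    effect: float | None = None
    adjusted_p: float | None = None


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    normal approximation with tie and continuity correction otherwise.
    The reported effect is the difference of group means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    effect = float(x.mean() - y.mean())
    if np.unique(pooled).size == 1:
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0, effect=effect)
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)), effect=effect)


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a t-based two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(statistic=float(r), p_value=float(p), effect=float(r))


def correlation_p_from_r(r, n: int) -> np.ndarray:
    """Two-sided p for a correlation via t = r sqrt((n-2)/(1-r^2)) on n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    return 2.0 * sps.t.sf(np.abs(t), df=n - 2)


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for y with psi'(y) = x (monotone decreasing).
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) on log variances."""
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(z, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_deg(
    matrix: pd.DataFrame,
    groups,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated two-sample t-test between two groups.

    ``matrix`` is genes x samples on the log2 scale; ``groups`` assigns each
    sample to one of exactly two labels.  log2FC is the difference of group
    means (first label minus second, labels in sorted order).  Residual
    variances are shrunk toward a moment-fitted prior; BH adjustment across
    genes; the DEG flag applies |log2FC| > lfc_threshold and adjusted
    p < alpha.  ``prior_df=0`` recovers the ordinary equal-variance t-test.
    """
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    a = matrix.loc[:, groups == labels[0]].to_numpy(dtype=float)
    b = matrix.loc[:, groups == labels[1]].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    if prior_df is None:
        d0, s0_sq = _fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_sq = 0.0, 0.0
    else:
        d0 = float(prior_df)
        _, s0_sq = _fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=df_total)
    adj = benjamini_hochberg(p)
    out = pd.DataFrame(
        {
            "log2fc": diff,
            "t": t,
            "p_value": p,
            "adjusted_p": adj,
            "deg": (np.abs(diff) > lfc_threshold) & (adj < alpha),
        },
        index=matrix.index,
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def hypergeometric_ora(hit_genes, universe, gene_sets) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of hits in each gene set.

    ``gene_sets`` maps set name -> gene list (a GeneSetCollection works).
    Sets are intersected with the universe; BH adjustment across sets.
    """
    sets = getattr(gene_sets, "sets", gene_sets)
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    hits = set(hit_genes)
    if not hits <= uni:
        raise ValueError("hit genes must be a subset of the universe")
    rows = []
    for name, members in sets.items():
        in_uni = uni.intersection(members)
        k = len(in_uni & hits)
        big_k, big_n, n = len(in_uni), len(uni), len(hits)
        p = float(sps.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        expected = n * big_k / big_n
        fold = (k / expected) if expected > 0 else np.nan
        rows.append((name, big_k, k, fold, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "fold_enrichment", "p_value"])
    out["adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy()) if len(out) else []
    return out.set_index("set")


def kruskal_wallis(samples: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H test across >= 3 groups (midranks, tie correction)."""
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    arrs = [np.asarray(s, dtype=float) for s in samples]
    pooled = np.concatenate(arrs)
    if np.unique(pooled).size == 1:
        return TestResult(statistic=0.0, p_value=1.0)
    h, p = sps.kruskal(*arrs)
    return TestResult(statistic=float(h), p_value=float(p))


def pairwise_wilcoxon(values, labels) -> pd.DataFrame:
    """All pairwise two-group rank-sum tests with BH adjustment."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    lvls = sorted(pd.unique(labels))
    rows = []
    for i, gi in enumerate(lvls):
        for gj in lvls[i + 1:]:
            res = wilcoxon_rank_sum(values[labels == gi], values[labels == gj])
            rows.append((gi, gj, res.statistic, res.p_value, res.effect))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value", "effect"])
    if len(out):
        out["adjusted_p"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out
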