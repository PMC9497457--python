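"""Simplified weighted co-expression module detection.

Unsigned adjacency |cor|^beta with the soft power chosen by scale-free
topology fit, topological overlap similarity, average-linkage clustering of
1 - TOM with a static height cut, module eigengenes (first principal
component, mean loading oriented positive) and module-trait correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import correlation


@dataclass
class ModuleAssignment:
    module_of_gene: pd.Series  # module 0 = unassigned
    power: int
    eigengenes: pd.DataFrame  # samples x modules
    module_trait: pd.DataFrame | None = None
    genes_used: list[str] = field(default_factory=list)


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Per-node sum of off-diagonal adjacency."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    return a.sum(axis=1)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) ~ log10(mean k) over connectivity bins."""
    k = k[k > 0]
    if k.size < 4:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    xs, ys = np.array(xs), np.array(ys)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    r2 = 1.0 - resid.var() / ys.var()
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(
    matrix: pd.DataFrame, powers=range(1, 21), target_r2: float = 0.85
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose adjacency gives signed scale-free R^2 >= target.

    Falls back to the argmax power with a warning when no power reaches the
    target.  Returns the power and the per-power fit table.
    """
    if matrix.shape[0] < 20:
        raise ValueError("need at least 20 genes to assess scale-free topology")
    cor = np.abs(np.corrcoef(matrix.to_numpy(dtype=float)))
    cor = np.nan_to_num(cor, nan=0.0)
    rows = []
    for beta in powers:
        k = connectivity(cor**beta)
        rows.append((beta, scale_free_fit(k), float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "sft_r2", "mean_k"]).set_index("power")
    ok = table.index[table["sft_r2"] >= target_r2]
    if len(ok):
        return int(ok[0]), table
    # sample-size-based fallback (unsigned-network convention) when the data
    # show no scale-free topology, e.g. planted-block fixtures
    n = matrix.shape[1]
    fallback = 6 if n >= 40 else 7 if n >= 30 else 8 if n >= 20 else 9
    warnings.warn(
        f"no power reached scale-free R^2 {target_r2}; "
        f"using the sample-size default power {fallback}",
        stacklevel=2,
    )
    return fallback, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap: (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j)+1-a_ij)."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def module_eigengene(module_expr: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component over samples of per-gene standardized rows.

    The sign is fixed so the mean gene loading is positive.  Returns the
    unit-norm sample vector and its explained-variance fraction.
    """
    x = module_expr.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = vt[0]
    if u[:, 0].mean() < 0:
        eig = -eig
    explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return pd.Series(eig, index=module_expr.columns), explained


def _gap_cut_height(heights: np.ndarray) -> float:
    """Static cut at the midpoint of the largest gap between merge heights.

    Coherent modules produce a dendrogram whose within-module merges sit well
    below the between-module merges; the widest gap in the sorted merge
    heights marks that boundary.  Only the upper half of merges is searched
    so that early, densely packed merges cannot attract the cut.
    """
    hs = np.sort(heights)
    lo = len(hs) // 2
    gaps = np.diff(hs[lo:])
    if gaps.size == 0:
        return float(hs[-1])
    i = int(np.argmax(gaps))
    return float((hs[lo + i] + hs[lo + i + 1]) / 2.0)


def detect_modules(
    matrix: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    top_variance_frac: float = 0.25,
    min_module_size: int = 30,
    power: int | None = None,
    cut_height_quantile: float | None = None,
    coherence_ratio: float = 1.5,
) -> ModuleAssignment:
    """Detect co-expression modules on the top-variance genes.

    Genes are filtered to the top ``top_variance_frac`` by variance; the tree
    of 1 - TOM is cut statically, by default at the largest gap between merge
    heights (pass ``cut_height_quantile`` to cut at a fixed quantile
    instead); clusters below ``min_module_size``, or whose mean within-cluster
    TOM is not at least ``coherence_ratio`` times the global off-diagonal
    mean, go to module 0 (unassigned); remaining modules are renumbered by
    decreasing size.  When ``traits`` is given (samples x indicator/numeric
    columns), the eigengene of each module is correlated with every trait.
    """
    variances = matrix.var(axis=1)
    n_keep = max(int(np.ceil(top_variance_frac * matrix.shape[0])), 2)
    genes = variances.sort_values(ascending=False).index[:n_keep]
    if len(genes) < 2 * min_module_size:
        raise ValueError("too few genes after variance filtering for the module size")
    sub = matrix.loc[genes]
    if power is None:
        power, _ = pick_soft_threshold(sub)
    cor = np.abs(np.corrcoef(sub.to_numpy(dtype=float)))
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    tom = tom_similarity(cor**power)
    d = 1.0 - tom
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False), "average")
    if cut_height_quantile is not None:
        cut = float(np.quantile(z[:, 2], cut_height_quantile))
    else:
        cut = _gap_cut_height(z[:, 2])
    raw = fcluster(z, t=cut, criterion="distance")

    offdiag = tom[~np.eye(len(genes), dtype=bool)]
    global_mean_tom = float(offdiag.mean()) if offdiag.size else 0.0
    sizes = pd.Series(raw).value_counts()
    keep = []
    for cl in sizes.index[sizes >= min_module_size]:
        idx = np.flatnonzero(raw == cl)
        within = tom[np.ix_(idx, idx)][~np.eye(len(idx), dtype=bool)]
        if within.mean() >= coherence_ratio * global_mean_tom:
            keep.append(cl)
    order = sizes.loc[keep].sort_values(ascending=False).index
    relabel = {old: i + 1 for i, old in enumerate(order)}
    labels = pd.Series(
        [relabel.get(c, 0) for c in raw], index=genes, name="module"
    )

    eigs = {}
    for mod in sorted(set(labels) - {0}):
        eigs[f"ME{mod}"], _ = module_eigengene(sub.loc[labels.index[labels == mod]])
    eigengenes = pd.DataFrame(eigs, index=sub.columns)

    module_trait = None
    if traits is not None and not eigengenes.empty:
        rows = []
        for me in eigengenes.columns:
            for tr in traits.columns:
                res = correlation(eigengenes[me].to_numpy(),
                                  traits[tr].to_numpy(dtype=float))
                rows.append((me, tr, res.statistic, res.p_value))
        module_trait = pd.DataFrame(rows, columns=["module", "trait", "r", "p_value"])
    return ModuleAssignment(
        module_of_gene=labels,
        power=int(power),
        eigengenes=eigengenes,
        module_trait=module_trait,
        genes_used=list(genes),
    )
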