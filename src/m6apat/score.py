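"""Per-sample m6A signature scoring (m6Ascore).

The score of a sample is the sum of its first two principal-component
coordinates from a PCA of the signature-gene expression profile.  Samples
are then split into high/low score groups and compared across pattern,
cluster and subtype labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as stats_core


@dataclass
class M6AScoreTable:
    table: pd.DataFrame  # index sample; columns score, pc1, pc2
    scaled: bool
    genes_used: list[str]
    split_rule: str | None = None
    threshold: float | None = None

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def compute_m6ascore(
    matrix: pd.DataFrame, signature_genes, scale: bool = True
) -> M6AScoreTable:
    """PCA of signature-gene rows over samples; score = PC1 + PC2.

    Gene rows are centered (and, by default, scaled to unit variance) before
    the PCA.  Each component's sign is oriented so it correlates positively
    with the per-sample mean signature expression, making the score
    deterministic.
    """
    genes = [g for g in signature_genes if g in matrix.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 signature genes present in the matrix")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = matrix.loc[genes].to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if scale:
        sd = x.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        x = x / sd
    # PCA with samples as observations: SVD of the samples-x-genes matrix
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    pcs = u[:, :2] * s[:2]
    if pcs.shape[1] < 2:
        pcs = np.column_stack([pcs, np.zeros(pcs.shape[0])])
    mean_expr = matrix.loc[genes].mean(axis=0).to_numpy()
    for k in range(2):
        if np.std(pcs[:, k]) > 0:
            r = np.corrcoef(pcs[:, k], mean_expr)[0, 1]
            if np.isfinite(r) and r < 0:
                pcs[:, k] = -pcs[:, k]
    table = pd.DataFrame(
        {"score": pcs[:, 0] + pcs[:, 1], "pc1": pcs[:, 0], "pc2": pcs[:, 1]},
        index=matrix.columns,
    )
    return M6AScoreTable(table=table, scaled=scale, genes_used=genes)


def split_by_score(score_table: M6AScoreTable, rule: str = "median") -> pd.Series:
    """Label samples 'high' (score > threshold) or 'low'; records the rule."""
    scores = score_table.scores
    if scores.empty:
        raise ValueError("empty score table")
    if np.ptp(scores.to_numpy()) == 0:
        raise ValueError("all scores identical; no split possible")
    if rule == "median":
        threshold = float(scores.median())
    elif rule == "mean":
        threshold = float(scores.mean())
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    score_table.split_rule = rule
    score_table.threshold = threshold
    groups = pd.Series(
        np.where(scores > threshold, "high", "low"), index=scores.index, name="score_group"
    )
    score_table.table["score_group"] = groups
    return groups


def compare_scores_across(labels, score_table: M6AScoreTable) -> dict:
    """Omnibus and pairwise nonparametric comparison of scores across groups.

    Two groups: rank-sum test.  Three or more: Kruskal-Wallis omnibus, with
    BH-adjusted pairwise rank-sum tests when the omnibus p < 0.05.
    """
    labels = pd.Series(np.asarray(labels), index=score_table.scores.index)
    lvls = sorted(labels.unique())
    if len(lvls) < 2:
        raise ValueError("need at least 2 labeled groups")
    vals = score_table.scores.to_numpy()
    arrays = [vals[(labels == g).to_numpy()] for g in lvls]
    if len(lvls) == 2:
        omnibus = stats_core.wilcoxon_rank_sum(arrays[0], arrays[1])
        pairwise = None
    else:
        omnibus = stats_core.kruskal_wallis(arrays)
        pairwise = (
            stats_core.pairwise_wilcoxon(vals, labels.to_numpy())
            if omnibus.p_value < 0.05
            else None
        )
    medians = {g: float(np.median(a)) for g, a in zip(lvls, arrays)}
    return {"omnibus": omnibus, "pairwise": pairwise, "group_medians": medians}


def crosstab_alluvial(annotation: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Counts of every combination of the requested label columns.

    Suitable for exporting an alluvial/Sankey-style flow table; the counts
    sum to the cohort size.
    """
    if columns is None:
        columns = [
            c for c in ("subtype", "pattern", "lncrna_cluster", "score_group")
            if c in annotation.columns
        ]
    missing = [c for c in columns if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation is missing column(s): {missing}")
    if not columns:
        raise ValueError("no label columns to cross-tabulate")
    out = (
        annotation.groupby(list(columns), dropna=False, observed=True)
        .size()
        .reset_index(name="count")
    )
    return out
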