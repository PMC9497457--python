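"""Resampled consensus clustering with PAC-based model selection.

For each candidate K, samples are repeatedly subsampled without replacement
and clustered by average-linkage hierarchical clustering on a
1 - Pearson-correlation distance; the consensus matrix entry (i, j) is the
fraction of co-sampled runs in which i and j co-cluster.  The number of
clusters is chosen by the lowest proportion of ambiguously clustered pairs
(PAC): the mass of the consensus-value CDF inside an intermediate interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ConsensusResult:
    k_range: list[int]
    consensus: dict[int, np.ndarray]
    pac: dict[int, float]
    chosen_k: int
    labels: pd.Series
    low_confidence: bool = False
    sample_ids: list[str] = field(default_factory=list)


def _corr_distance(columns: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance between columns of a features-x-n array."""
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(columns.T)
    c = np.nan_to_num(c, nan=0.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return squareform(d, checks=False)


def _hclust_labels(columns: np.ndarray, k: int) -> np.ndarray:
    z = linkage(_corr_distance(columns), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def consensus_matrix(
    matrix: pd.DataFrame,
    k: int,
    n_reps: int = 1000,
    p_item: float = 0.8,
    seed: int | np.random.Generator = 0,
    center_genes: bool = True,
) -> np.ndarray:
    """Consensus matrix over subsampled hierarchical clusterings at K = k.

    ``center_genes`` median-centers each feature row first (the usual
    preparation for correlation-based clustering of expression profiles, so
    inter-sample correlation reflects relative rather than absolute level).
    """
    x = matrix.to_numpy(dtype=float)
    if center_genes:
        x = x - np.median(x, axis=1, keepdims=True)
    n = x.shape[1]
    if k < 2 or k >= n:
        raise ValueError("K must satisfy 2 <= K < n_samples")
    if n < 2 * k:
        raise ValueError("need at least 2*K samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = int(np.ceil(p_item * n))
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(n_reps):
        idx = rng.choice(n, size=n_sub, replace=False)
        labels = _hclust_labels(x[:, idx], k)
        same = labels[:, None] == labels[None, :]
        ix = np.ix_(idx, idx)
        together[ix] += same
        sampled[ix] += 1.0
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum()) // 2} sample pair(s) never co-sampled; consensus set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.maximum(sampled, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    return consensus


def pac(consensus: np.ndarray, u1: float = 0.1, u2: float = 0.9) -> float:
    """Proportion of ambiguously clustered pairs: F(u2) - F(u1) of the
    empirical CDF of strictly-upper-triangle consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > u1) & (vals <= u2)))


def select_k_and_label(
    matrix: pd.DataFrame,
    k_range=range(2, 7),
    n_reps: int = 1000,
    p_item: float = 0.8,
    seed: int = 0,
    u1: float = 0.1,
    u2: float = 0.9,
    center_genes: bool = True,
) -> ConsensusResult:
    """Run consensus clustering over K, choose the lowest-PAC K, label samples.

    Ties in PAC resolve to the smaller K.  When even the best PAC exceeds 0.5
    the result is flagged low-confidence.  Final labels come from
    average-linkage clustering of 1 - consensus at the chosen K.
    """
    ks = sorted(k_range)
    n = matrix.shape[1]
    if not ks or ks[0] < 2 or ks[-1] >= n:
        raise ValueError("K range must lie within (1, n_samples)")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(ks))
    consensus: dict[int, np.ndarray] = {}
    pac_of: dict[int, float] = {}
    for k, child in zip(ks, children):
        cm = consensus_matrix(
            matrix, k, n_reps=n_reps, p_item=p_item,
            seed=np.random.default_rng(child), center_genes=center_genes,
        )
        consensus[k] = cm
        pac_of[k] = pac(cm, u1=u1, u2=u2)
    chosen = min(ks, key=lambda k: (pac_of[k], k))
    d = 1.0 - consensus[chosen]
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(np.clip((d + d.T) / 2.0, 0.0, None), checks=False), method="average")
    labels = fcluster(z, t=chosen, criterion="maxclust")
    return ConsensusResult(
        k_range=ks,
        consensus=consensus,
        pac=pac_of,
        chosen_k=chosen,
        labels=pd.Series(labels, index=matrix.columns, name="cluster"),
        low_confidence=min(pac_of.values()) > 0.5,
        sample_ids=list(matrix.columns),
    )
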