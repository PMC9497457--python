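"""Sample-wise gene-set scoring and group-difference reporting.

Implements single-sample GSEA (rank-weighted running-sum integral) and GSVA
(Gaussian-kernel CDF statistic with a KS-like walk), the GMT format, and the
per-row two-group / multi-group nonparametric comparison used for immune-cell,
immune-reaction, HLA and regulator panels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core


@dataclass
class GeneSetCollection:
    """Named gene sets (immune cells, reactions, pathways)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, genes) -> "GeneSetCollection":
        """Intersect every set with ``genes``, dropping empty sets (warned)."""
        genes = set(genes)
        kept, dropped = {}, []
        for name, members in self.sets.items():
            inter = [g for g in members if g in genes]
            if inter:
                kept[name] = inter
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"dropped {len(dropped)} set(s) with no matrix overlap: "
                          f"{dropped[:5]}", stacklevel=2)
        return GeneSetCollection(sets=kept,
                                 descriptions={k: self.descriptions.get(k, "") for k in kept},
                                 provenance=self.provenance)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, tab-separated members per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicated set name {name!r}")
            members = [m for m in members if m]
            sets[name] = list(dict.fromkeys(members))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *members]) + "\n")


def ssgsea_scores(
    matrix: pd.DataFrame,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """Single-sample GSEA enrichment scores (sets x samples).

    Per sample, genes are ranked by expression (midranks for ties; the top
    gene has rank N).  Walking down the ranking, in-set genes add
    rank^alpha / sum(in-set rank^alpha) and out-set genes subtract
    1/(N - |S|); the score is the sum of the running walk (the area under the
    walk).  With ``normalize`` the whole score matrix is divided by its
    global max - min, so the output range is exactly 1.
    """
    x = matrix.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    coll = sets.restrict(matrix.index)
    gene_pos = {g: i for i, g in enumerate(matrix.index)}
    masks = {}
    for name, members in coll.sets.items():
        if len(members) >= n_genes:
            raise ValueError(f"set {name!r} covers every gene; out-set is empty")
        m = np.zeros(n_genes, dtype=bool)
        m[[gene_pos[g] for g in members]] = True
        masks[name] = m

    # midranks, top gene gets rank N
    ranks = sps.rankdata(x, axis=0)
    order = np.argsort(-x, axis=0, kind="stable")
    scores = np.empty((len(masks), n_samples))
    for j in range(n_samples):
        rv = ranks[:, j] ** alpha
        ord_j = order[:, j]
        for si, (name, mask) in enumerate(masks.items()):
            in_sorted = mask[ord_j]
            w = np.where(in_sorted, rv[ord_j], 0.0)
            denom_in = w.sum()
            dec = 1.0 / (n_genes - mask.sum())
            steps = np.where(in_sorted, w / denom_in, -dec)
            scores[si, j] = np.cumsum(steps).sum()
    out = pd.DataFrame(scores, index=list(masks), columns=matrix.columns)
    if normalize:
        rng = out.to_numpy().max() - out.to_numpy().min()
        if rng == 0:
            warnings.warn("degenerate score matrix; normalization skipped", stacklevel=2)
        else:
            out = out / rng
    out.attrs["method"] = "ssgsea"
    return out


def gsva_scores(matrix: pd.DataFrame, sets: GeneSetCollection, tau: float = 1.0) -> pd.DataFrame:
    """GSVA enrichment scores (sets x samples).

    Per gene, expression is transformed to a relative statistic via a
    Gaussian-kernel CDF across samples (bandwidth = sample SD / 4); per
    sample, genes are ranked by that statistic and given the symmetric rank
    statistic |N/2 - rank|; a KS-like walk weighted by statistic^tau yields
    the score as the signed sum of the maximum positive and negative
    deviations.
    """
    x = matrix.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("GSVA needs at least 3 samples for density estimation")
    coll = sets.restrict(matrix.index)
    gene_pos = {g: i for i, g in enumerate(matrix.index)}

    sd = x.std(axis=1, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    z = np.empty_like(x)
    for g in range(n_genes):
        if sd[g] == 0:
            z[g] = 0.5
        else:
            diffs = (x[g][:, None] - x[g][None, :]) / h[g]
            z[g] = sps.norm.cdf(diffs).mean(axis=1)

    # rank genes per sample by z, descending; position 1 = largest statistic
    pos = np.empty_like(z)
    for j in range(n_samples):
        pos[:, j] = sps.rankdata(-z[:, j], method="ordinal")
    stat = np.abs(n_genes / 2.0 - pos)
    # constant genes carry no cross-sample information: zero walk weight
    stat[sd == 0] = 0.0

    scores = np.empty((len(coll.sets), n_samples))
    for si, (name, members) in enumerate(coll.sets.items()):
        mask = np.zeros(n_genes, dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        if mask.all():
            raise ValueError(f"set {name!r} covers every gene; out-set is empty")
        for j in range(n_samples):
            ord_j = np.argsort(pos[:, j], kind="stable")
            in_sorted = mask[ord_j]
            w = np.where(in_sorted, stat[ord_j, j] ** tau, 0.0)
            denom = w.sum()
            dec = 1.0 / (n_genes - mask.sum())
            if denom == 0:
                scores[si, j] = 0.0
                continue
            walk = np.cumsum(np.where(in_sorted, w / denom, -dec))
            scores[si, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    out = pd.DataFrame(scores, index=list(coll.sets), columns=matrix.columns)
    out.attrs["method"] = "gsva"
    return out


def group_difference_report(
    scores_or_expr: pd.DataFrame, labels, family: str = ""
) -> pd.DataFrame:
    """Per-row nonparametric group comparison with BH control within the family.

    Two groups: two-sided rank-sum per row (effect = mean difference).
    Three or more: Kruskal-Wallis per row.
    """
    labels = pd.Series(np.asarray(labels), index=scores_or_expr.columns)
    lvls = sorted(labels.unique())
    if len(lvls) < 2:
        raise ValueError("need at least 2 groups")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("a group has no samples")
    rows = []
    for name, row in scores_or_expr.iterrows():
        vals = row.to_numpy(dtype=float)
        if len(lvls) == 2:
            res = stats_core.wilcoxon_rank_sum(
                vals[(labels == lvls[0]).to_numpy()], vals[(labels == lvls[1]).to_numpy()]
            )
        else:
            res = stats_core.kruskal_wallis(
                [vals[(labels == g).to_numpy()] for g in lvls]
            )
        rows.append((name, res.statistic, res.p_value, res.effect))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "p_value", "effect"])
    out["adjusted_p"] = stats_core.benjamini_hochberg(out["p_value"].to_numpy())
    out.attrs["family"] = family
    out.attrs["test"] = "wilcoxon" if len(lvls) == 2 else "kruskal-wallis"
    return out.set_index("feature")
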