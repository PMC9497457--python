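"""Expression-matrix I/O, gene collapsing, cohort merging and batch correction.

Expression matrices are pandas DataFrames: rows = gene ids, columns = sample
ids, values = log2 expression.  Sample annotations are DataFrames indexed by
sample id with at least ``group`` (case/control) and ``batch`` columns.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def read_expression(path) -> pd.DataFrame:
    """Read a genes-x-samples TSV (first column gene id, header sample ids)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = sample_ids
    out = df.apply(pd.to_numeric, errors="coerce")
    if out.isna().to_numpy().any():
        bad = np.argwhere(out.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric value at gene {out.index[bad[0]]!r}, sample {out.columns[bad[1]]!r}"
        )
    out.index.name = df.index.name or "gene"
    return out


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis(matrix.index.name or "gene").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if ann.index.duplicated().any():
        raise ValueError("duplicate sample ids in annotation")
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.rename_axis(annotation.index.name or "sample").to_csv(path, sep="\t")


def collapse_duplicate_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated gene ids to their element-wise median row.

    Output order is the order of first occurrence, mirroring the convention of
    taking the median probe value when several probes map to one symbol.
    """
    if not matrix.index.duplicated().any():
        return matrix.copy()
    order = matrix.index.drop_duplicates()
    collapsed = matrix.groupby(level=0, sort=False).median()
    return collapsed.loc[order]


def merge_cohorts(
    matrices: list[pd.DataFrame], batch_labels: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-concatenate cohorts on their common gene set, recording batch."""
    if len(matrices) != len(batch_labels):
        raise ValueError("one batch label per matrix required")
    if not matrices:
        raise ValueError("no matrices to merge")
    common = matrices[0].index
    for m in matrices[1:]:
        common = common.intersection(m.index)
    common = matrices[0].index[matrices[0].index.isin(common)]
    if len(common) == 0:
        raise ValueError("empty gene intersection across cohorts")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.columns)
    if len(set(all_samples)) != len(all_samples):
        clash = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"clashing sample ids across cohorts: {clash}")
    merged = pd.concat([m.loc[common] for m in matrices], axis=1)
    batch = pd.Series(
        np.repeat(batch_labels, [m.shape[1] for m in matrices]), index=merged.columns
    )
    annotation = pd.DataFrame({"batch": batch})
    annotation.index.name = "sample"
    return merged, annotation


def correct_batches(
    matrix: pd.DataFrame, annotation: pd.DataFrame, max_iter: int = 100, tol: float = 1e-6
) -> pd.DataFrame:
    """Parametric empirical-Bayes batch correction (ComBat-style, batch only).

    Per gene: standardize by the grand mean and pooled within-batch variance;
    estimate per-batch location and scale; shrink both toward moment-matched
    priors (normal prior for location, inverse-gamma for scale); remove and
    rescale; restore the grand mean exactly.  Genes with zero pooled variance
    are left unadjusted with a warning.
    """
    if not matrix.columns.equals(annotation.index):
        annotation = annotation.loc[matrix.columns]
    batches = pd.Categorical(annotation["batch"])
    levels = list(batches.categories)
    if len(levels) < 2:
        raise ValueError("batch correction requires at least 2 batches")
    masks = {b: (batches == b) for b in levels}
    sizes = {b: int(m.sum()) for b, m in masks.items()}
    for b, n in sizes.items():
        if n < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")

    x = matrix.to_numpy(dtype=float)
    n_total = x.shape[1]
    batch_means = np.column_stack([x[:, masks[b]].mean(axis=1) for b in levels])
    weights = np.array([sizes[b] / n_total for b in levels])
    grand = batch_means @ weights
    resid = x - batch_means[:, batches.codes]
    pooled_var = (resid**2).mean(axis=1)
    keep = pooled_var > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} zero-variance gene(s) left unadjusted", stacklevel=2
        )
    out = x.copy()
    sd = np.sqrt(pooled_var[keep])
    z = (x[keep] - grand[keep, None]) / sd[:, None]

    adj = np.empty_like(z)
    for i, b in enumerate(levels):
        zb = z[:, masks[b]]
        nb = sizes[b]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, v = d_hat.mean(), d_hat.var(ddof=1)
        if v <= 0:
            a_pr, b_pr = np.inf, np.inf
        else:
            a_pr = (2.0 * v + m**2) / v
            b_pr = (m * v + m**3) / v
        g_star, d_star = g_hat.copy(), d_hat.copy()
        for _ in range(max_iter):
            g_new = (nb * t2 * g_hat + d_star * g_bar) / (nb * t2 + d_star)
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            if np.isinf(a_pr):
                d_new = np.full_like(d_star, m)
            else:
                d_new = (b_pr + 0.5 * ss) / (nb / 2.0 + a_pr - 1.0)
            change = max(
                np.max(np.abs(g_new - g_star) / np.maximum(np.abs(g_star), 1e-12)),
                np.max(np.abs(d_new - d_star) / np.maximum(np.abs(d_star), 1e-12)),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        adj[:, masks[b]] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    corrected = adj * sd[:, None] + grand[keep, None]
    # enforce exact grand-mean preservation (shrinkage leaves a tiny residual)
    corrected += (x[keep].mean(axis=1) - corrected.mean(axis=1))[:, None]
    out[keep] = corrected
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
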