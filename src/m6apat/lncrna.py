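"""Regulator-related lncRNA selection by correlation thresholding.

A lncRNA is called related to a modification (m6A or m5C) when its expression
correlates with at least one regulator of that modification at |r| > 0.4 and
p < 0.001 (Pearson; strict inequalities).  The m6A- and m5C-related sets are
intersected to obtain dual-modification lncRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import RegulatorCatalog
from .stats import correlation_p_from_r


@dataclass
class LncRNALinkSet:
    """Retained lncRNAs with every regulator pair that passed both thresholds."""

    links: dict[str, list[tuple[str, float, float]]]
    modification: str
    r_threshold: float = 0.4
    p_threshold: float = 0.001

    def lncrna_ids(self) -> list[str]:
        return sorted(self.links)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lnc, reg, r, p)
            for lnc, pairs in self.links.items()
            for reg, r, p in pairs
        ]
        return pd.DataFrame(rows, columns=["lncrna", "regulator", "r", "p_value"])


def select_related_lncrnas(
    matrix: pd.DataFrame,
    lncrna_ids,
    catalog: RegulatorCatalog,
    modification: str,
    r_thresh: float = 0.4,
    p_thresh: float = 0.001,
) -> LncRNALinkSet:
    """Correlate every lncRNA with every regulator of one modification.

    A lncRNA is retained iff at least one pair satisfies |r| > r_thresh and
    p < p_thresh; all passing pairs are stored.  lncRNAs or regulators absent
    from the matrix are skipped with a warning.
    """
    regs = [g for g in catalog.genes(modification=modification)]
    present_regs = [g for g in regs if g in matrix.index]
    if not present_regs:
        raise ValueError(f"no {modification} regulators found in the matrix")
    if len(present_regs) < len(regs):
        warnings.warn(
            f"{len(regs) - len(present_regs)} {modification} regulator(s) absent "
            "from the matrix; skipped",
            stacklevel=2,
        )
    lncrna_ids = list(lncrna_ids)
    present_lncs = [g for g in lncrna_ids if g in matrix.index]
    if len(present_lncs) < len(lncrna_ids):
        warnings.warn(
            f"{len(lncrna_ids) - len(present_lncs)} lncRNA id(s) absent from the "
            "matrix; skipped",
            stacklevel=2,
        )
    n = matrix.shape[1]
    lx = matrix.loc[present_lncs].to_numpy(dtype=float)
    rx = matrix.loc[present_regs].to_numpy(dtype=float)

    def _std_rows(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        sd[sd == 0] = np.nan
        return a / sd

    r = (_std_rows(lx) @ _std_rows(rx).T) / n
    p = correlation_p_from_r(r, n)
    passing = (np.abs(r) > r_thresh) & (p < p_thresh)
    links: dict[str, list[tuple[str, float, float]]] = {}
    for i, lnc in enumerate(present_lncs):
        pairs = [
            (present_regs[j], float(r[i, j]), float(p[i, j]))
            for j in np.flatnonzero(passing[i])
        ]
        if pairs:
            links[lnc] = pairs
    return LncRNALinkSet(
        links=links, modification=modification, r_threshold=r_thresh, p_threshold=p_thresh
    )


def intersect_link_sets(a: LncRNALinkSet, b: LncRNALinkSet) -> list[str]:
    """Sorted lncRNA ids retained in both link sets."""
    return sorted(set(a.links) & set(b.links))
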