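"""Packaged catalogs of RNA-methylation regulators and diagnostic signatures.

Two catalogs ship with the package: 26 N6-methyladenosine (m6A) regulators
(9 writers / 3 erasers / 14 readers) and 14 5-methylcytosine (m5C) regulators
(10 writers / 3 erasers / 1 reader).  "Writer" = methyltransferase,
"eraser" = demethylase, "reader" = methylation-binding protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

ROLES = ("writer", "eraser", "reader")
MODIFICATIONS = ("m6A", "m5C")


@dataclass(frozen=True)
class RegulatorEntry:
    gene: str
    modification: str
    role: str


@dataclass
class RegulatorCatalog:
    """A named list of regulator genes with modification and role tags."""

    entries: list[RegulatorEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.role not in ROLES:
                raise ValueError(f"unknown role {e.role!r} for {e.gene}")
            if e.modification not in MODIFICATIONS:
                raise ValueError(f"unknown modification {e.modification!r} for {e.gene}")
            key = (e.gene, e.modification)
            if key in seen:
                raise ValueError(f"duplicate catalog entry {key}")
            seen.add(key)

    def genes(self, modification: str | None = None, role: str | None = None) -> list[str]:
        return [
            e.gene
            for e in self.entries
            if (modification is None or e.modification == modification)
            and (role is None or e.role == role)
        ]

    def role_counts(self, modification: str) -> dict[str, int]:
        counts = {r: 0 for r in ROLES}
        for e in self.entries:
            if e.modification == modification:
                counts[e.role] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene, e.modification, e.role) for e in self.entries],
            columns=["gene", "modification", "role"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegulatorCatalog":
        return cls([RegulatorEntry(r.gene, r.modification, r.role) for r in df.itertuples()])


def _load_tsv(name: str) -> RegulatorCatalog:
    with resources.files("m6apat.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return RegulatorCatalog.from_frame(df)


def load_m6a_catalog() -> RegulatorCatalog:
    """The 26 m6A regulators (9 writers, 3 erasers, 14 readers)."""
    return _load_tsv("m6a_regulators.tsv")


def load_m5c_catalog() -> RegulatorCatalog:
    """The 14 m5C regulators (10 writers, 3 erasers, 1 reader)."""
    return _load_tsv("m5c_regulators.tsv")


def load_combined_catalog() -> RegulatorCatalog:
    return RegulatorCatalog(load_m6a_catalog().entries + load_m5c_catalog().entries)


def load_diagnostic_signatures() -> dict[str, list[str]]:
    """Published diagnostic signatures: 14 m6A regulators and 8 lncRNAs."""
    with resources.files("m6apat.data").joinpath("diagnostic_signatures.json").open() as fh:
        return json.load(fh)
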