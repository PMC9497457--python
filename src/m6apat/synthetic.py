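"""Synthetic case/control transcriptome cohorts with known ground truth.

The generator emulates a merged multi-batch microarray study of an
inflammatory disease: log2-scale Gaussian expression; additive per-gene
per-batch location shifts and multiplicative dispersion; a case-vs-control
shift on a subset of diagnostic regulator genes; latent case-only molecular
patterns expressed as disjoint regulator blocks; lncRNAs constructed to hit a
target Pearson correlation with a regulator; and immune-signature gene blocks
whose set-level activity is elevated in chosen patterns.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import load_m5c_catalog, load_m6a_catalog
from .enrichment import GeneSetCollection

IMMUNE_CELL_TYPES = [
    "Activated B cell", "Activated CD4 T cell", "Activated CD8 T cell",
    "Activated dendritic cell", "CD56bright natural killer cell",
    "CD56dim natural killer cell", "Eosinophil", "Gamma delta T cell",
    "Immature B cell", "Immature dendritic cell", "Macrophage", "Mast cell",
    "MDSC", "Monocyte", "Natural killer cell", "Natural killer T cell",
    "Neutrophil", "Plasmacytoid dendritic cell", "Regulatory T cell",
    "T follicular helper cell", "Type 1 T helper cell",
    "Type 17 T helper cell", "Type 2 T helper cell",
]

IMMUNE_REACTIONS = [
    "Antigen Processing and Presentation", "Antimicrobials",
    "BCR Signaling Pathway", "Chemokine Receptors", "Chemokines",
    "Cytokine Receptors", "Cytokines", "Interferon Receptors", "Interferons",
    "Interleukin Receptors", "Interleukins",
    "Natural Killer Cell Cytotoxicity", "TCR Signaling Pathway",
    "TGFb Family Members", "TGFb Family Member Receptors",
    "TNF Family Members", "TNF Family Member Receptors",
]

CLINICAL_SUBTYPES = ["oligoarticular", "polyarticular", "systemic", "ERA"]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the merged study design: 196 cases and 89 controls pooled
    from 5 batches, 26 m6A regulator genes, 3 latent case patterns.  Effect
    sizes are in log2 units.
    """

    n_cases: int = 196
    n_controls: int = 89
    n_batches: int = 5
    batch_shift_sd: float = 0.5
    batch_scale_sd: float = 0.2
    n_genes: int = 2000
    n_regulators: int = 26
    n_lncrnas: int = 100
    n_patterns: int = 3
    pattern_effect: float = 2.0
    case_effect: float = 1.5
    n_diagnostic: int = 10
    lncrna_link_r: float = 0.6
    lncrna_linked_frac: float = 0.6
    noise_sd: float = 0.5
    immune_effect: float = 1.0
    immune_set_size: int = 15
    include_m5c: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cases", "n_controls", "n_batches", "n_genes",
                     "n_regulators", "n_lncrnas", "n_patterns",
                     "n_diagnostic", "immune_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.n_patterns < 2:
            raise ValueError("n_patterns must be >= 2")
        n_m5c = 14 if self.include_m5c else 0
        n_immune = (len(IMMUNE_CELL_TYPES) + len(IMMUNE_REACTIONS)) * self.immune_set_size
        if self.n_regulators + n_m5c + self.n_lncrnas + n_immune > self.n_genes:
            raise ValueError(
                "n_genes too small for n_regulators + n_lncrnas + immune signature genes"
            )
        if not 0 < self.lncrna_link_r < 1:
            raise ValueError("lncrna_link_r must lie strictly between 0 and 1")
        if not 0 <= self.lncrna_linked_frac <= 1:
            raise ValueError("lncrna_linked_frac must lie in [0, 1]")
        if self.n_diagnostic > self.n_regulators:
            raise ValueError("n_diagnostic cannot exceed n_regulators")
        for name in ("batch_shift_sd", "batch_scale_sd", "noise_sd",
                     "pattern_effect", "case_effect", "immune_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _pattern_names(n: int) -> list[str]:
    return list(string.ascii_uppercase[:n])


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    pattern_of_sample: dict[str, str]
    diagnostic_genes: list[str]
    linked_lncrnas: dict[str, list[str]]
    batch_of_sample: dict[str, str]
    immune_up_sets: dict[str, list[str]]
    immune_set_genes: dict[str, list[str]]
    pattern_blocks: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_names(config: SimulationConfig) -> tuple[list[str], dict[str, list[str]]]:
    m6a = load_m6a_catalog().genes()
    if config.n_regulators == len(m6a):
        regulators = m6a
    else:
        regulators = [f"REG{i + 1:03d}" for i in range(config.n_regulators)]
    m5c = load_m5c_catalog().genes() if config.include_m5c else []
    lncrnas = [f"LNC{i + 1:04d}" for i in range(config.n_lncrnas)]
    set_names = IMMUNE_CELL_TYPES + IMMUNE_REACTIONS
    immune: list[str] = []
    set_genes: dict[str, list[str]] = {}
    for si, name in enumerate(set_names):
        block = [f"IMM{si * config.immune_set_size + j + 1:05d}"
                 for j in range(config.immune_set_size)]
        set_genes[name] = block
        immune.extend(block)
    n_fill = config.n_genes - len(regulators) - len(m5c) - len(lncrnas) - len(immune)
    filler = [f"GENE{i + 1:05d}" for i in range(n_fill)]
    genes = regulators + m5c + lncrnas + immune + filler
    groups = {"m6a": regulators, "m5c": m5c, "lncrna": lncrnas, "immune": immune,
              "filler": filler}
    return genes, {**groups, **{"sets": set_genes}}  # type: ignore[dict-item]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a genes-x-samples cohort with planted, recoverable structure.

    Returns the expression matrix (log2 scale), a sample annotation table
    (group, batch, subtype, pattern) and the ground truth.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, layout = _gene_names(config)
    n = config.n_cases + config.n_controls
    samples = [f"CASE{i + 1:04d}" for i in range(config.n_cases)] + [
        f"CTRL{i + 1:04d}" for i in range(config.n_controls)
    ]
    is_case = np.arange(n) < config.n_cases

    # balanced but shuffled assignment: near-equal pattern sizes keep the
    # planted subgroups exchangeable, while shuffling decouples pattern from
    # the (cyclic) batch assignment
    patterns = _pattern_names(config.n_patterns)
    pattern_idx = rng.permutation(np.arange(config.n_cases) % config.n_patterns)
    pattern_of_sample = {samples[i]: patterns[pattern_idx[i]] for i in range(config.n_cases)}

    batch_idx = np.arange(n) % config.n_batches
    batch_names = [f"Batch{i + 1}" for i in range(config.n_batches)]
    batch_of_sample = {samples[i]: batch_names[batch_idx[i]] for i in range(n)}

    gene_pos = {g: i for i, g in enumerate(genes)}
    mu = rng.uniform(4.0, 10.0, size=len(genes))
    signal = np.zeros((len(genes), n))

    # case/control shift on randomly chosen diagnostic regulators
    regs = layout["m6a"]
    diag = sorted(rng.choice(regs, size=config.n_diagnostic, replace=False).tolist())
    for g in diag:
        signal[gene_pos[g], is_case] += config.case_effect

    # disjoint equal-size regulator blocks elevated in one pattern each (cases
    # only); equal sizes keep the patterns exchangeable so no cluster merge is
    # privileged; leftover regulators carry no pattern signal
    block_size = len(regs) // config.n_patterns
    blocks = [
        np.arange(p * block_size, (p + 1) * block_size)
        for p in range(config.n_patterns)
    ]
    pattern_blocks = {patterns[p]: [regs[i] for i in blk] for p, blk in enumerate(blocks)}
    for p, blk in enumerate(blocks):
        cols = np.flatnonzero(is_case)[pattern_idx == p]
        for i in blk:
            signal[gene_pos[regs[i]], cols] += config.pattern_effect

    # immune signature sets elevated in one pattern each
    set_genes: dict[str, list[str]] = layout["sets"]
    immune_up_sets: dict[str, list[str]] = {p: [] for p in patterns}
    for si, name in enumerate(IMMUNE_CELL_TYPES):
        if si < 2 * config.n_patterns and config.immune_effect > 0:
            immune_up_sets[patterns[si % config.n_patterns]].append(name)
    for si, name in enumerate(IMMUNE_REACTIONS):
        if si < config.n_patterns and config.immune_effect > 0:
            immune_up_sets[patterns[si % config.n_patterns]].append(name)
    for p, names in immune_up_sets.items():
        cols = np.flatnonzero(is_case)[pattern_idx == patterns.index(p)]
        for name in names:
            for g in set_genes[name]:
                signal[gene_pos[g], cols] += config.immune_effect

    eps = rng.normal(0.0, 1.0, size=(len(genes), n))
    bio = mu[:, None] + signal + config.noise_sd * eps

    # linked lncRNAs: r * standardized(target) + sqrt(1 - r^2) * fresh noise
    lncs = layout["lncrna"]
    n_linked = int(round(config.lncrna_linked_frac * config.n_lncrnas))
    linked_lncrnas: dict[str, list[str]] = {}
    r = config.lncrna_link_r
    m5c_regs = layout["m5c"]
    for j in range(n_linked):
        lnc = lncs[j]
        if not m5c_regs:
            kind = "m6a"
        else:
            kind = ("m6a", "m5c", "both")[j % 3]
        if kind == "both":
            targets = [str(rng.choice(regs)), str(rng.choice(m5c_regs))]
            z1 = _standardize(bio[gene_pos[targets[0]]])
            z2 = _standardize(bio[gene_pos[targets[1]]])
            rho = float(np.corrcoef(z1, z2)[0, 1])
            # noise weight solving corr(y, z_k) = r; infeasible only if the two
            # targets are strongly anti-correlated, in which case b2 floors at 0
            b2 = max(((1 + rho) / r) ** 2 - 2 * (1 + rho), 0.0)
            y = z1 + z2 + np.sqrt(b2) * rng.normal(size=n)
        else:
            pool = regs if kind == "m6a" else m5c_regs
            targets = [str(rng.choice(pool))]
            z = _standardize(bio[gene_pos[targets[0]]])
            y = r * z + np.sqrt(1.0 - r**2) * rng.normal(size=n)
        linked_lncrnas[lnc] = targets
        bio[gene_pos[lnc]] = mu[gene_pos[lnc]] + config.noise_sd * _standardize(y)

    # batch effects: per-gene location shift and multiplicative dispersion
    gamma = rng.normal(0.0, config.batch_shift_sd, size=(len(genes), config.n_batches))
    delta = np.exp(rng.normal(0.0, config.batch_scale_sd, size=(len(genes), config.n_batches)))
    expr = mu[:, None] + delta[:, batch_idx] * (bio - mu[:, None]) + gamma[:, batch_idx]

    matrix = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    annotation = pd.DataFrame(
        {
            "group": np.where(is_case, "case", "control"),
            "batch": [batch_names[b] for b in batch_idx],
            "subtype": [
                CLINICAL_SUBTYPES[i] if c else ""
                for c, i in zip(is_case, rng.integers(0, len(CLINICAL_SUBTYPES), size=n))
            ],
            "pattern": [pattern_of_sample.get(s, "") for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    truth = GroundTruth(
        pattern_of_sample=pattern_of_sample,
        diagnostic_genes=diag,
        linked_lncrnas=linked_lncrnas,
        batch_of_sample=batch_of_sample,
        immune_up_sets=immune_up_sets,
        immune_set_genes=set_genes,
        pattern_blocks=pattern_blocks,
    )
    return matrix, annotation, truth


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def make_fixture_genesets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Materialize the 23 immune-cell and 17 immune-reaction signature sets."""
    sets = {name: list(genes) for name, genes in truth.immune_set_genes.items()}
    return GeneSetCollection(
        sets=sets,
        descriptions={
            name: ("immune cell type signature (synthetic)" if name in IMMUNE_CELL_TYPES
                   else "immune reaction signature (synthetic)")
            for name in sets
        },
        provenance="synthetic stand-in signatures generated by m6apat.synthetic",
    )
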