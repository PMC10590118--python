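"""Shared in-memory containers for the pipeline.

All tabular data are pandas objects; the thin dataclasses here only bundle
matrices with their metadata and enforce the invariants every stage relies on
(unique gene symbols, complete sample annotation, no missing values).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("uM", "uM_LPS", "hlf", "hlf_LPS")

#: The four condition contrasts analysed throughout: treatment effect,
#: LPS response without treatment, LPS response comparison under treatment,
#: and the within-treatment LPS null.
CONTRASTS = (
    ("hlf", "uM"),
    ("uM_LPS", "uM"),
    ("hlf_LPS", "uM_LPS"),
    ("hlf_LPS", "hlf"),
)


def contrast_name(num: str, den: str) -> str:
    return f"{num}-vs-{den}"


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """log2 expression (genes x samples) plus per-sample condition/donor labels.

    ``values``: DataFrame indexed by gene symbol, columns are sample IDs.
    ``samples``: DataFrame indexed by sample ID with columns ``condition``
    and ``donor``, in the same order as ``values.columns``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample column: {dup!r}")
        if v.isna().any().any():
            gene = v.index[v.isna().any(axis=1)][0]
            raise ValidationError(f"missing expression value (gene {gene!r})")
        if not np.issubdtype(v.to_numpy().dtype, np.number):
            raise ValidationError("expression values must be numeric")
        missing = set(v.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        for col in ("condition", "donor"):
            if col not in self.samples.columns:
                raise ValidationError(f"sample sheet lacks column {col!r}")
            if self.samples[col].isna().any():
                raise ValidationError(f"sample sheet has missing {col!r}")
        # keep metadata aligned to column order
        self.samples = self.samples.loc[list(v.columns)]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> pd.Series:
        return self.samples["condition"]

    def condition_means(self) -> pd.DataFrame:
        """Mean expression per gene across donors, one column per condition."""
        groups = self.values.T.groupby(self.conditions, observed=True).mean().T
        order = [c for c in CONDITIONS if c in groups.columns]
        extra = [c for c in groups.columns if c not in order]
        return groups[order + extra]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.samples.copy())


class GeneSetCollection(Mapping[str, frozenset]):
    """Named gene sets (pathways or regulator targets) with descriptions."""

    def __init__(self, sets: Mapping[str, set], descriptions: Mapping[str, str] | None = None):
        cleaned: dict[str, frozenset] = {}
        for name, members in sets.items():
            members = frozenset(members)
            if name in cleaned:
                raise ValidationError(f"duplicate gene-set name: {name!r}")
            if not members:
                raise ValidationError(f"empty gene set: {name!r}")
            cleaned[name] = members
        self._sets = cleaned
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> frozenset:
        return self._sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


EDGE_COLUMNS = ["gene_a", "gene_b", "channel", "directed", "confidence"]
CHANNELS = ("physical", "soluble")


def validate_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Check the typed edge-list invariants; returns the validated frame.

    Soluble edges are directed cytokine->receptor; physical edges undirected.
    """
    for col in ("gene_a", "gene_b", "channel"):
        if col not in edges.columns:
            raise ValidationError(f"edge table lacks column {col!r}")
    bad = set(edges["channel"]) - set(CHANNELS)
    if bad:
        raise ValidationError(f"unknown channel label(s): {sorted(bad)}")
    if "directed" not in edges.columns:
        edges = edges.assign(directed=(edges["channel"] == "soluble").astype(int))
    sol = edges[edges["channel"] == "soluble"]
    if (sol["directed"].astype(int) != 1).any():
        raise ValidationError("soluble edges must be directed (cytokine -> receptor)")
    phys = edges[edges["channel"] == "physical"]
    if (phys["directed"].astype(int) != 0).any():
        raise ValidationError("physical edges must be undirected")
    if "confidence" in edges.columns:
        conf = edges["confidence"].dropna()
        if ((conf < 0) | (conf > 1)).any():
            raise ValidationError("confidence must lie in [0, 1]")
    loops = edges["gene_a"] == edges["gene_b"]
    if loops.any():
        raise ValidationError(f"self-loop edge on {edges.loc[loops, 'gene_a'].iloc[0]!r}")
    return edges.reset_index(drop=True)


@dataclass
class ContrastResult:
    """Per-gene statistics for one condition contrast.

    ``table`` columns: gene, logFC, t, p, fdr (BH-adjusted).
    """

    contrast: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "logFC", "t", "p", "fdr"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValidationError(f"contrast table lacks columns {sorted(missing)}")


@dataclass
class ModeratedFit:
    """Empirical-Bayes moderated linear-model fit across genes."""

    genes: pd.Index
    coefficients: pd.DataFrame           # genes x design coefficients
    sigma2: np.ndarray                   # residual variance s^2 per gene
    df_residual: float                   # residual df d (balanced design)
    df_prior: float                      # d0
    s2_prior: float                      # s0^2
    s2_post: np.ndarray                  # posterior variances
    design: pd.DataFrame = field(repr=False, default=None)
    xtx_inv: np.ndarray = field(repr=False, default=None)


@dataclass
class RegulatorNetwork:
    """Soft-thresholded co-expression network restricted to top edges."""

    edges: pd.DataFrame                  # gene_a, gene_b, weight
    beta: int
    r2: float
    edge_keep: float
    regulators: list
    targets: dict                        # regulator -> frozenset of neighbours
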