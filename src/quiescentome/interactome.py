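"""Cell-cell interaction propensity between macrophage conditions and partner
immune cells.

The metric: after z-standardizing each gene across the columns of its own
matrix (macrophage condition means on one side, partner cell-type profiles on
the other), the product of the two standardized values of an interacting pair
is summed over all curated edges of a channel. Physical (membrane PPI) edges
are undirected and counted in both orientations; soluble (cytokine->receptor)
edges are macrophage-outgoing. Scores are in arbitrary units and reported as
deltas against a reference condition; a per-gene decomposition identifies the
drivers of a condition difference.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)


def filter_by_annotation(deg_table: pd.DataFrame, annotations: pd.DataFrame,
                         cls: str) -> pd.DataFrame:
    """Restrict a DEG table to genes carrying an annotation class."""
    valid = sorted(annotations["class"].unique())
    if cls not in valid:
        raise ValidationError(f"unknown class {cls!r}; valid classes: {valid}")
    members = set(annotations.loc[annotations["class"] == cls, "gene"])
    return deg_table[deg_table["gene"].isin(members)].reset_index(drop=True)


def standardize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene z-scores across the matrix's columns (sample SD by default).

    Zero-variance genes become all-zero rows (with a warning) rather than NaN.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("standardization needs >= 2 columns")
    arr = matrix.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    # rows constant up to rounding would otherwise divide accumulated
    # cancellation error by a ~1e-15 SD and return garbage z-scores
    tol = 1e-12 * np.maximum(1.0, np.abs(mean))
    flat = (sd <= tol).ravel()
    if flat.any():
        log.warning("%d zero-variance genes standardized to zero", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > tol, (arr - mean) / sd, 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def condition_profile(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Macrophage-side profile: mean across donors, one column per condition."""
    return matrix.condition_means()


def _channel_pairs(network: pd.DataFrame, channel: str):
    """Ordered (macro_gene, partner_gene) orientations for one channel."""
    sub = network[network["channel"] == channel]
    pairs = []
    for a, b in zip(sub["gene_a"], sub["gene_b"]):
        if channel == "soluble":
            pairs.append(((a, b),))          # cytokine (macro) -> receptor (cell)
        else:
            pairs.append(((a, b), (b, a)))   # undirected: both orientations
    return pairs


def interaction_propensity(macro_z: pd.DataFrame, cell_z: pd.DataFrame,
                           network: pd.DataFrame, channel: str,
                           ) -> tuple[pd.DataFrame, dict]:
    """Sum over channel edges of z_macro(gene_a, condition) * z_cell(gene_b, cell).

    Returns a long table (condition, cell_type, channel, score) and a coverage
    report {'used': m, 'skipped': s, 'total': m+s}; edges whose genes are
    absent from a matrix are skipped, never imputed as zero.
    """
    if channel not in ("physical", "soluble"):
        raise ValidationError(f"unknown channel {channel!r}")
    macro_genes = set(macro_z.index)
    cell_genes = set(cell_z.index)
    used = skipped = 0
    total = np.zeros((macro_z.shape[1], cell_z.shape[1]))
    for orientations in _channel_pairs(network, channel):
        edge_used = False
        for m_gene, c_gene in orientations:
            if m_gene in macro_genes and c_gene in cell_genes:
                total += np.outer(macro_z.loc[m_gene].to_numpy(),
                                  cell_z.loc[c_gene].to_numpy())
                edge_used = True
        if edge_used:
            used += 1
        else:
            skipped += 1
    if used == 0:
        log.warning("no usable %s edges; propensity scores are all zero", channel)
    rows = []
    for i, cond in enumerate(macro_z.columns):
        for j, cell in enumerate(cell_z.columns):
            rows.append({"condition": cond, "cell_type": cell,
                         "channel": channel, "score": float(total[i, j])})
    scores = pd.DataFrame(rows)
    coverage = {"channel": channel, "used": used, "skipped": skipped,
                "total": used + skipped}
    return scores, coverage


def relative_to_reference(scores: pd.DataFrame, reference: str = "uM") -> pd.DataFrame:
    """Delta of every (condition, cell type) score against the reference
    condition (radar-chart-ready)."""
    if reference not in set(scores["condition"]):
        raise ValidationError(f"reference condition {reference!r} absent from scores")
    ref = scores[scores["condition"] == reference].set_index(["cell_type", "channel"])
    out = scores.copy()
    out["delta_vs_ref"] = [
        s - float(ref.loc[(ct, ch), "score"])
        for s, ct, ch in zip(out["score"], out["cell_type"], out["channel"])
    ]
    return out


def interaction_drivers(macro_z: pd.DataFrame, cell_z: pd.DataFrame,
                        network: pd.DataFrame, channel: str,
                        cond_a: str, cond_b: str,
                        cell_profiles: pd.DataFrame | None = None,
                        mean_expression: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene decomposition of the propensity difference between two
    macrophage conditions, summed over all partner cell types.

    contribution_delta(g) = sum over edges incident to g (macro side) of
    (z_a(g) - z_b(g)) * z_cell(partner, t), over every cell type t; the
    per-gene contributions sum exactly to the total propensity delta.
    Because each standardized partner row sums to zero across cell types,
    the signed sum is ~0 whenever the partner matrix is fully standardized,
    so ``contribution_magnitude`` (the per-cell-type contributions summed in
    absolute value) is also reported and used for ranking.
    ``interaction_count`` counts distinct partner cell types expressing
    (raw value > 0) at least one partner of g; ordering is by
    interaction_count, then contribution_magnitude (both descending).
    """
    for cond in (cond_a, cond_b):
        if cond not in macro_z.columns:
            raise ValidationError(f"condition {cond!r} absent from macrophage matrix")
    macro_genes = set(macro_z.index)
    cell_genes = set(cell_z.index)
    raw = cell_profiles if cell_profiles is not None else None
    per_cell: dict[str, np.ndarray] = {}
    partner_cells: dict[str, set] = {}
    for orientations in _channel_pairs(network, channel):
        for m_gene, c_gene in orientations:
            if m_gene not in macro_genes or c_gene not in cell_genes:
                continue
            zdiff = float(macro_z.loc[m_gene, cond_a] - macro_z.loc[m_gene, cond_b])
            acc = per_cell.setdefault(m_gene, np.zeros(cell_z.shape[1]))
            acc += zdiff * cell_z.loc[c_gene].to_numpy()
            cells = partner_cells.setdefault(m_gene, set())
            if raw is not None and c_gene in raw.index:
                cells |= set(raw.columns[raw.loc[c_gene] > 0])
            else:
                cells |= set(cell_z.columns)
    rows = []
    for gene, acc in per_cell.items():
        row = {"gene": gene,
               "contribution_delta": float(acc.sum()),
               "contribution_magnitude": float(np.abs(acc).sum()),
               "interaction_count": len(partner_cells[gene])}
        if mean_expression is not None and gene in mean_expression.index:
            row["mean_expression"] = float(mean_expression.loc[gene])
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            by=["interaction_count", "contribution_magnitude", "gene"],
            key=lambda s: s if s.name == "gene" else -s,
            kind="stable").reset_index(drop=True)
    return table
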