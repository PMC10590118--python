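"""Regulator-target network inference and composite importance scoring.

The network is a WGCNA-style unsigned co-expression graph: pairwise Pearson
|r| raised to the smallest soft power whose weighted-degree distribution is
approximately scale-free (fit index R^2 >= 0.85 by default), pruned to the
top fraction of edges network-wide. Each regulator's targets are its network
neighbours; their over-representation among differentially expressed genes
is tested with a one-sided Fisher exact test, and a rank-based composite
score in [0, 2] combines a regulator's own differential-expression evidence
with its target enrichment. The composite formula (sum of the two
rank-normalized -log10 p components) is this package's own definition; it is
declared in output metadata wherever scores are written.
"""
from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .types import ExpressionMatrix, RegulatorNetwork, ValidationError, validate_edges

log = logging.getLogger(__name__)

R2_MIN = 0.85
EDGE_KEEP = 0.05
PPI_MIN_CONF = 0.900

SCORE_DEFINITION = (
    "composite = ranknorm(-log10 p_differential) + ranknorm(-log10 p_enrichment), "
    "each component rank-normalized to [0, 1] across regulators"
)


def scale_free_fit(weighted_degrees, n_bins: int = 10) -> float:
    """Scale-free topology fit index: R^2 of log10(frequency) on log10(mean
    binned degree). Returns 0 (with a warning) when all degrees are equal."""
    k = np.asarray(weighted_degrees, dtype=float)
    k = k[k > 0]
    if k.size < 5:
        raise ValidationError("scale-free fit needs >= 5 nodes with positive degree")
    if np.ptp(k) == 0:
        log.warning("all degrees equal; scale-free fit undefined, returning 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        dk.append(k[mask].mean())
        pk.append(mask.sum() / k.size)
    dk, pk = np.array(dk), np.array(pk)
    ok = (dk > 0) & (pk > 0)
    if ok.sum() < 2:
        return 0.0
    x, y = np.log10(dk[ok]), np.log10(pk[ok])
    r = np.corrcoef(x, y)[0, 1]
    if np.isnan(r):
        return 0.0
    return float(r * r)


def choose_soft_power(corr_abs: np.ndarray, r2_min: float = R2_MIN,
                      powers=range(1, 21)) -> tuple[int, float]:
    """Smallest integer power whose degree distribution reaches ``r2_min``;
    falls back to the power with maximal fit (logged) if none does."""
    best_beta, best_r2 = None, -1.0
    for beta in powers:
        adj = corr_abs ** beta
        degrees = adj.sum(axis=1) - np.diag(adj)
        r2 = scale_free_fit(degrees)
        if r2 >= r2_min:
            return int(beta), float(r2)
        if r2 > best_r2:
            best_beta, best_r2 = int(beta), float(r2)
    log.warning("no soft power reached R^2 >= %.2f; using beta=%d (R^2=%.3f)",
                r2_min, best_beta, best_r2)
    return best_beta, best_r2


def build_coexpression_network(matrix: ExpressionMatrix, regulators,
                               r2_min: float = R2_MIN,
                               edge_keep: float = EDGE_KEEP,
                               beta: int | None = None) -> RegulatorNetwork:
    """Unsigned soft-thresholded co-expression network pruned to the top
    ``edge_keep`` fraction of edges (network-wide, before restriction to
    regulator-incident edges). Pass ``beta`` to skip the soft-power search
    (required for networks below the 5 nodes the scale-free fit needs)."""
    if matrix.values.shape[1] < 4:
        raise ValidationError("network inference needs >= 4 samples")
    values = matrix.values
    sds = values.std(axis=1)
    constant = sds[sds == 0].index
    if len(constant):
        log.warning("dropping %d constant gene rows from network", len(constant))
        values = values.drop(index=constant)
    genes = list(values.index)
    regulators = sorted(set(regulators) & set(genes))
    if len(regulators) < 2:
        raise ValidationError("need >= 2 regulators present in the matrix")
    corr = np.corrcoef(values.to_numpy())
    corr_abs = np.abs(np.nan_to_num(corr, nan=0.0))
    np.fill_diagonal(corr_abs, 0.0)
    if beta is None:
        beta, r2 = choose_soft_power(corr_abs, r2_min=r2_min)
    else:
        degrees = (corr_abs ** beta).sum(axis=1)
        r2 = scale_free_fit(degrees) if len(genes) >= 5 else 0.0
    adj = corr_abs ** beta

    iu = np.triu_indices(len(genes), k=1)
    weights = adj[iu]
    n_keep = math.ceil(edge_keep * weights.size)
    gene_arr = np.array(genes)
    order = np.lexsort((gene_arr[iu[1]], gene_arr[iu[0]], -weights))
    kept = order[:n_keep]
    edges = pd.DataFrame({
        "gene_a": gene_arr[iu[0]][kept],
        "gene_b": gene_arr[iu[1]][kept],
        "weight": weights[kept],
    }).reset_index(drop=True)

    targets: dict[str, frozenset] = {}
    for reg in regulators:
        nb = set(edges.loc[edges["gene_a"] == reg, "gene_b"])
        nb |= set(edges.loc[edges["gene_b"] == reg, "gene_a"])
        targets[reg] = frozenset(nb)
    return RegulatorNetwork(edges=edges, beta=beta, r2=r2, edge_keep=edge_keep,
                            regulators=regulators, targets=targets)


def regulator_enrichment(network: RegulatorNetwork, de_genes, universe,
                         adj_p_cut: float = 0.05, q_cut: float = 0.2) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each regulator's targets among
    differentially expressed genes (p < 0.05 genes by convention).

    Columns: regulator, n_targets, overlap, p, padj (BH), q (Storey),
    significant (padj < 0.05 and q < 0.2).
    """
    universe = set(universe)
    de = set(de_genes) & universe
    rows = []
    for reg in network.regulators:
        targets = set(network.targets[reg])
        if not targets <= universe:
            raise ValidationError(
                f"targets of {reg!r} fall outside the gene universe")
        a = len(targets & de)
        if len(targets) == 0:
            rows.append({"regulator": reg, "n_targets": 0, "overlap": 0,
                         "p": 1.0, "flag": "no-targets"})
            continue
        # one-sided (enrichment) Fisher = hypergeometric upper tail
        p = float(stats.hypergeom.sf(a - 1, len(universe), len(targets), len(de)))
        rows.append({"regulator": reg, "n_targets": len(targets), "overlap": a,
                     "p": min(p, 1.0), "flag": ""})
    table = pd.DataFrame(rows)
    table["padj"] = adjust_bh(table["p"].to_numpy())
    table["q"] = storey_q(table["p"].to_numpy())
    table["significant"] = (table["padj"] < adj_p_cut) & (table["q"] < q_cut)
    return table


def storey_q(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the point estimate pi0 = #{p > lambda} / (m (1-lambda)),
    clipped to (0, 1]; reduces to BH scaled by pi0."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = min(1.0, max((p > lam).sum() / (m * (1.0 - lam)), 1.0 / m))
    return np.minimum(adjust_bh(p) * pi0, 1.0)


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Average ranks mapped to [0, 1]; a single element maps to 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return np.ones(1)
    ranks = stats.rankdata(values, method="average")
    return (ranks - 1.0) / (values.size - 1.0)


def regenrich_score(differential_p, enrichment_p, regulators=None) -> pd.DataFrame:
    """Composite regulator-importance score in [0, 2].

    Each component is the rank-normalized -log10 p across regulators, so the
    score is invariant to monotone transformations of either p-vector; the
    best regulator on both axes scores exactly 2.
    """
    dp = np.asarray(differential_p, dtype=float)
    ep = np.asarray(enrichment_p, dtype=float)
    if dp.shape != ep.shape:
        raise ValidationError("p-vectors must have equal length")
    if np.any((dp <= 0) | (dp > 1)) or np.any((ep <= 0) | (ep > 1)):
        tiny = np.finfo(float).tiny
        if np.any(dp == 0) or np.any(ep == 0):
            log.warning("clamping zero p-values to machine minimum")
            dp = np.clip(dp, tiny, 1.0)
            ep = np.clip(ep, tiny, 1.0)
        else:
            raise ValidationError("p-values must lie in (0, 1]")
    d_comp = _rank_normalize(-np.log10(dp))
    e_comp = _rank_normalize(-np.log10(ep))
    table = pd.DataFrame({
        "regulator": regulators if regulators is not None else np.arange(dp.size),
        "differential_p": dp, "enrichment_p": ep,
        "differential_component": d_comp, "enrichment_component": e_comp,
        "score": d_comp + e_comp,
    })
    return table.sort_values(["score", "regulator"], ascending=[False, True],
                             kind="stable").reset_index(drop=True)


def top_regulators(scores: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k regulators by composite score (ties by name, deterministic)."""
    return scores.head(k).reset_index(drop=True)


def attribute_regulators_to_pathways(network: RegulatorNetwork,
                                     adjacency: pd.DataFrame,
                                     scores: pd.DataFrame | None = None,
                                     top_k: int = 5) -> pd.DataFrame:
    """Point-count attribution of regulators to enriched pathways.

    A regulator earns one point per gene its target set shares with a
    pathway's genes in the DEG-pathway adjacency; per pathway the ``top_k``
    regulators by points are kept (ties broken by composite score, then
    lexicographic). Sankey-ready: regulator (source), pathway (target), points.
    """
    if adjacency.empty:
        raise ValidationError("DEG-pathway adjacency is empty")
    score_of = {}
    if scores is not None:
        score_of = dict(zip(scores["regulator"], scores["score"]))
    rows = []
    for pathway in adjacency.columns:
        path_genes = set(adjacency.index[adjacency[pathway] == 1])
        scored = []
        for reg in network.regulators:
            points = len(set(network.targets[reg]) & path_genes)
            if points > 0:
                scored.append((points, score_of.get(reg, 0.0), reg))
        scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
        for points, _, reg in scored[:top_k]:
            rows.append({"regulator": reg, "pathway": pathway, "points": points})
    return pd.DataFrame(rows, columns=["regulator", "pathway", "points"])


def filter_ppi_edges(edges: pd.DataFrame, min_conf: float = PPI_MIN_CONF) -> pd.DataFrame:
    """Keep edges with confidence >= ``min_conf`` (the highest-confidence
    STRING-style filter; the bound is inclusive)."""
    if len(edges) == 0:
        return edges.copy().reset_index(drop=True)
    if "confidence" not in edges.columns or edges["confidence"].isna().any():
        raise ValidationError("all edges must carry a confidence score")
    validate_edges(edges)
    return edges[edges["confidence"] >= min_conf].reset_index(drop=True)
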