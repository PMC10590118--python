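"""Pathway over-representation with expression-matched backgrounds.

Over-representation is tested with the upper-tail hypergeometric probability
P(X >= k) against a background universe restricted to genes whose mean
expression is similar to the differentially expressed genes (equal-frequency
binning), which controls the expression-level bias of array-based enrichment.
Also provides the cross-contrast theme comparison and the DEG-pathway
adjacency used for chord diagrams.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh
from .types import ExpressionMatrix, GeneSetCollection, ValidationError

CHORD_LFC = 2.5
THEME_SIG_ADJ_P = 0.1


def matched_background(deg, matrix: ExpressionMatrix, bins: int = 10) -> set:
    """Background = union of the equal-frequency mean-expression bins that
    contain at least one DEG; always a superset of the DEG."""
    deg = set(deg)
    if not deg:
        raise ValidationError("matched_background requires a non-empty DEG set")
    missing = deg - set(matrix.genes)
    if missing:
        raise ValidationError(f"DEG absent from matrix: {sorted(missing)[:5]}")
    means = matrix.values.mean(axis=1)
    order = np.argsort(means.to_numpy(), kind="stable")
    gene_arr = means.index.to_numpy()[order]
    background: set = set()
    for chunk in np.array_split(gene_arr, bins):
        chunk_set = set(chunk)
        if chunk_set & deg:
            background |= chunk_set
    return background


def ora_hypergeometric(deg, background, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of each set against the background.

    Columns: set, k (overlap), K (set size in universe), n (DEG count),
    N (universe size), p, padj. Sets with no gene in the background are
    dropped; p is the upper tail P(X >= k) so a disjoint set gets p = 1.
    """
    deg, background = set(deg), set(background)
    if not deg <= background:
        raise ValidationError("DEG must be a subset of the background universe")
    N, n = len(background), len(deg)
    rows = []
    for name in collection:
        members = collection[name] & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & deg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(table):
        table["padj"] = adjust_bh(table["p"].to_numpy())
    else:
        table["padj"] = pd.Series(dtype=float)
    return table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)


def _direction_tag(members, deg_table: pd.DataFrame) -> str:
    sub = deg_table[deg_table["gene"].isin(members)]
    if sub.empty:
        return "none"
    mean_lfc = sub["logFC"].mean()
    if mean_lfc > 0:
        return "up"
    if mean_lfc < 0:
        return "down"
    return "mixed"


def theme_compare(results, deg_tables, collection: GeneSetCollection,
                  sig_adj_p: float = THEME_SIG_ADJ_P) -> pd.DataFrame:
    """Cross-contrast comparison of enriched themes (dot-plot-ready).

    ``results``: list of (contrast, enrichment table); ``deg_tables``: mapping
    contrast -> DEG table with logFC, used for the up/down direction tag.
    Sets significant (padj < ``sig_adj_p``) in any contrast are reported for
    every contrast, flagged by a ``significant`` column.
    """
    if len(results) < 2:
        raise ValidationError("theme comparison needs >= 2 contrasts")
    keep = set()
    for _, table in results:
        if len(table):
            keep |= set(table.loc[table["padj"] < sig_adj_p, "set"])
    rows = []
    for contrast, table in results:
        indexed = table.set_index("set") if len(table) else table
        for name in sorted(keep):
            deg_table = deg_tables[contrast]
            tag = _direction_tag(collection[name], deg_table)
            if name in getattr(indexed, "index", []):
                r = indexed.loc[name]
                rows.append({
                    "set": name, "contrast": contrast, "k": int(r["k"]),
                    "K": int(r["K"]), "n": int(r["n"]), "N": int(r["N"]),
                    "p": float(r["p"]), "padj": float(r["padj"]),
                    "significant": bool(r["padj"] < sig_adj_p), "direction": tag,
                })
            else:
                rows.append({
                    "set": name, "contrast": contrast, "k": 0, "K": 0, "n": 0,
                    "N": 0, "p": 1.0, "padj": 1.0, "significant": False,
                    "direction": tag,
                })
    return pd.DataFrame(rows, columns=["set", "contrast", "k", "K", "n", "N",
                                       "p", "padj", "significant", "direction"])


def deg_pathway_adjacency(deg_table: pd.DataFrame, enriched_sets,
                          collection: GeneSetCollection,
                          lfc_filter: float = CHORD_LFC,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Membership matrix between strong DEG and enriched pathways.

    Rows are DEG with |logFC| strictly above ``lfc_filter`` (the chord-diagram
    noise filter); returns (adjacency 0/1 DataFrame genes x sets, long edge
    list with gene, set, logFC).
    """
    strong = deg_table[(deg_table["logFC"] > lfc_filter)
                       | (deg_table["logFC"] < -lfc_filter)]
    sets = list(enriched_sets)
    adjacency = pd.DataFrame(0, index=pd.Index(strong["gene"], name="gene"),
                             columns=sets, dtype=int)
    edge_rows = []
    lfc_of = dict(zip(strong["gene"], strong["logFC"]))
    for name in sets:
        members = collection[name]
        for gene in adjacency.index:
            if gene in members:
                adjacency.loc[gene, name] = 1
                edge_rows.append({"gene": gene, "set": name,
                                  "logFC": float(lfc_of[gene])})
    edges = pd.DataFrame(edge_rows, columns=["gene", "set", "logFC"])
    return adjacency, edges
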