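"""Per-gene differential expression with empirical-Bayes variance moderation.

The model is the standard microarray linear model: for each gene g,

    y_g = X beta_g + eps,   eps ~ N(0, sigma_g^2 I)

with a design holding condition effects and (by default) additive donor
blocking terms, matching a paired design where the same donors contribute one
sample per condition. Residual variances are shrunk toward a pooled prior by
closed-form moment matching of log s^2 against a scaled-F distribution, and
contrasts are tested with moderated t-statistics on d + d0 degrees of freedom.
"""
from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import ContrastResult, ExpressionMatrix, ModeratedFit, ValidationError, contrast_name

log = logging.getLogger(__name__)

FDR_CUT = 0.05
LFC_CUT = 0.58


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the per-column sorted values; ties
    within a column receive the mean of the reference quantiles they span.
    """
    values = matrix.values
    if values.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if values.isna().any().any():
        raise ValidationError("missing values in expression matrix")
    arr = values.to_numpy(dtype=float)
    reference = np.mean(np.sort(arr, axis=0), axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty_like(order)
        ranks[order] = np.arange(len(col))
        normalized = reference[ranks]
        # ties: average the reference values over the tied block
        sorted_col = col[order]
        block_start = 0
        for i in range(1, len(col) + 1):
            if i == len(col) or sorted_col[i] != sorted_col[block_start]:
                if i - block_start > 1:
                    tied = order[block_start:i]
                    normalized[tied] = reference[block_start:i].mean()
                block_start = i
        out[:, j] = normalized
    return ExpressionMatrix(
        pd.DataFrame(out, index=values.index, columns=values.columns),
        matrix.samples.copy(),
    )


# ---------------------------------------------------------------------------
# linear model
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame, donor_blocking: bool = True,
                 reference: str = "uM") -> pd.DataFrame:
    """Treatment-coded design matrix: intercept + condition + donor dummies."""
    conditions = samples["condition"].astype(str)
    levels = [reference] + sorted(c for c in conditions.unique() if c != reference)
    if reference not in set(conditions):
        raise ValidationError(f"reference condition {reference!r} absent from samples")
    cols = {"intercept": np.ones(len(samples))}
    for lvl in levels[1:]:
        cols[f"cond_{lvl}"] = (conditions == lvl).astype(float).to_numpy()
    if donor_blocking:
        donors = samples["donor"].astype(str)
        for d in sorted(donors.unique())[1:]:
            cols[f"donor_{d}"] = (donors == d).astype(float).to_numpy()
    design = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = [
            c for c in design.columns
            if np.linalg.matrix_rank(design.drop(columns=c).to_numpy()) == rank
        ]
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")
    return design


def fit_linear_model(matrix: ExpressionMatrix, donor_blocking: bool = True,
                     reference: str = "uM") -> ModeratedFit:
    """Per-gene least squares for all genes at once.

    Returns an (un-moderated) fit: ``df_prior`` is 0 and ``s2_post == sigma2``
    until :func:`ebayes_moderate` is applied.
    """
    design = build_design(matrix.samples, donor_blocking=donor_blocking,
                          reference=reference)
    X = design.to_numpy()
    Y = matrix.values.to_numpy(dtype=float).T          # samples x genes
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValidationError(f"residual df {df} < 1 (n={n}, p={p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y                            # p x genes
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / df
    coef = pd.DataFrame(beta.T, index=matrix.genes, columns=design.columns)
    return ModeratedFit(
        genes=matrix.genes, coefficients=coef, sigma2=s2, df_residual=float(df),
        df_prior=0.0, s2_prior=float("nan"), s2_post=s2.copy(),
        design=design, xtx_inv=xtx_inv,
    )


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log s^2 to a scaled F to get (d0, s0^2).

    Under the hierarchical model s^2 ~ s0^2 * F(d, d0); on the log scale the
    mean and variance of log s^2 have closed forms in digamma/trigamma, which
    this inverts. Returns d0 = inf when the observed spread of log s^2 is no
    larger than expected from chi^2_d sampling alone.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.size < 10:
        raise ValidationError("need >= 10 genes to estimate the variance prior")
    if np.all(sigma2 <= 0):
        raise ValidationError("all residual variances are zero")
    if np.any(sigma2 <= 0):
        floor = sigma2[sigma2 > 0].min() * 1e-8
        log.warning("replacing %d zero residual variances with %.3g",
                    int((sigma2 <= 0).sum()), floor)
        sigma2 = np.where(sigma2 <= 0, floor, sigma2)
    if np.ptp(sigma2) == 0:
        # exactly equal variances: no sampling spread at all, so the prior
        # is the common value itself with infinite prior df
        return float("inf"), float(sigma2[0])
    e = np.log(sigma2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(emean + special.digamma(df_prior / 2.0)
                          - np.log(df_prior / 2.0))
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(df_prior), float(s2_prior)


def ebayes_moderate(fit: ModeratedFit) -> ModeratedFit:
    """Shrink per-gene variances toward the pooled prior.

    Posterior variance is the df-weighted blend
    ``(d0*s0^2 + d*s^2) / (d0 + d)``; with d0 = inf every gene gets s0^2.
    """
    d = fit.df_residual
    sigma2 = fit.sigma2
    if np.all(sigma2 <= 0):
        log.warning("all residual variances zero; falling back to ordinary t")
        return ModeratedFit(
            genes=fit.genes, coefficients=fit.coefficients, sigma2=sigma2,
            df_residual=d, df_prior=0.0, s2_prior=0.0, s2_post=sigma2.copy(),
            design=fit.design, xtx_inv=fit.xtx_inv,
        )
    d0, s02 = estimate_prior(sigma2, d)
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s02)
    else:
        s2_post = (d0 * s02 + d * sigma2) / (d0 + d)
    return ModeratedFit(
        genes=fit.genes, coefficients=fit.coefficients, sigma2=sigma2,
        df_residual=d, df_prior=d0, s2_prior=s02, s2_post=s2_post,
        design=fit.design, xtx_inv=fit.xtx_inv,
    )


def _contrast_vector(fit: ModeratedFit, numerator: str, denominator: str,
                     reference: str = "uM") -> np.ndarray:
    cols = list(fit.coefficients.columns)
    c = np.zeros(len(cols))
    for cond, sign in ((numerator, 1.0), (denominator, -1.0)):
        if cond == reference:
            continue  # reference is absorbed by the intercept
        name = f"cond_{cond}"
        if name not in cols:
            raise ValidationError(f"condition {cond!r} not in design")
        c[cols.index(name)] = sign
    return c


def contrast_test(fit: ModeratedFit, numerator: str, denominator: str,
                  reference: str = "uM") -> ContrastResult:
    """Moderated t-test of a condition contrast.

    logFC is the contrast coefficient (log2 scale); the statistic is
    ``logFC / (s_post * sqrt(v_c))`` on ``d + d0`` df, where ``v_c`` is the
    contrast's unscaled variance ``c' (X'X)^-1 c``.
    """
    c = _contrast_vector(fit, numerator, denominator, reference)
    logfc = fit.coefficients.to_numpy() @ c
    v_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.s2_post * v_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        # se == 0 only for degenerate all-constant genes: t = 0 when the
        # effect is also 0, +/- inf otherwise.
        t = np.where(se > 0, logfc / se,
                     np.where(logfc == 0.0, 0.0, np.sign(logfc) * np.inf))
    df_total = fit.df_residual + fit.df_prior
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame({
        "gene": fit.genes, "logFC": logfc, "t": t, "p": p, "fdr": adjust_bh(p),
    })
    return ContrastResult(contrast_name(numerator, denominator), table)


# ---------------------------------------------------------------------------
# multiple testing & selection
# ---------------------------------------------------------------------------

def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_deg(result: ContrastResult, fdr_cut: float = FDR_CUT,
               lfc_cut: float = LFC_CUT) -> pd.DataFrame:
    """Genes with FDR strictly below ``fdr_cut`` and |logFC| strictly above
    ``lfc_cut``; adds a ``direction`` column (up/down)."""
    t = result.table
    keep = (t["fdr"] < fdr_cut) & ((t["logFC"] > lfc_cut) | (t["logFC"] < -lfc_cut))
    out = t.loc[keep, ["gene", "logFC", "fdr"]].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# targeted ANOVA / Tukey
# ---------------------------------------------------------------------------

def anova_tukey(matrix: ExpressionMatrix, genes) -> pd.DataFrame:
    """One-way ANOVA across conditions plus Tukey HSD pairwise adjusted p.

    Long output: one row per (gene, condition pair) with the ANOVA F and p
    attached, suitable for boxplot annotation of targeted genes.
    """
    cond = matrix.conditions
    levels = sorted(cond.unique())
    if len(levels) < 2:
        raise ValidationError("ANOVA needs >= 2 condition groups")
    groups_idx = {lvl: np.flatnonzero((cond == lvl).to_numpy()) for lvl in levels}
    for lvl, idx in groups_idx.items():
        if len(idx) < 2:
            raise ValidationError(f"condition {lvl!r} has < 2 samples")
    rows = []
    for gene in genes:
        if gene not in matrix.values.index:
            raise ValidationError(f"gene {gene!r} absent from expression matrix")
        y = matrix.values.loc[gene].to_numpy(dtype=float)
        samples = [y[idx] for idx in groups_idx.values()]
        if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
            f_stat, f_p = 0.0, 1.0
            pvals = np.ones((len(levels), len(levels)))
        else:
            f_stat, f_p = stats.f_oneway(*samples)
            pvals = stats.tukey_hsd(*samples).pvalue
        for i, j in combinations(range(len(levels)), 2):
            rows.append({
                "gene": gene, "group_a": levels[i], "group_b": levels[j],
                "p_tukey": float(pvals[i, j]), "F": float(f_stat),
                "p_anova": float(f_p),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# convenience driver
# ---------------------------------------------------------------------------

def run_contrasts(matrix: ExpressionMatrix, contrasts=None, donor_blocking=True,
                  reference: str = "uM") -> dict[str, ContrastResult]:
    """Fit, moderate, and test a list of (numerator, denominator) contrasts."""
    from .types import CONTRASTS
    contrasts = contrasts or CONTRASTS
    fit = ebayes_moderate(fit_linear_model(matrix, donor_blocking=donor_blocking,
                                           reference=reference))
    return {
        contrast_name(a, b): contrast_test(fit, a, b, reference)
        for a, b in contrasts
    }
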