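"""Genetic alteration-driven gene discovery.

Differential expression uses an empirical-Bayes moderated t-statistic: the
per-gene residual variance s² (pooled, d = n−2 df) is shrunk toward a prior
(d0, s0²) estimated by matching the first two moments of log s² to a
scaled-inverse-chi-square marginal, giving the posterior variance

    s̃² = (d0·s0² + d·s²) / (d0 + d)

and a moderated t = log2FC / (s̃·√(1/n_t + 1/n_n)) on d0 + d degrees of
freedom. Driver categories then follow the study's filters: differentially
methylated genes with inverse expression~beta correlation (methylation-driven),
differentially expressed genes inside amplified/deleted regions (CNA-driven),
and non-silently mutated differentially expressed genes (mutation-driven).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests

from .io import CnaCalls, ExpressionMatrix, MethylationMatrix, MutationTable

logger = logging.getLogger(__name__)


@dataclass
class DriverGeneSet:
    """One category's driven genes with per-gene evidence records."""

    category: str  # {methylation, cna, mutation}
    genes: list[str]
    evidence: pd.DataFrame


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_significance(set_a, set_b, universe_size: int) -> tuple[int, float]:
    """Upper-tail (inclusive) hypergeometric test of |A ∩ B|.

    p = P(X ≥ k) for X ~ Hypergeom(N=universe_size, K=|A|, n=|B|).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("universe smaller than one of the sets")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return k, min(p, 1.0)


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def estimate_variance_prior(s2, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) from the marginal distribution of log s².

    Under s²|σ² ~ σ²·χ²_d/d and σ² ~ d0·s0²/χ²_{d0}, the log sample variance
    has mean log s0² + ψ(d/2) − log(d/2) − ψ(d0/2) + log(d0/2) and variance
    ψ'(d/2) + ψ'(d0/2); d0 is recovered by inverting the trigamma function.
    Returns d0 = inf when the observed spread does not exceed ψ'(d/2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    excess = evar - float(special.polygamma(1, df / 2.0))
    if excess <= 1e-12:
        return np.inf, float(np.exp(emean))
    # solve trigamma(d0/2) = excess; trigamma is strictly decreasing
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - excess, 1e-6, 1e8, xtol=1e-12
    )
    d0 = 2.0 * half_d0
    s02 = float(np.exp(emean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s02


def moderated_t_from_stats(log2fc, s2, df: float, d0: float, s02: float,
                           n_tumor: int, n_normal: int):
    """Evaluate the shrinkage formula given (d0, s0²); returns (t, p, df_total).

    d0 = inf collapses to the z-like form log2FC/(s0·√(1/n_t+1/n_n));
    d0 = 0 recovers the ordinary t on d degrees of freedom.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    scale = np.sqrt(s2_post * (1.0 / n_tumor + 1.0 / n_normal))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / scale
    zero = scale == 0
    if np.any(zero):
        logger.warning("%d zero-variance gene(s); t set by the sign of the effect",
                       int(zero.sum()))
        t = np.where(zero & (log2fc == 0), 0.0, t)
        t = np.where(zero & (log2fc != 0), np.sign(log2fc) * np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, p)
    return t, p, df_total


def moderated_t_test(expr: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene moderated t-test of tumor vs normal log2 expression.

    Returns a DataFrame indexed by gene with columns mean_tumor, mean_normal,
    log2fc, s2, t, df, p, fdr, direction.
    """
    tum = expr.values[expr.tumor_samples()].to_numpy()
    nor = expr.values[expr.normal_samples()].to_numpy()
    n_t, n_n = tum.shape[1], nor.shape[1]
    if n_t < 2 or n_n < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_t = tum.mean(axis=1)
    mean_n = nor.mean(axis=1)
    log2fc = mean_t - mean_n
    df = float(n_t + n_n - 2)
    ss = ((tum - mean_t[:, None]) ** 2).sum(axis=1) + ((nor - mean_n[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    d0, s02 = estimate_variance_prior(s2, df)
    t, p, df_total = moderated_t_from_stats(log2fc, s2, df, d0, s02, n_t, n_n)
    out = pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "log2fc": log2fc,
            "s2": s2,
            "t": t,
            "df": df_total,
            "p": p,
            "fdr": benjamini_hochberg(p),
            "direction": np.where(log2fc >= 0, "up", "down"),
        },
        index=pd.Index(expr.genes, name="gene"),
    )
    out.attrs["d0"] = d0
    out.attrs["s02"] = s02
    return out


def select_degs(statstable: pd.DataFrame, fc_thresh: float = 2.0,
                fdr_thresh: float = 0.05) -> tuple[set[str], set[str]]:
    """Differentially expressed genes at FDR < fdr_thresh and fold change > fc_thresh.

    The fold-change rule is two-sided: up means 2^log2FC > fc_thresh, down
    means 2^log2FC < 1/fc_thresh.
    """
    if len(statstable) == 0:
        raise ValueError("empty statistics table")
    lfc_cut = np.log2(fc_thresh)
    sig = statstable["fdr"] < fdr_thresh
    up = set(statstable.index[sig & (statstable["log2fc"] > lfc_cut)])
    down = set(statstable.index[sig & (statstable["log2fc"] < -lfc_cut)])
    return up, down


def diff_methylation(meth: MethylationMatrix) -> pd.DataFrame:
    """Per-gene Welch t-test of tumor vs normal beta values."""
    g = meth.group.loc[list(meth.beta.columns)]
    tum = meth.beta.loc[:, (g == "tumor").to_numpy()].to_numpy()
    nor = meth.beta.loc[:, (g == "normal").to_numpy()].to_numpy()
    if tum.shape[1] < 2 or nor.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    delta = tum.mean(axis=1) - nor.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(tum, nor, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(t)
    t = np.where(degenerate & (delta == 0), 0.0, t)
    t = np.where(degenerate & (delta != 0), np.copysign(np.inf, delta), t)
    p = np.where(np.isnan(p), np.where(delta == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {
            "mean_tumor": tum.mean(axis=1),
            "mean_normal": nor.mean(axis=1),
            "delta_beta": delta,
            "t": t,
            "p": p,
            "fdr": benjamini_hochberg(p),
            "direction": np.where(delta >= 0, "hyper", "hypo"),
        },
        index=pd.Index(meth.genes, name="gene"),
    )


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(x, y)[0, 1])
    r = np.clip(r, -1.0, 1.0)
    if abs(r) == 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2.0 * stats.t.sf(abs(tstat), n - 2))


def methylation_driven(dm: pd.DataFrame, expr: ExpressionMatrix,
                       meth: MethylationMatrix, dm_fdr_thresh: float = 0.05,
                       corr_p_thresh: float = 0.05,
                       tumor_only: bool = True) -> DriverGeneSet:
    """Differentially methylated genes whose expression inversely tracks beta.

    For each gene at dm FDR < threshold, Pearson r between expression and beta
    (tumor samples by default); genes with r < 0 and BH-adjusted correlation
    p < threshold are methylation-driven.
    """
    candidates = list(dm.index[dm["fdr"] < dm_fdr_thresh])
    if tumor_only:
        samples = [s for s in expr.tumor_samples() if s in set(meth.beta.columns)]
    else:
        samples = [s for s in expr.samples if s in set(meth.beta.columns)]
    rows = []
    for gene in candidates:
        if gene not in expr.values.index or gene not in meth.beta.index:
            logger.warning("gene %s missing from a matrix; skipped", gene)
            continue
        r, p = _pearson_with_p(
            meth.beta.loc[gene, samples].to_numpy(),
            expr.values.loc[gene, samples].to_numpy(),
        )
        if np.isnan(r):
            logger.warning("gene %s has constant values; correlation skipped", gene)
            continue
        rows.append((gene, dm.loc[gene, "delta_beta"], dm.loc[gene, "fdr"], r, p))
    ev = pd.DataFrame(rows, columns=["gene", "delta_beta", "dm_fdr", "r", "p"])
    ev["adjusted_p"] = benjamini_hochberg(ev["p"]) if len(ev) else []
    keep = ev[(ev["r"] < 0) & (ev["adjusted_p"] < corr_p_thresh)]
    return DriverGeneSet(
        category="methylation",
        genes=sorted(keep["gene"]),
        evidence=keep.reset_index(drop=True),
    )


def cna_driven(cna: CnaCalls, up_genes, down_genes,
               require_concordance: bool = False) -> DriverGeneSet:
    """Differentially expressed genes inside amplified/deleted regions.

    With ``require_concordance`` the direction must match the region class
    (amplified∩up, deleted∩down); by default region membership alone suffices.
    """
    up, down = set(up_genes), set(down_genes)
    rows = []
    for gene in sorted(cna.amp_genes | cna.del_genes):
        region = "amp" if gene in cna.amp_genes else "del"
        if gene in up:
            direction = "up"
        elif gene in down:
            direction = "down"
        else:
            continue
        if require_concordance and not (
            (region == "amp" and direction == "up")
            or (region == "del" and direction == "down")
        ):
            continue
        rows.append((gene, region, direction))
    ev = pd.DataFrame(rows, columns=["gene", "region", "direction"])
    return DriverGeneSet(category="cna", genes=sorted(ev["gene"]), evidence=ev)


def mutation_driven(mut: MutationTable, up_genes, down_genes,
                    min_samples: int = 1) -> DriverGeneSet:
    """Non-silently mutated genes (≥ min_samples distinct samples) that are DE."""
    counts = mut.nonsilent_sample_counts()
    mutated = set(counts.index[counts >= min_samples])
    degs = set(up_genes) | set(down_genes)
    keep = sorted(mutated & degs)
    ev = pd.DataFrame(
        {
            "gene": keep,
            "n_mutated_samples": [int(counts[g]) for g in keep],
            "direction": ["up" if g in set(up_genes) else "down" for g in keep],
        }
    )
    return DriverGeneSet(category="mutation", genes=keep, evidence=ev)
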