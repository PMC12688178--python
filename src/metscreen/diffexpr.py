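"""Two-group moderated differential expression and FDR machinery.

Each contrast (M vs PT, PT vs N, high vs low, sh vs scr) is a two-group
linear model per gene: the pooled within-group variance is shrunk toward a
common prior by empirical Bayes (method-of-moments on log-variances via
digamma/trigamma identities), yielding a moderated t with
``df_residual + d0`` degrees of freedom.  Benjamini-Hochberg controls the
FDR across genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

CONTRASTS = {
    "M_vs_PT": ("M", "PT"),
    "PT_vs_N": ("PT", "N"),
    "high_vs_low": ("high", "low"),
    "sh_vs_scr": ("sh", "scr"),
}


@dataclass
class GroupStats:
    """Per-gene two-group summaries; ``log2fc = mean_a - mean_b``."""

    gene_ids: pd.Index
    mean_a: np.ndarray
    mean_b: np.ndarray
    s2: np.ndarray          # pooled within-group variance
    df_residual: int        # n_a + n_b - 2
    n_a: int
    n_b: int

    @property
    def log2fc(self) -> np.ndarray:
        return self.mean_a - self.mean_b


@dataclass
class EBFit:
    """Empirical-Bayes variance moderation: ``s2_tilde = (d0*s0_2 + df*s2)/(d0 + df)``."""

    d0: float               # prior degrees of freedom (math.inf allowed)
    s0_2: float             # prior variance
    s2_tilde: np.ndarray    # per-gene posterior variances


def group_stats(matrix: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str]) -> GroupStats:
    """Pooled two-group summaries for ``contrast = (a, b)`` group labels."""
    label_a, label_b = contrast
    groups = groups.reindex(matrix.columns)
    cols_a = matrix.columns[(groups == label_a).to_numpy()]
    cols_b = matrix.columns[(groups == label_b).to_numpy()]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(f"contrast {label_a} vs {label_b}: both groups need >= 2 samples "
                         f"(got {len(cols_a)}, {len(cols_b)})")
    xa = matrix[cols_a].to_numpy(float)
    xb = matrix[cols_b].to_numpy(float)
    na, nb = xa.shape[1], xb.shape[1]
    mean_a = xa.mean(axis=1)
    mean_b = xb.mean(axis=1)
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    return GroupStats(matrix.index, mean_a, mean_b, ss / df, df, na, nb)


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (trigamma is monotone decreasing)."""
    if y <= 0:
        return math.inf
    lo, hi = 1e-8, 1e8
    tg = lambda x: float(special.polygamma(1, x)) - y
    if tg(lo) < 0:      # y above trigamma(1e-8): x below bracket
        return lo
    if tg(hi) > 0:
        return hi
    return optimize.brentq(tg, lo, hi, xtol=1e-12, rtol=1e-12)


def eb_shrink(s2: np.ndarray, df_residual: int) -> EBFit:
    """Estimate the variance prior and shrink gene-wise variances toward it.

    Hyperparameters by moment matching on ``log s2``: the excess of
    ``var(log s2)`` over the sampling term ``trigamma(df/2)`` identifies the
    prior df ``d0`` through ``trigamma(d0/2)``; no excess means the true
    variances are exchangeable and ``d0 = inf`` (complete shrinkage).
    Genes with ``s2 = 0`` are shrunk like any other (they receive
    ``d0*s0_2/(d0+df)``) but are excluded from hyperparameter fitting.
    """
    s2 = np.asarray(s2, float)
    ok = s2 > 0
    if ok.sum() < 50:
        raise ValueError("need >= 50 genes with positive variance to fit the prior")
    df = float(df_residual)
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(special.polygamma(1, df / 2))
    if excess <= 0:
        # no excess dispersion: the variances are exchangeable; complete
        # shrinkage to their geometric mean (identical s2 come back unchanged)
        d0 = math.inf
        s0_2 = float(np.exp(np.log(s2[ok]).mean()))
        s2_tilde = np.full_like(s2, s0_2)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
        s2_tilde = (d0 * s0_2 + df * s2) / (d0 + df)
    return EBFit(d0, s0_2, s2_tilde)


def moderated_t(gstats: GroupStats, eb: EBFit) -> pd.DataFrame:
    """Moderated t and two-sided p per gene.

    ``t = log2fc / sqrt(s2_tilde * (1/n_a + 1/n_b))`` referred to a t
    distribution with ``df_residual + d0`` degrees of freedom (normal when
    ``d0`` is infinite).  Zero-variance, zero-difference genes get t = 0.
    """
    scale = np.sqrt(eb.s2_tilde * (1.0 / gstats.n_a + 1.0 / gstats.n_b))
    lfc = gstats.log2fc
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, lfc / np.where(scale > 0, scale, 1.0),
                     np.where(lfc == 0, 0.0, np.sign(lfc) * np.inf))
    df_total = gstats.df_residual + eb.d0
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame({
        "log2fc": lfc, "t_mod": t, "p": p, "fdr": bh_fdr(p),
    }, index=gstats.gene_ids)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_analysis(matrix: pd.DataFrame, groups: pd.Series, contrast: tuple[str, str],
                cohort_id: str = "", contrast_name: str = "") -> pd.DataFrame:
    """Full per-gene table for one contrast: log2fc, t_mod, p, fdr."""
    gs = group_stats(matrix, groups, contrast)
    eb = eb_shrink(gs.s2, gs.df_residual)
    result = moderated_t(gs, eb)
    result.attrs.update(cohort_id=cohort_id, contrast=contrast_name or f"{contrast[0]}_vs_{contrast[1]}",
                        d0=eb.d0, s0_2=eb.s0_2)
    return result


def call_degs(results: pd.DataFrame, fdr_cut: float = 0.05, lfc_cut: float = 1.0,
              ) -> tuple[list[str], list[str]]:
    """Differentially expressed gene lists at ``fdr < fdr_cut`` and ``|log2fc| > lfc_cut``."""
    if results.empty:
        return [], []
    sig = results["fdr"] < fdr_cut
    up = results.index[sig & (results["log2fc"] > lfc_cut)].tolist()
    down = results.index[sig & (results["log2fc"] < -lfc_cut)].tolist()
    return up, down
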