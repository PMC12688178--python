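"""Mean-split stratification, weighted-KS gene-set enrichment, signature scores.

A cohort is split into "high" and "low" groups by one gene's mean
expression; genes are ranked by a signal-to-noise metric between the groups;
each gene set is scored by the weighted Kolmogorov-Smirnov running sum
(enrichment score, ES), normalized against a phenotype-permutation null
(NES, permutation p, sign-stratified FDR q).  Signature activity per sample
is the mean of gene-wise z-scores, and gene-vs-signature association is
tested by Spearman correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    name: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            self.members = list(dict.fromkeys(self.members))


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    leading_edge: list = field(default_factory=list)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def mean_split(expr: np.ndarray | pd.Series) -> np.ndarray:
    """Labels ``high`` (value >= mean) / ``low`` per sample."""
    values = np.asarray(expr, float)
    if values.size < 4:
        raise ValueError("mean split needs >= 4 samples")
    if values.max() == values.min():
        raise ValueError("constant expression vector: mean split undefined")
    return np.where(values >= values.mean(), "high", "low")


def _s2n_scores(x: np.ndarray, high: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene with the GSEA sd floor; falls back to the
    mean difference when a group is too small for a variance."""
    low = ~high
    if high.sum() < 3 or low.sum() < 3:
        log.info("rank_metric: a group has < 3 samples; falling back to log2fc metric")
        return x[:, high].mean(axis=1) - x[:, low].mean(axis=1)
    mh, ml = x[:, high].mean(axis=1), x[:, low].mean(axis=1)
    sh = x[:, high].std(axis=1, ddof=1)
    sl = x[:, low].std(axis=1, ddof=1)
    sh = np.maximum(sh, np.maximum(0.2 * np.abs(mh), 0.2))
    sl = np.maximum(sl, np.maximum(0.2 * np.abs(ml), 0.2))
    return (mh - ml) / (sh + sl)


def rank_metric(matrix: pd.DataFrame, labels: np.ndarray | pd.Series) -> pd.Series:
    """Ranked gene list, best "high"-associated gene first.

    Ties are broken lexicographically by gene id so the ranking is
    deterministic.
    """
    labels = np.asarray(labels)
    high = labels == "high"
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both 'high' and 'low' labels must be present")
    scores = _s2n_scores(matrix.to_numpy(float), high)
    s = pd.Series(scores, index=matrix.index, name="score")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def gsea_es(ranked: pd.Series, gene_set: GeneSet | list[str], weight: float = 1.0,
            ) -> tuple[float, np.ndarray]:
    """Weighted-KS running sum over a ranked list.

    Hits step up by ``|score|^weight`` (normalized over hits), misses step
    down by ``1/(N - |S|)``; the enrichment score is the walk value of
    maximal absolute deviation from zero, signed.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else list(gene_set)
    hit = ranked.index.isin(members)
    n = ranked.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("no gene-set member present in the ranked universe")
    if n_hit == n:
        raise ValueError("gene set covers the whole universe; misses undefined")
    w = np.abs(ranked.to_numpy(float)) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:          # all hit scores exactly zero: fall back to equal steps
        w_hit = hit.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~hit) / (n - n_hit)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i]), walk


def _leading_edge(ranked: pd.Series, members: list[str], walk: np.ndarray, es: float) -> list[str]:
    hit = ranked.index.isin(members)
    i = int(np.argmax(np.abs(walk)))
    if es >= 0:
        keep = np.zeros(ranked.size, bool)
        keep[: i + 1] = True
    else:
        keep = np.zeros(ranked.size, bool)
        keep[i:] = True
    return list(ranked.index[hit & keep])


def _permutation_labels(n: int, n_high: int, n_perm: int, rng: np.random.Generator):
    """Yield permuted high-masks; exhaustive when fewer distinct ones exist."""
    distinct = math.comb(n, n_high)
    if distinct < n_perm:
        log.warning("only %d distinct label permutations (< %d requested); using the exhaustive set",
                    distinct, n_perm)
        for combo in itertools.combinations(range(n), n_high):
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            yield mask
    else:
        for _ in range(n_perm):
            mask = np.zeros(n, bool)
            mask[rng.choice(n, size=n_high, replace=False)] = True
            yield mask


def gsea_permutation(matrix: pd.DataFrame, labels: np.ndarray | pd.Series,
                     sets: list[GeneSet], n_perm: int = 1000, weight: float = 1.0,
                     seed: int = 0) -> list[EnrichmentResult]:
    """Phenotype-permutation GSEA for a collection of gene sets.

    NES normalizes each observed ES by the mean |permuted ES| of matching
    sign; the permutation p is the fraction of same-sign permuted ES at
    least as extreme; q follows the sign-stratified NES-comparison
    convention.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(4,)))
    ranked = rank_metric(matrix, labels)
    observed = {}
    for s in sets:
        es, walk = gsea_es(ranked, s, weight)
        observed[s.name] = (es, _leading_edge(ranked, s.members, walk, es))

    x = matrix.to_numpy(float)
    n = labels.size
    n_high = int((labels == "high").sum())
    genes = matrix.index
    perm_es = {s.name: [] for s in sets}
    for mask in _permutation_labels(n, n_high, n_perm, rng):
        scores = _s2n_scores(x, mask)
        s_series = pd.Series(scores, index=genes)
        order = np.lexsort((genes.to_numpy(), -scores))
        ranked_p = s_series.iloc[order]
        for s in sets:
            es_p, _ = gsea_es(ranked_p, s, weight)
            perm_es[s.name].append(es_p)

    nes_obs, nes_perm_all = {}, {}
    results = []
    for s in sets:
        es, le = observed[s.name]
        perms = np.asarray(perm_es[s.name])
        same = perms[np.sign(perms) == np.sign(es)] if es != 0 else perms
        if same.size == 0:
            nes, p = np.nan, 0.0
        else:
            denom = np.abs(same).mean()
            nes = es / denom if denom > 0 else np.nan
            p = float((np.abs(same) >= abs(es)).mean())
        nes_obs[s.name] = nes
        pos = perms[perms > 0]
        neg = perms[perms < 0]
        nes_perm_all[s.name] = np.r_[pos / np.abs(pos).mean() if pos.size else [],
                                     neg / np.abs(neg).mean() if neg.size else []]
        results.append(EnrichmentResult(s.name, es, float(nes), p, np.nan, le))

    # sign-stratified FDR over NES values
    all_perm_nes = np.concatenate([v for v in nes_perm_all.values()]) if nes_perm_all else np.array([])
    obs_nes = np.array([nes_obs[r.set_name] for r in results])
    for r in results:
        nes = nes_obs[r.set_name]
        if not np.isfinite(nes):
            r.fdr_q = np.nan
            continue
        if nes >= 0:
            top = (all_perm_nes >= nes).mean() / max((all_perm_nes >= 0).mean(), 1e-12)
            bottom = (obs_nes[np.isfinite(obs_nes)] >= nes).mean() / max(
                (obs_nes[np.isfinite(obs_nes)] >= 0).mean(), 1e-12)
        else:
            top = (all_perm_nes <= nes).mean() / max((all_perm_nes < 0).mean(), 1e-12)
            bottom = (obs_nes[np.isfinite(obs_nes)] <= nes).mean() / max(
                (obs_nes[np.isfinite(obs_nes)] < 0).mean(), 1e-12)
        r.fdr_q = float(min(top / max(bottom, 1e-12), 1.0))
    return results


def signature_score(matrix: pd.DataFrame, gene_set: GeneSet | list[str]) -> pd.Series:
    """Per-sample signature activity: mean of gene-wise z-scores.

    Constant genes are dropped (they carry no sample ordering); absent
    members are logged.
    """
    members = gene_set.members if isinstance(gene_set, GeneSet) else list(gene_set)
    present = [g for g in members if g in matrix.index]
    absent = len(members) - len(present)
    if absent:
        log.info("signature_score: %d of %d members absent from matrix", absent, len(members))
    if not present:
        raise ValueError("no signature member present in the matrix")
    sub = matrix.loc[present]
    sd = sub.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all signature members are constant across samples")
    z = sub[keep].sub(sub[keep].mean(axis=1), axis=0).div(sd[keep], axis=0)
    return z.mean(axis=0)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (t-approximation)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4 or x.size != y.size:
        raise ValueError("spearman needs two equal-length vectors of >= 4 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman requires finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
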