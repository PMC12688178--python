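"""Synthetic multi-cohort prostate-cancer expression data with planted truth.

The generator emulates the shape of a public-repository meta-analysis:
several cohorts of heterogeneous size and scale, each with normal (N),
primary-tumor (PT) and metastasis (M) samples, a subset of cohorts carrying
biochemical-recurrence follow-up for their PT samples, and a single-cell
compartment summary (percent of expressing cells per cell type).

Planted gene classes
--------------------
``prognostic_up`` / ``prognostic_down``
    Carry a per-SD log-hazard coefficient (positive / negative) but no
    tissue-group shift.
``met_up`` / ``met_down``
    Shifted by ``+/- de_effect`` log2 units in M samples only.  A configurable
    fraction of them additionally carries a hazard coefficient: those genes are
    the "metastasis AND prognosis" truth the screen is meant to recover.
``initiation``
    Shifted already in PT (vs N) and further in M, i.e. progression genes that
    the initiation-exclusion arm of the screen must remove.
``null``
    No planted structure.

Hazard model
------------
Survival times for PT samples of follow-up cohorts are exponential with
hazard ``lambda0 * exp(eta)``, ``eta = sum_g beta_g * z_g`` over the
hazard-carrying genes (``z_g`` the gene's standardized log2 expression).
Hazard-carrying genes co-load on a single latent "tumor aggressiveness"
factor (loading ``prognostic_corr``), so each of them is a good marginal
readout of the composite risk score while the score's total variance stays
realistic.  Censoring is uniform on ``[0, followup_horizon]`` for a
``censoring_rate`` fraction of samples and administrative at the horizon
otherwise.  Times are reported at 0.1-month resolution, so ties occur as in
real recurrence data.

A second latent factor emulates the androgen-receptor program: 31 "signature"
genes load positively on it and one metastasis-and-prognosis gene (the
TCF19-like candidate, flagged ``ar_anticorr``) loads negatively, reproducing
the inverse gene-vs-signature correlation geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohorts import ExpressionCohort, SurvivalTable

TRUTH_CLASSES = ("prognostic_up", "prognostic_down", "met_up", "met_down",
                 "initiation", "null")
CELL_TYPES = ("epithelial", "endothelial", "fibroblast", "immune")

# spawn-key namespaces for deriving per-purpose child seeds from the master seed
_KEY_TRUTH = 1
_KEY_COHORT = 2
_KEY_COMPARTMENT = 3


@dataclass
class SimConfig:
    """Study conditions for the synthetic multi-cohort screen.

    Cohort sizes loosely follow the public prostate-cancer cohorts such a
    meta-analysis draws on (tens of normals, 50-200 primaries, 20-35
    metastases); four of the five cohorts carry follow-up.
    """

    n_cohorts: int = 5
    #: (n_N, n_PT, n_M) per cohort
    samples_per_group: tuple = ((29, 131, 19), (52, 200, 25), (20, 92, 25),
                                (18, 112, 23), (28, 59, 35))
    #: which cohorts carry biochemical-recurrence follow-up
    followup: tuple = (True, True, True, True, False)
    #: export scale per cohort; "linear" cohorts are written as 2**x
    scale: tuple = ("log2", "linear", "log2", "linear", "log2")
    n_genes: int = 2000
    frac_prognostic_up: float = 0.005
    frac_prognostic_down: float = 0.004
    frac_met_up: float = 0.010
    frac_met_down: float = 0.008
    frac_initiation: float = 0.010
    #: fraction of met_up / met_down genes that also carry hazard
    met_prognostic_fraction: float = 0.25
    #: log2-units shift of M samples for met genes (PT shift for initiation)
    de_effect: float = 1.5
    #: M shift of initiation genes = this multiple of their PT shift
    initiation_met_ratio: float = 1.5
    #: per-gene, per-SD log-hazard coefficient magnitude; with the default
    #: 27 hazard genes and loading 0.85 the composite risk score has SD ~1
    #: and each hazard gene's marginal Q1-vs-Q4 log-HR lands near 1.5-1.8,
    #: the strong-candidate regime such screens are built to detect
    hazard_beta: float = 0.045
    #: loading of hazard genes on the shared aggressiveness factor
    prognostic_corr: float = 0.85
    baseline_mu_range: tuple = (4.0, 12.0)
    #: scaled-inverse-chi-square prior for gene-wise variances
    var_prior_df: float = 4.0
    var_prior_scale: float = 0.25
    censoring_rate: float = 0.5
    followup_horizon: float = 120.0
    n_ar_genes: int = 31
    ar_loading: float = 0.75
    #: (aggressiveness, AR-factor) loadings of the TCF19-like gene
    ar_anticorr_loadings: tuple = (0.70, -0.60)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        for name in ("samples_per_group", "followup", "scale"):
            if len(getattr(self, name)) != self.n_cohorts:
                raise ValueError(f"{name} must have one entry per cohort")
        for trio in self.samples_per_group:
            if len(trio) != 3 or any(int(n) < 0 for n in trio):
                raise ValueError("samples_per_group entries must be (n_N, n_PT, n_M) >= 0")
        fracs = (self.frac_prognostic_up, self.frac_prognostic_down,
                 self.frac_met_up, self.frac_met_down, self.frac_initiation)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must be non-negative and sum to <= 1")
        if not 0 <= self.censoring_rate <= 1:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.followup_horizon <= 0:
            raise ValueError("followup_horizon must be positive")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def _rng(cfg_seed: int, *key: int) -> np.random.Generator:
    """Child generator at a fixed, documented offset from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=key))


def make_truth(config: SimConfig) -> pd.DataFrame:
    """Assign gene classes, effects and factor loadings.

    Returns a DataFrame indexed by gene_id with columns ``class``,
    ``de_effect``, ``hazard_beta``, ``ar_signature``, ``ar_anticorr``,
    ``aggr_loading``, ``ar_loading``, ``mu``, ``sigma``.
    """
    config.validate()
    rng = _rng(config.seed, _KEY_TRUTH)
    g = config.n_genes
    width = max(4, len(str(g)))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, g + 1)])

    counts = {
        "prognostic_up": int(round(config.frac_prognostic_up * g)),
        "prognostic_down": int(round(config.frac_prognostic_down * g)),
        "met_up": int(round(config.frac_met_up * g)),
        "met_down": int(round(config.frac_met_down * g)),
        "initiation": int(round(config.frac_initiation * g)),
    }
    order = rng.permutation(g)
    classes = np.full(g, "null", dtype=object)
    pos = 0
    for cls in ("prognostic_up", "prognostic_down", "met_up", "met_down", "initiation"):
        classes[order[pos:pos + counts[cls]]] = cls
        pos += counts[cls]

    de = np.zeros(g)
    de[classes == "met_up"] = config.de_effect
    de[classes == "met_down"] = -config.de_effect
    de[classes == "initiation"] = config.de_effect  # PT shift; M shift scaled in simulate

    beta = np.zeros(g)
    beta[classes == "prognostic_up"] = config.hazard_beta
    beta[classes == "prognostic_down"] = -config.hazard_beta
    for cls, sign in (("met_up", 1.0), ("met_down", -1.0)):
        idx = np.flatnonzero(classes == cls)
        k = int(round(config.met_prognostic_fraction * idx.size))
        beta[idx[:k]] = sign * config.hazard_beta  # idx order is the random permutation

    aggr = np.where(beta != 0, np.sign(beta) * config.prognostic_corr, 0.0)

    ar_sig = np.zeros(g, dtype=bool)
    nulls = np.flatnonzero(classes == "null")
    ar_sig[rng.choice(nulls, size=min(config.n_ar_genes, nulls.size), replace=False)] = True
    ar_load = np.where(ar_sig, config.ar_loading, 0.0)

    ar_anti = np.zeros(g, dtype=bool)
    epithelial = np.zeros(g, dtype=bool)
    met_prog_up = np.flatnonzero((classes == "met_up") & (beta > 0))
    if met_prog_up.size:
        j = met_prog_up[0]
        ar_anti[j] = True
        aggr[j], ar_load[j] = config.ar_anticorr_loadings
        # two epithelial-compartment candidates among the up-candidates,
        # emulating the single-cell filter that keeps 2 of the shortlist
        epithelial[met_prog_up[:2]] = True

    lo, hi = config.baseline_mu_range
    mu = rng.uniform(lo, hi, size=g)
    # sigma^2 ~ scaled-inv-chi2(d0, s0^2): true hyperparameters for EB recovery
    sigma2 = config.var_prior_df * config.var_prior_scale / rng.chisquare(config.var_prior_df, size=g)
    truth = pd.DataFrame({
        "class": classes, "de_effect": de, "hazard_beta": beta,
        "ar_signature": ar_sig, "ar_anticorr": ar_anti, "epithelial": epithelial,
        "aggr_loading": aggr, "ar_loading": ar_load,
        "mu": mu, "sigma": np.sqrt(sigma2),
    }, index=pd.Index(genes, name="gene_id"))
    return truth


def simulate_multicohort(config: SimConfig,
                         truth: pd.DataFrame | None = None,
                         ) -> tuple[list[ExpressionCohort], list[SurvivalTable], pd.DataFrame]:
    """Generate the full multi-cohort dataset.

    Deterministic for a fixed ``config.seed``.  Returns the cohorts (in
    config order), the survival tables of the follow-up cohorts, and the
    gene truth table.
    """
    if truth is None:
        truth = make_truth(config)
    mu = truth["mu"].to_numpy()
    sigma = truth["sigma"].to_numpy()
    w_a = truth["aggr_loading"].to_numpy()
    w_f = truth["ar_loading"].to_numpy()
    w_e = np.sqrt(np.clip(1.0 - w_a ** 2 - w_f ** 2, 0.0, None))
    de = truth["de_effect"].to_numpy()
    beta = truth["hazard_beta"].to_numpy()
    is_init = (truth["class"] == "initiation").to_numpy()
    is_met = truth["class"].isin(["met_up", "met_down"]).to_numpy()
    hazard_idx = np.flatnonzero(beta != 0)

    cohorts: list[ExpressionCohort] = []
    survivals: list[SurvivalTable] = []
    for c in range(config.n_cohorts):
        rng = _rng(config.seed, _KEY_COHORT, c)
        n_n, n_pt, n_m = (int(v) for v in config.samples_per_group[c])
        cid = f"c{c + 1}"
        groups = np.array(["N"] * n_n + ["PT"] * n_pt + ["M"] * n_m)
        n_s = groups.size
        samples = np.array([f"{cid}_s{i + 1:03d}" for i in range(n_s)])

        a = rng.standard_normal(n_s)            # aggressiveness factor
        f = rng.standard_normal(n_s)            # AR-program factor
        eps = rng.standard_normal((truth.shape[0], n_s))
        x = (mu[:, None]
             + sigma[:, None] * (np.outer(w_a, a) + np.outer(w_f, f) + w_e[:, None] * eps))
        # planted group shifts
        is_m = groups == "M"
        is_pt = groups == "PT"
        x[np.ix_(is_met, is_m)] += de[is_met, None]
        x[np.ix_(is_init, is_pt)] += de[is_init, None]
        x[np.ix_(is_init, is_m)] += config.initiation_met_ratio * de[is_init, None]

        if config.followup[c] and n_pt > 0:
            pt_cols = np.flatnonzero(is_pt)
            z = (x[np.ix_(hazard_idx, pt_cols)] - mu[hazard_idx, None]) / sigma[hazard_idx, None]
            eta = beta[hazard_idx] @ z
            lam0 = np.log(2.0) / (0.5 * config.followup_horizon)
            t_event = rng.exponential(1.0, size=pt_cols.size) / (lam0 * np.exp(eta))
            u = rng.uniform(size=pt_cols.size)
            c_time = np.where(u < config.censoring_rate,
                              rng.uniform(0.0, config.followup_horizon, size=pt_cols.size),
                              config.followup_horizon)
            time = np.maximum(np.round(np.minimum(t_event, c_time), 1), 0.1)
            event = (t_event <= c_time).astype(int)
            survivals.append(SurvivalTable(cid, pd.DataFrame(
                {"time": time, "event": event},
                index=pd.Index(samples[pt_cols], name="sample_id"))))

        if config.scale[c] == "linear":
            matrix = pd.DataFrame(np.power(2.0, x), index=truth.index, columns=samples)
            state = {"background_corrected": False, "log2": False, "quantile_normalized": False}
        else:
            matrix = pd.DataFrame(x, index=truth.index, columns=samples)
            state = {"background_corrected": False, "log2": True, "quantile_normalized": False}
        cohorts.append(ExpressionCohort(cid, matrix, pd.Series(groups, index=samples), state))
    return cohorts, survivals, truth


def simulate_compartment_table(truth: pd.DataFrame, epithelial_genes: set,
                               seed: int = 0,
                               high_pct: tuple = (40.0, 90.0),
                               low_pct: tuple = (0.0, 8.0)) -> pd.DataFrame:
    """Single-cell compartment summary: percent expressing and mean expression.

    Genes listed in ``epithelial_genes`` (a set of gene ids) get a high
    epithelial percent-expressing; every other gene is concentrated in one
    randomly chosen stromal compartment.  Deterministic for a fixed seed.
    """
    rng = _rng(int(seed), _KEY_COMPARTMENT)
    genes = truth.index.to_numpy()
    g = genes.size
    pct = {ct: rng.uniform(*low_pct, size=g) for ct in CELL_TYPES}
    mean_expr = {ct: rng.uniform(0.1, 3.0, size=g) for ct in CELL_TYPES}
    epi_mask = np.isin(genes, list(epithelial_genes))
    pct["epithelial"][epi_mask] = rng.uniform(*high_pct, size=int(epi_mask.sum()))
    stromal = np.array(CELL_TYPES[1:])[rng.integers(0, 3, size=g)]
    for ct in CELL_TYPES[1:]:
        pick = (stromal == ct) & ~epi_mask
        pct[ct][pick] = rng.uniform(*high_pct, size=int(pick.sum()))
    out = {}
    for ct in CELL_TYPES:
        out[f"pct_{ct}"] = np.round(pct[ct], 2)
        out[f"mean_{ct}"] = np.round(np.where(pct[ct] > 5, mean_expr[ct], 0.05 * mean_expr[ct]), 3)
    return pd.DataFrame(out, index=pd.Index(genes, name="gene_id"))


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", float_format="%.6g")


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the literal class label "null" must not become NaN
    truth = pd.read_csv(path, sep="\t", index_col="gene_id", keep_default_na=False)
    for col in ("ar_signature", "ar_anticorr", "epithelial"):
        if truth[col].dtype == object:
            truth[col] = truth[col] == "True"
    return truth
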