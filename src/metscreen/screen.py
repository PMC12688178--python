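"""Cross-cohort decision logic of the candidate screen.

Four stages, each a set operation over per-cohort statistics:

1. prognostic consistency — a gene must be significant (Q1-vs-Q4 LRT) in
   enough follow-up cohorts with one hazard direction;
2. metastasis selection — concordantly significant in M-vs-PT across
   cohorts, minus genes consistently altered already at initiation
   (PT-vs-N), isolating metastasis-specific changes;
3. intersection — metastasis candidates that are also consistently
   prognostic, optionally requiring the hazard direction to match the
   fold-change direction;
4. epithelial filter — candidates must be expressed predominantly in the
   tumor-epithelial compartment of single-cell data.

All thresholds live in :class:`ScreenConfig`; relaxing any cut-off can only
grow the output lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Stringency knobs of the screen; ``None`` counts mean "all cohorts"."""

    de_p_cut: float = 0.05
    de_lfc_cut: float = 0.0
    use_fdr: bool = False           # gate DE significance on fdr instead of p
    min_met_cohorts: int | None = None
    max_init_cohorts: int | None = None   # default: exclude iff concordant in ALL cohorts
    prog_p_cut: float = 0.05
    min_prog_cohorts: int | None = None
    require_direction_match: bool = True
    epithelial_pct_cut: float = 10.0

    def validate(self) -> None:
        for name in ("de_p_cut", "prog_p_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ScreenResult:
    """Per-gene flag table plus the surviving candidate lists at each stage."""

    flags: pd.DataFrame
    prognostic: list = field(default_factory=list)
    met_up_shortlist: list = field(default_factory=list)
    met_down_shortlist: list = field(default_factory=list)
    final_up: list = field(default_factory=list)
    final_down: list = field(default_factory=list)
    final_epithelial: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def _de_col(cfg: ScreenConfig) -> str:
    return "fdr" if cfg.use_fdr else "p"


def prognostic_consistency(results: dict[str, pd.DataFrame], cfg: ScreenConfig) -> pd.DataFrame:
    """Flag genes with a consistent recurrence-risk association across cohorts.

    ``results`` maps cohort id -> per-gene table with ``beta``, ``lrt_p``,
    ``converged``.  A gene is flagged iff it is significant in at least
    ``min_prog_cohorts`` cohorts and every significant cohort agrees on the
    hazard direction.  Missing or non-converged fits count as
    non-significant.  Returns per-gene ``n_sig``, ``direction``, ``flagged``.
    """
    if len(results) < 2:
        raise ValueError("prognostic consistency needs >= 2 follow-up cohorts")
    cfg.validate()
    need = cfg.min_prog_cohorts if cfg.min_prog_cohorts is not None else len(results)
    universe = sorted(set().union(*(set(df.index) for df in results.values())))
    n_sig = pd.Series(0, index=universe)
    pos = pd.Series(0, index=universe)
    neg = pd.Series(0, index=universe)
    for cid, df in results.items():
        missing = len(universe) - df.index.size
        if missing:
            log.info("prognostic_consistency: %d genes absent from cohort %s treated as non-significant",
                     missing, cid)
        sub = df.reindex(universe)
        sig = (sub["lrt_p"] < cfg.prog_p_cut) & sub["converged"].eq(True)
        n_sig += sig.astype(int)
        pos += (sig & (sub["beta"] > 0)).astype(int)
        neg += (sig & (sub["beta"] < 0)).astype(int)
    concordant = (pos == 0) | (neg == 0)
    flagged = (n_sig >= need) & concordant
    direction = np.where(pos > neg, 1, np.where(neg > pos, -1, 0))
    return pd.DataFrame({"n_sig": n_sig, "direction": direction,
                         "flagged": flagged}, index=pd.Index(universe, name="gene_id"))


def metastasis_selection(de_m_pt: dict[str, pd.DataFrame], de_pt_n: dict[str, pd.DataFrame],
                         cfg: ScreenConfig) -> tuple[list[str], list[str]]:
    """Metastasis-specific up/down gene lists.

    A gene enters ``met_up`` iff it is significantly up in at least
    ``min_met_cohorts`` M-vs-PT results with no cohort significantly down
    (sign concordance), and is NOT concordantly significant in PT-vs-N in
    more than ``max_init_cohorts`` cohorts (initiation exclusion);
    ``met_down`` symmetric.
    """
    cfg.validate()
    need = cfg.min_met_cohorts if cfg.min_met_cohorts is not None else len(de_m_pt)
    max_init = (cfg.max_init_cohorts if cfg.max_init_cohorts is not None
                else max(len(de_pt_n) - 1, 0))
    col = _de_col(cfg)
    universe = sorted(set().union(*(set(df.index) for df in de_m_pt.values())))

    def sig_counts(tables: dict[str, pd.DataFrame]) -> tuple[pd.Series, pd.Series]:
        up = pd.Series(0, index=universe)
        down = pd.Series(0, index=universe)
        for df in tables.values():
            sub = df.reindex(universe)
            sig = sub[col] < cfg.de_p_cut        # NaN (missing gene) compares False
            up += (sig & (sub["log2fc"] > cfg.de_lfc_cut)).astype(int)
            down += (sig & (sub["log2fc"] < -cfg.de_lfc_cut)).astype(int)
        return up, down

    met_up_n, met_down_n = sig_counts(de_m_pt)
    init_up_n, init_down_n = sig_counts(de_pt_n) if de_pt_n else (pd.Series(0, index=universe),) * 2
    # "consistently altered" at initiation: same direction in > max_init cohorts
    initiation = (init_up_n > max_init) | (init_down_n > max_init)
    met_up = (met_up_n >= need) & ~initiation
    met_down = (met_down_n >= need) & ~initiation
    return list(pd.Index(universe)[met_up]), list(pd.Index(universe)[met_down])


def intersect_candidates(prognostic_flags: pd.DataFrame, met_up: list[str],
                         met_down: list[str], cfg: ScreenConfig) -> ScreenResult:
    """Intersect metastasis candidates with the consistent-prognosis set."""
    cfg.validate()
    prognostic = prognostic_flags.index[prognostic_flags["flagged"]].tolist()
    prog = prognostic_flags.reindex(prognostic_flags.index.union(met_up + met_down))

    def final(candidates: list[str], want_sign: int) -> list[str]:
        out = []
        for gene in sorted(candidates):
            row = prog.loc[gene] if gene in prog.index else None
            if row is None or not bool(row.get("flagged", False)):
                continue
            if cfg.require_direction_match and int(row["direction"]) != want_sign:
                continue
            out.append(gene)
        return out

    final_up = final(met_up, +1)
    final_down = final(met_down, -1)
    # a gene can sit in both met lists only under lax cohort counts; keep the
    # finals disjoint by resolving on the prognostic hazard direction
    both = set(final_up) & set(final_down)
    for gene in both:
        direction = int(prog.loc[gene, "direction"])
        if direction >= 0:
            final_down.remove(gene)
        if direction <= 0:
            final_up.remove(gene)
    flags = pd.DataFrame(index=prognostic_flags.index)
    flags["prognostic_consistent"] = prognostic_flags["flagged"]
    flags["met_up"] = flags.index.isin(met_up)
    flags["met_down"] = flags.index.isin(met_down)
    counts = {
        "genes": int(prognostic_flags.shape[0]),
        "prognostic_consistent": len(prognostic),
        "met_up_shortlist": len(met_up),
        "met_down_shortlist": len(met_down),
        "final_up": len(final_up),
        "final_down": len(final_down),
    }
    return ScreenResult(flags=flags, prognostic=sorted(prognostic),
                        met_up_shortlist=sorted(met_up), met_down_shortlist=sorted(met_down),
                        final_up=final_up, final_down=final_down, counts=counts)


def epithelial_filter(candidates: list[str], compartment_table: pd.DataFrame,
                      cfg: ScreenConfig) -> list[str]:
    """Keep candidates expressed predominantly in the epithelial compartment.

    A candidate survives iff its epithelial percent-expressing is at least
    ``epithelial_pct_cut`` AND at least every stromal compartment's percent.
    Candidates absent from the table are dropped and logged.
    """
    pct_cols = [c for c in compartment_table.columns if c.startswith("pct_")]
    stromal = [c for c in pct_cols if c != "pct_epithelial"]
    kept = []
    for gene in sorted(candidates):
        if gene not in compartment_table.index:
            log.info("epithelial_filter: candidate %s absent from compartment table, dropped", gene)
            continue
        row = compartment_table.loc[gene]
        epi = float(row["pct_epithelial"])
        if epi >= cfg.epithelial_pct_cut and all(epi >= float(row[c]) for c in stromal):
            kept.append(gene)
    return kept
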