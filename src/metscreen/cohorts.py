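"""Core containers: expression cohorts, survival tables, and their on-disk dialect.

A cohort is a genes x samples matrix plus a per-sample tissue group label
(N = normal, PT = primary tumor, M = metastasis) and a record of which
normalization steps have been applied.  Follow-up cohorts additionally carry a
survival table (biochemical-recurrence time in months and an event flag) for
their primary-tumor samples.

On disk a cohort is ``expr_<id>.tsv`` (genes as rows, sample ids as header),
``clinical_<id>.csv`` (sample_id, group, time_months, event) and a JSON sidecar
``expr_<id>.norm.json`` holding the normalization state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GROUPS = ("N", "PT", "M")


@dataclass
class ExpressionCohort:
    """One cohort's expression matrix with sample annotations.

    Parameters
    ----------
    cohort_id : str
        Short identifier, used in file names.
    matrix : pandas.DataFrame
        Genes x samples, real-valued, gene ids as the index.
    sample_groups : pandas.Series
        Sample id -> group label in ``{"N", "PT", "M"}``; must cover every
        column of ``matrix``.
    normalization_state : dict
        Flags ``background_corrected``, ``log2``, ``quantile_normalized``
        plus any recorded shifts.
    """

    cohort_id: str
    matrix: pd.DataFrame
    sample_groups: pd.Series
    normalization_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.index.hasnans or not self.matrix.index.is_unique:
            raise ValueError(f"{self.cohort_id}: gene ids must be unique and non-missing")
        missing = set(self.matrix.columns) - set(self.sample_groups.index)
        if missing:
            raise ValueError(f"{self.cohort_id}: samples without group label: {sorted(missing)[:5]}")
        bad = set(self.sample_groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"{self.cohort_id}: unknown group labels {bad}")

    def samples_in(self, *groups: str) -> list[str]:
        """Column names belonging to any of the given tissue groups."""
        keep = self.sample_groups[self.sample_groups.isin(groups)].index
        return [s for s in self.matrix.columns if s in set(keep)]

    def copy(self) -> "ExpressionCohort":
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            matrix=self.matrix.copy(),
            sample_groups=self.sample_groups.copy(),
            normalization_state=dict(self.normalization_state),
        )


@dataclass
class SurvivalTable:
    """Biochemical-recurrence follow-up for one cohort.

    ``data`` is indexed by sample id with columns ``time`` (months, > 0) and
    ``event`` (1 = recurrence, 0 = censored).
    """

    cohort_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"time", "event"} <= set(self.data.columns):
            raise ValueError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise ValueError(f"{self.cohort_id}: follow-up times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError(f"{self.cohort_id}: event flags must be 0/1")

    @property
    def time(self):
        return self.data["time"].to_numpy(float)

    @property
    def event(self):
        return self.data["event"].to_numpy(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


# ---------------------------------------------------------------------------
# on-disk dialect

_FLOAT_FMT = "%.6g"


def write_cohort(cohort: ExpressionCohort, outdir: str | Path,
                 survival: SurvivalTable | None = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = cohort.cohort_id
    cohort.matrix.to_csv(outdir / f"expr_{cid}.tsv", sep="\t",
                         float_format=_FLOAT_FMT, index_label="gene_id")
    clin = pd.DataFrame({
        "sample_id": cohort.matrix.columns,
        "group": cohort.sample_groups.reindex(cohort.matrix.columns).to_numpy(),
    })
    if survival is not None:
        surv = survival.data.reindex(clin["sample_id"])
        clin["time_months"] = surv["time"].to_numpy()
        clin["event"] = surv["event"].to_numpy()
    else:
        clin["time_months"] = ""
        clin["event"] = ""
    clin.to_csv(outdir / f"clinical_{cid}.csv", index=False, float_format=_FLOAT_FMT)
    with open(outdir / f"expr_{cid}.norm.json", "w") as fh:
        json.dump(cohort.normalization_state, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cohort(outdir: str | Path, cohort_id: str) -> tuple[ExpressionCohort, SurvivalTable | None]:
    outdir = Path(outdir)
    matrix = pd.read_csv(outdir / f"expr_{cohort_id}.tsv", sep="\t", index_col="gene_id")
    clin = pd.read_csv(outdir / f"clinical_{cohort_id}.csv", dtype={"sample_id": str})
    groups = pd.Series(clin["group"].to_numpy(), index=clin["sample_id"])
    state = {}
    sidecar = outdir / f"expr_{cohort_id}.norm.json"
    if sidecar.exists():
        state = json.loads(sidecar.read_text())
    cohort = ExpressionCohort(cohort_id, matrix, groups, state)
    survival = None
    has_fu = clin["time_months"].notna() if "time_months" in clin else None
    if has_fu is not None and has_fu.any():
        fu = clin[has_fu]
        survival = SurvivalTable(cohort_id, pd.DataFrame(
            {"time": fu["time_months"].to_numpy(float), "event": fu["event"].to_numpy(int)},
            index=pd.Index(fu["sample_id"], name="sample_id")))
    return cohort, survival
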