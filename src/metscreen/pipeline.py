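"""One reproducible run: simulate -> harmonize -> DE -> prognosis -> screen -> enrichment.

All randomness flows from a single master seed; every stage writes plain
TSV/CSV/JSON and the run manifest records the config snapshot, per-file
SHA-256 digests and the per-stage gene counts, so a run can be verified to
reproduce byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohorts import ExpressionCohort, SurvivalTable, write_cohort
from .diffexpr import de_analysis
from .enrichment import GeneSet, gsea_permutation, signature_score, spearman
from .harmonize import HarmonizePolicy, harmonize
from .screen import (ScreenConfig, ScreenResult, epithelial_filter,
                     intersect_candidates, metastasis_selection,
                     prognostic_consistency)
from .survival import prognosis_screen
from .synthetic_cohorts import SimConfig, simulate_compartment_table, simulate_multicohort

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class EnrichmentConfig:
    """Settings of the mean-split enrichment stage."""

    target_gene: str = "auto"       # "auto" = the planted AR-anticorrelated gene
    gene_sets: str = "planted_ar"   # "planted_ar" or a GMT path
    n_perm: int = 200
    weight: float = 1.0
    n_control_sets: int = 3
    control_set_size: int = 25


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    harmonize: HarmonizePolicy = field(default_factory=HarmonizePolicy)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for section, default in (("sim", cfg.sim), ("harmonize", cfg.harmonize),
                                 ("screen", cfg.screen), ("enrichment", cfg.enrichment)):
            overrides = raw.get(section, {})
            if overrides:
                fields = {f.name for f in dataclasses.fields(default)}
                unknown = set(overrides) - fields
                if unknown:
                    raise ValueError(f"unknown keys in config section '{section}': {sorted(unknown)}")
                coerced = {k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                           if isinstance(v, list) else v
                           for k, v in overrides.items()}
                setattr(cfg, section, replace(default, **coerced))
        return cfg

    def snapshot(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in ("sim", "harmonize", "screen", "enrichment")}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


@dataclass
class RunContext:
    """Everything a run computed, for in-memory use by tests and drivers."""

    cohorts: list
    survivals: list
    truth: pd.DataFrame
    compartments: pd.DataFrame
    de_m_pt: dict
    de_pt_n: dict
    prognosis: dict
    screen_result: ScreenResult
    enrichment: list | None
    correlation: dict | None
    manifest: dict


def run_screen(config: PipelineConfig, seed: int, outdir: str | Path | None = None,
               with_enrichment: bool = True) -> RunContext:
    """Execute the full screen for one seed; optionally write all artifacts."""
    sim_cfg = config.sim.with_seed(seed)
    cohorts, survivals, truth = simulate_multicohort(sim_cfg)
    epithelial = set(truth.index[truth["epithelial"]]) if "epithelial" in truth else set()
    compartments = simulate_compartment_table(truth, epithelial, seed=seed)
    surv_by_id = {s.cohort_id: s for s in survivals}

    harmonized = [harmonize(c, config.harmonize) for c in cohorts]

    de_m_pt: dict[str, pd.DataFrame] = {}
    de_pt_n: dict[str, pd.DataFrame] = {}
    for cohort in harmonized:
        for name, pair, store in (("M_vs_PT", ("M", "PT"), de_m_pt),
                                  ("PT_vs_N", ("PT", "N"), de_pt_n)):
            counts = cohort.sample_groups.value_counts()
            if counts.get(pair[0], 0) < 2 or counts.get(pair[1], 0) < 2:
                log.info("cohort %s: skipping contrast %s (insufficient samples)", cohort.cohort_id, name)
                continue
            store[cohort.cohort_id] = de_analysis(cohort.matrix, cohort.sample_groups,
                                                  pair, cohort.cohort_id, name)

    prognosis = {c.cohort_id: prognosis_screen(c.matrix, surv_by_id[c.cohort_id])
                 for c in harmonized if c.cohort_id in surv_by_id}

    prog_flags = prognostic_consistency(prognosis, config.screen)
    met_up, met_down = metastasis_selection(de_m_pt, de_pt_n, config.screen)
    result = intersect_candidates(prog_flags, met_up, met_down, config.screen)
    result.final_epithelial = epithelial_filter(result.final_up, compartments, config.screen)
    result.counts["final_epithelial"] = len(result.final_epithelial)

    enr_results = corr = None
    if with_enrichment:
        enr_results, corr = _enrichment_stage(config, seed, harmonized, surv_by_id, truth)

    manifest = {
        "seed": int(seed),
        "version": __version__,
        "config": config.snapshot(),
        "stage_counts": result.counts,
        "files": {},
    }
    ctx = RunContext(harmonized, survivals, truth, compartments, de_m_pt, de_pt_n,
                     prognosis, result, enr_results, corr, manifest)
    if outdir is not None:
        _write_run(ctx, cohorts, Path(outdir))
    return ctx


def _largest_followup(harmonized, surv_by_id) -> tuple[ExpressionCohort, SurvivalTable]:
    best = max((c for c in harmonized if c.cohort_id in surv_by_id),
               key=lambda c: len(surv_by_id[c.cohort_id].sample_ids))
    return best, surv_by_id[best.cohort_id]


def _enrichment_stage(config: PipelineConfig, seed: int, harmonized, surv_by_id, truth):
    """Mean-split GSEA of the AR program against the TCF19-like target gene."""
    ecfg = config.enrichment
    cohort, surv = _largest_followup(harmonized, surv_by_id)
    pt = cohort.samples_in("PT")
    matrix = cohort.matrix[pt]
    if ecfg.target_gene == "auto":
        anticorr = truth.index[truth["ar_anticorr"]]
        if anticorr.empty:
            log.info("no planted AR-anticorrelated gene; skipping enrichment stage")
            return None, None
        target = anticorr[0]
    else:
        target = ecfg.target_gene
    if target not in matrix.index:
        raise ValueError(f"enrichment target gene {target!r} absent from matrix")

    if ecfg.gene_sets == "planted_ar":
        ar_members = list(truth.index[truth["ar_signature"]])
        sets = [GeneSet("AR_SIGNATURE", "planted androgen-receptor program", ar_members)]
        rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(5,)))
        pool = truth.index[(truth["class"] == "null") & ~truth["ar_signature"]].to_numpy()
        for i in range(ecfg.n_control_sets):
            members = list(rng.choice(pool, size=min(ecfg.control_set_size, pool.size), replace=False))
            sets.append(GeneSet(f"CONTROL_{i + 1}", "random null genes", members))
    else:
        from .enrichment import read_gmt
        sets = read_gmt(ecfg.gene_sets)
        if not sets:
            raise ValueError(f"no gene sets parsed from {ecfg.gene_sets}")
        ar_members = sets[0].members

    from .enrichment import mean_split
    labels = mean_split(matrix.loc[target])
    enr = gsea_permutation(matrix, labels, sets, n_perm=ecfg.n_perm,
                           weight=ecfg.weight, seed=seed)
    score = signature_score(matrix, ar_members)
    rho, p = spearman(matrix.loc[target].to_numpy(), score.to_numpy())
    corr = {"cohort": cohort.cohort_id, "target_gene": str(target),
            "signature": "AR_SIGNATURE", "n_samples": len(pt),
            "spearman_rho": rho, "spearman_p": p}
    return enr, corr


def _write_run(ctx: RunContext, raw_cohorts, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    surv_by_id = {s.cohort_id: s for s in ctx.survivals}
    for cohort in raw_cohorts:
        write_cohort(cohort, outdir / "data", surv_by_id.get(cohort.cohort_id))
    _write_tsv(ctx.truth, outdir / "data" / "truth.tsv")
    _write_tsv(ctx.compartments, outdir / "data" / "compartments.tsv")
    for cohort in ctx.cohorts:
        write_cohort(cohort, outdir / "harmonized", surv_by_id.get(cohort.cohort_id))
    for store, tag in ((ctx.de_m_pt, "M_vs_PT"), (ctx.de_pt_n, "PT_vs_N")):
        for cid, df in store.items():
            _write_tsv(df, outdir / "de" / f"de_{cid}_{tag}.tsv")
    for cid, df in ctx.prognosis.items():
        _write_tsv(df, outdir / "prognosis" / f"prognosis_{cid}.tsv")
    _write_tsv(ctx.screen_result.flags, outdir / "screen" / "flags.tsv")
    summary = {
        "counts": ctx.screen_result.counts,
        "prognostic": ctx.screen_result.prognostic,
        "met_up_shortlist": ctx.screen_result.met_up_shortlist,
        "met_down_shortlist": ctx.screen_result.met_down_shortlist,
        "final_up": ctx.screen_result.final_up,
        "final_down": ctx.screen_result.final_down,
        "final_epithelial": ctx.screen_result.final_epithelial,
    }
    (outdir / "screen").mkdir(parents=True, exist_ok=True)
    (outdir / "screen" / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    if ctx.enrichment is not None:
        rows = [{"set": r.set_name, "es": r.es, "nes": r.nes, "p_perm": r.p_perm,
                 "fdr_q": r.fdr_q, "leading_edge": ",".join(r.leading_edge)}
                for r in ctx.enrichment]
        _write_tsv(pd.DataFrame(rows).set_index("set"), outdir / "enrichment" / "enrichment.tsv")
        (outdir / "enrichment" / "correlation.json").write_text(
            json.dumps(ctx.correlation, indent=1, default=float) + "\n")
    files = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            files[str(path.relative_to(outdir))] = _sha256(path)
    ctx.manifest["files"] = files
    (outdir / "manifest.json").write_text(json.dumps(ctx.manifest, indent=1, sort_keys=True) + "\n")


def run_enrichment(config: PipelineConfig, seed: int, outdir: str | Path | None = None):
    """Standalone enrichment stage on freshly simulated, harmonized cohorts."""
    sim_cfg = config.sim.with_seed(seed)
    cohorts, survivals, truth = simulate_multicohort(sim_cfg)
    harmonized = [harmonize(c, config.harmonize) for c in cohorts]
    surv_by_id = {s.cohort_id: s for s in survivals}
    enr, corr = _enrichment_stage(config, seed, harmonized, surv_by_id, truth)
    if outdir is not None and enr is not None:
        outdir = Path(outdir)
        rows = [{"set": r.set_name, "es": r.es, "nes": r.nes, "p_perm": r.p_perm,
                 "fdr_q": r.fdr_q, "leading_edge": ",".join(r.leading_edge)}
                for r in enr]
        _write_tsv(pd.DataFrame(rows).set_index("set"), outdir / "enrichment.tsv")
        (outdir / "correlation.json").write_text(json.dumps(corr, indent=1, default=float) + "\n")
    return enr, corr
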