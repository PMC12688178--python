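"""Screen decision logic: voting rules, monotonicity, determinism, recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import metscreen as ms
from metscreen.screen import (ScreenConfig, epithelial_filter,
                              intersect_candidates, metastasis_selection,
                              prognostic_consistency)
from metscreen.synthetic_cohorts import make_truth, simulate_compartment_table


def prog_table(rows: dict) -> pd.DataFrame:
    """rows: gene -> (beta, lrt_p, converged)."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["beta", "lrt_p", "converged"])
    df.index.name = "gene_id"
    return df


def de_table(rows: dict) -> pd.DataFrame:
    """rows: gene -> (log2fc, p); fdr mirrored from p for rule tests."""
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["log2fc", "p"])
    df["fdr"] = df["p"]
    df.index.name = "gene_id"
    return df


class TestPrognosticConsistency:
    def test_significant_same_direction_everywhere_is_flagged(self):
        res = {c: prog_table({"g1": (0.8, 0.01, True)}) for c in "abcd"}
        flags = prognostic_consistency(res, ScreenConfig())
        assert bool(flags.loc["g1", "flagged"]) and flags.loc["g1", "direction"] == 1

    def test_direction_clash_blocks_flag(self):
        res = {c: prog_table({"g1": (0.8, 0.01, True)}) for c in "abc"}
        res["d"] = prog_table({"g1": (-0.9, 0.01, True)})
        flags = prognostic_consistency(res, ScreenConfig())
        assert not bool(flags.loc["g1", "flagged"])

    def test_missing_gene_counts_as_nonsignificant(self):
        res = {c: prog_table({"g1": (0.8, 0.01, True)}) for c in "abc"}
        res["d"] = prog_table({"g2": (0.5, 0.5, True)})
        flags = prognostic_consistency(res, ScreenConfig())
        assert not bool(flags.loc["g1", "flagged"])
        cfg = ScreenConfig(min_prog_cohorts=3)
        assert bool(prognostic_consistency(res, cfg).loc["g1", "flagged"])

    def test_nonconverged_fits_do_not_count(self):
        res = {c: prog_table({"g1": (0.8, 0.001, c != "d")}) for c in "abcd"}
        assert not bool(prognostic_consistency(res, ScreenConfig()).loc["g1", "flagged"])

    def test_needs_two_cohorts(self):
        with pytest.raises(ValueError):
            prognostic_consistency({"a": prog_table({"g": (1, 0.01, True)})}, ScreenConfig())

    def test_planted_recovery_at_unit_hazard(self):
        # independent prognostic genes at per-SD log-hazard 1.0, four
        # follow-up cohorts of 150 primaries: >= 80% flagged, nulls <= 1%
        from metscreen.harmonize import harmonize
        from metscreen.survival import prognosis_screen
        cfg = replace(
            ms.SimConfig(), n_cohorts=4, n_genes=400,
            samples_per_group=((4, 150, 4),) * 4, followup=(True,) * 4,
            scale=("log2",) * 4, frac_prognostic_up=5 / 400, frac_prognostic_down=0.0,
            frac_met_up=0.0, frac_met_down=0.0, frac_initiation=0.0,
            n_ar_genes=0, hazard_beta=1.0, prognostic_corr=0.0)
        cohorts, survivals, truth = ms.simulate_multicohort(cfg.with_seed(21))
        prog = {s.cohort_id: prognosis_screen(harmonize(c).matrix, s)
                for c, s in zip(cohorts, survivals)}
        flags = prognostic_consistency(prog, ScreenConfig())
        planted = truth.index[truth["hazard_beta"] > 0]
        nulls = truth.index[truth["hazard_beta"] == 0]
        assert flags.loc[planted, "flagged"].mean() >= 0.8
        assert flags.loc[nulls, "flagged"].mean() <= 0.01


class TestMetastasisSelection:
    def test_concordant_met_gene_without_initiation_signal_selected(self):
        m = {c: de_table({"g1": (1.0, 0.001)}) for c in "abcde"}
        n = {c: de_table({"g1": (0.1, 0.9)}) for c in "abcde"}
        up, down = metastasis_selection(m, n, ScreenConfig())
        assert up == ["g1"] and down == []

    def test_gene_up_in_both_contrasts_excluded_as_initiation(self):
        m = {c: de_table({"g1": (1.0, 0.001)}) for c in "abcde"}
        n = {c: de_table({"g1": (1.2, 0.001)}) for c in "abcde"}
        up, down = metastasis_selection(m, n, ScreenConfig())
        assert up == []

    def test_initiation_exclusion_requires_full_concordance_by_default(self):
        m = {c: de_table({"g1": (1.0, 0.001)}) for c in "abcde"}
        n = {c: de_table({"g1": (1.2, 0.001 if c != "e" else 0.9)}) for c in "abcde"}
        up, _ = metastasis_selection(m, n, ScreenConfig())
        assert up == ["g1"]                     # significant in only 4/5 PT-vs-N

    def test_down_side_symmetric(self):
        m = {c: de_table({"g1": (-1.0, 0.001)}) for c in "abcde"}
        up, down = metastasis_selection(m, {}, ScreenConfig())
        assert down == ["g1"] and up == []


class TestIntersectCandidates:
    def _flags(self, rows):
        df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=["n_sig", "direction", "flagged"])
        df.index.name = "gene_id"
        return df

    def test_disjoint_inputs_give_empty_finals(self):
        flags = self._flags({"g1": (4, 1, True), "g2": (0, 0, False)})
        res = intersect_candidates(flags, ["g2"], [], ScreenConfig())
        assert res.final_up == [] and res.final_down == []

    def test_direction_mismatch_excluded_when_required(self):
        flags = self._flags({"g1": (4, -1, True)})
        cfg = ScreenConfig(require_direction_match=True)
        assert intersect_candidates(flags, ["g1"], [], cfg).final_up == []
        cfg_off = ScreenConfig(require_direction_match=False)
        assert intersect_candidates(flags, ["g1"], [], cfg_off).final_up == ["g1"]

    def test_counts_consistent_and_lists_nested(self):
        flags = self._flags({"g1": (4, 1, True), "g2": (4, -1, True), "g3": (0, 0, False)})
        res = intersect_candidates(flags, ["g1", "g3"], ["g2"], ScreenConfig())
        assert res.final_up == ["g1"] and res.final_down == ["g2"]
        assert set(res.final_up) <= set(res.met_up_shortlist)
        assert res.counts["final_up"] == 1 and res.counts["met_up_shortlist"] == 2
        assert not set(res.final_up) & set(res.final_down)


class TestEpithelialFilter:
    def _table(self, rows):
        df = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["pct_epithelial", "pct_endothelial", "pct_fibroblast", "pct_immune"])
        df.index.name = "gene_id"
        return df

    def test_threshold_and_dominance_rules(self):
        table = self._table({
            "kept": (15.0, 4.0, 3.0, 2.0),
            "low": (8.0, 1.0, 1.0, 1.0),          # below the 10% cut
            "stromal": (15.0, 40.0, 2.0, 1.0),    # endothelial dominates
        })
        kept = epithelial_filter(["kept", "low", "stromal"], table, ScreenConfig())
        assert kept == ["kept"]

    def test_absent_candidate_dropped(self):
        table = self._table({"g1": (50.0, 1.0, 1.0, 1.0)})
        assert epithelial_filter(["g1", "ghost"], table, ScreenConfig()) == ["g1"]

    def test_nine_candidates_two_planted_epithelial(self):
        # reconstruction of the shortlist-to-epithelial step: of 9
        # candidates only the 2 planted epithelial genes survive
        truth = make_truth(replace(ms.SimConfig(), n_genes=200).with_seed(3))
        candidates = list(truth.index[:9])
        planted = set(candidates[2:4])
        table = simulate_compartment_table(truth, planted, seed=3)
        kept = epithelial_filter(candidates, table, ScreenConfig())
        assert set(kept) == planted


class TestScreenProperties:
    @pytest.fixture()
    def random_inputs(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(120)]
        prog = {c: prog_table({g: (rng.normal(), rng.uniform(), True) for g in genes})
                for c in "abcd"}
        m = {c: de_table({g: (rng.normal(), rng.uniform() ** 2) for g in genes})
             for c in "abcde"}
        n = {c: de_table({g: (rng.normal(), rng.uniform()) for g in genes})
             for c in "abcde"}
        return prog, m, n

    def test_relaxing_cutoffs_never_shrinks_lists(self, random_inputs):
        prog, m, n = random_inputs
        strict = ScreenConfig(prog_p_cut=0.05, de_p_cut=0.05, min_prog_cohorts=4,
                              min_met_cohorts=4)
        lax = ScreenConfig(prog_p_cut=0.3, de_p_cut=0.3, min_prog_cohorts=2,
                           min_met_cohorts=2, max_init_cohorts=5)
        f_strict = prognostic_consistency(prog, strict)
        f_lax = prognostic_consistency(prog, lax)
        assert set(f_strict.index[f_strict["flagged"]]) <= set(f_lax.index[f_lax["flagged"]])
        up_s, down_s = metastasis_selection(m, n, strict)
        # lax initiation exclusion must also be relaxed for joint monotonicity
        up_l, down_l = metastasis_selection(m, n, lax)
        assert set(up_s) <= set(up_l) and set(down_s) <= set(down_l)

    def test_gene_order_invariance(self, random_inputs):
        prog, m, n = random_inputs
        cfg = ScreenConfig(min_met_cohorts=3, de_p_cut=0.2, prog_p_cut=0.2,
                           min_prog_cohorts=3)
        shuffled_m = {c: df.sample(frac=1, random_state=1) for c, df in m.items()}
        shuffled_prog = {c: df.sample(frac=1, random_state=2) for c, df in prog.items()}
        a = intersect_candidates(prognostic_consistency(prog, cfg),
                                 *metastasis_selection(m, n, cfg), cfg)
        b = intersect_candidates(prognostic_consistency(shuffled_prog, cfg),
                                 *metastasis_selection(shuffled_m, n, cfg), cfg)
        assert a.final_up == b.final_up and a.final_down == b.final_down
        assert a.met_up_shortlist == b.met_up_shortlist


class TestEndToEndRecovery:
    def test_planted_candidates_dominate_finals(self, default_run):
        r = default_run.screen_result
        truth = default_run.truth
        t_up = set(truth.index[(truth["class"] == "met_up") & (truth["hazard_beta"] > 0)])
        t_dn = set(truth.index[(truth["class"] == "met_down") & (truth["hazard_beta"] < 0)])
        j_up = len(set(r.final_up) & t_up) / len(set(r.final_up) | t_up)
        j_dn = len(set(r.final_down) & t_dn) / len(set(r.final_down) | t_dn)
        assert j_up >= 0.6 and j_dn >= 0.6

    def test_initiation_genes_do_not_leak(self, default_run):
        truth = default_run.truth
        init = set(truth.index[truth["class"] == "initiation"])
        r = default_run.screen_result
        leaked = (set(r.met_up_shortlist) | set(r.met_down_shortlist)) & init
        assert len(leaked) <= 0.05 * len(init)

    def test_epithelial_stage_keeps_planted_pair(self, default_run):
        truth = default_run.truth
        planted = set(truth.index[truth["epithelial"]])
        assert set(default_run.screen_result.final_epithelial) == planted
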