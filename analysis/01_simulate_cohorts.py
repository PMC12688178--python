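"""Generate the synthetic multi-cohort study.

Five prostate-cancer-like expression cohorts (N/PT/M groups, heterogeneous
sizes and scales), biochemical-recurrence follow-up for four of them, a
single-cell compartment summary, and the gene-level ground truth.  Writes
the full matrices under scratch/ and a compact study description under
results/.
"""

import argparse

import pandas as pd

import metscreen as ms
from metscreen.cohorts import write_cohort
from metscreen.synthetic_cohorts import simulate_compartment_table, write_truth

from _common import DEFAULT_SEED, outdirs


def main(seed: int) -> None:
    scratch, results = outdirs()
    cfg = ms.SimConfig().with_seed(seed)
    cohorts, survivals, truth = ms.simulate_multicohort(cfg)
    surv = {s.cohort_id: s for s in survivals}
    datadir = scratch / "data"
    for cohort in cohorts:
        write_cohort(cohort, datadir, surv.get(cohort.cohort_id))
    write_truth(truth, datadir / "truth.tsv")
    comp = simulate_compartment_table(truth, set(truth.index[truth["epithelial"]]), seed=seed)
    comp.to_csv(datadir / "compartments.tsv", sep="\t", float_format="%.6g")

    rows = []
    for cohort in cohorts:
        counts = cohort.sample_groups.value_counts()
        s = surv.get(cohort.cohort_id)
        rows.append({
            "cohort": cohort.cohort_id,
            "n_normal": int(counts.get("N", 0)),
            "n_primary": int(counts.get("PT", 0)),
            "n_metastasis": int(counts.get("M", 0)),
            "followup": s is not None,
            "events": int(s.event.sum()) if s is not None else 0,
            "scale": "log2" if cohort.normalization_state.get("log2") else "linear",
        })
    summary = pd.DataFrame(rows).set_index("cohort")
    summary.to_csv(results / "cohort_summary.tsv", sep="\t")
    classes = truth["class"].value_counts().rename_axis("class").to_frame("n_genes")
    classes.to_csv(results / "planted_classes.tsv", sep="\t")
    print(f"seed {seed}: wrote {len(cohorts)} cohorts ({cfg.n_genes} genes) to {datadir}")
    print(summary.to_string())
    print("\nplanted gene classes:")
    print(classes.to_string())


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    main(parser.parse_args().seed)
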