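"""Per-cohort moderated differential expression for the two screen contrasts.

M-vs-PT (metastasis) and PT-vs-N (initiation) in every cohort that has the
samples, with empirical-Bayes variance moderation and BH FDR.  Full tables
go to scratch/; the per-cohort significant-gene counts and the strict DEG
calls (FDR < 0.05, |log2FC| > 1) go to results/.
"""

import argparse

import pandas as pd

from metscreen.cohorts import read_cohort
from metscreen.diffexpr import call_degs, de_analysis

from _common import COHORT_IDS, DEFAULT_SEED, outdirs

CONTRASTS = {"M_vs_PT": ("M", "PT"), "PT_vs_N": ("PT", "N")}


def main(seed: int) -> None:
    scratch, results = outdirs()
    dedir = scratch / "de"
    dedir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cid in COHORT_IDS:
        cohort, _ = read_cohort(scratch / "harmonized", cid)
        for name, pair in CONTRASTS.items():
            counts = cohort.sample_groups.value_counts()
            if counts.get(pair[0], 0) < 2 or counts.get(pair[1], 0) < 2:
                continue
            res = de_analysis(cohort.matrix, cohort.sample_groups, pair, cid, name)
            res.to_csv(dedir / f"de_{cid}_{name}.tsv", sep="\t", float_format="%.6g")
            up, down = call_degs(res, fdr_cut=0.05, lfc_cut=1.0)
            rows.append({
                "cohort": cid, "contrast": name,
                "sig_p05_up": int(((res["p"] < 0.05) & (res["log2fc"] > 0)).sum()),
                "sig_p05_down": int(((res["p"] < 0.05) & (res["log2fc"] < 0)).sum()),
                "deg_fdr05_lfc1_up": len(up), "deg_fdr05_lfc1_down": len(down),
                "eb_prior_df": round(res.attrs["d0"], 2),
            })
    summary = pd.DataFrame(rows).set_index(["cohort", "contrast"])
    summary.to_csv(results / "de_summary.tsv", sep="\t")
    print(summary.to_string())


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    main(parser.parse_args().seed)
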