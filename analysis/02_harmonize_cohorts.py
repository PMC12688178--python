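"""Harmonize the cohorts: detect scale, log2-transform where needed,
quantile-normalize.

Reads the raw matrices written by 01, applies the "when needed" policy, and
records which corrections each cohort actually received.
"""

import argparse

import pandas as pd

from metscreen.cohorts import read_cohort, write_cohort
from metscreen.harmonize import HarmonizePolicy, detect_scale, harmonize

from _common import COHORT_IDS, DEFAULT_SEED, outdirs


def main(seed: int) -> None:
    scratch, results = outdirs()
    datadir = scratch / "data"
    outdir = scratch / "harmonized"
    policy = HarmonizePolicy()
    rows = []
    for cid in COHORT_IDS:
        cohort, survival = read_cohort(datadir, cid)
        scale_in = detect_scale(cohort.matrix, policy.scale_cutoff)
        out = harmonize(cohort, policy)
        write_cohort(out, outdir, survival)
        rows.append({
            "cohort": cid,
            "input_scale": scale_in,
            "log2_applied": scale_in == "linear",
            "background_shift": out.normalization_state.get("background_shift", 0.0),
            "quantile_normalized": out.normalization_state.get("quantile_normalized", False),
        })
    summary = pd.DataFrame(rows).set_index("cohort")
    summary.to_csv(results / "harmonization_summary.tsv", sep="\t")
    print(f"harmonized {len(rows)} cohorts into {outdir}")
    print(summary.to_string())


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    main(parser.parse_args().seed)
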