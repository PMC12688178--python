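"""Molecular association of the nominated target gene with the AR program.

Mean-split stratification of the largest follow-up cohort's primary tumors
by the TCF19-like candidate, phenotype-permutation GSEA of the planted
31-gene AR signature (plus random control sets), and Spearman correlation
between the candidate and the per-sample signature score.
"""

import argparse
import json

import numpy as np
import pandas as pd

from metscreen.cohorts import read_cohort
from metscreen.enrichment import (GeneSet, gsea_permutation, mean_split,
                                  signature_score, spearman, write_gmt)
from metscreen.synthetic_cohorts import read_truth

from _common import COHORT_IDS, DEFAULT_SEED, outdirs


def main(seed: int) -> None:
    scratch, results = outdirs()
    truth = read_truth(scratch / "data" / "truth.tsv")
    target = truth.index[truth["ar_anticorr"]][0]
    ar_members = list(truth.index[truth["ar_signature"]])

    # largest follow-up cohort, primary tumors only
    best, best_surv = None, None
    for cid in COHORT_IDS:
        cohort, survival = read_cohort(scratch / "harmonized", cid)
        if survival is not None and (best is None or len(survival.sample_ids) > len(best_surv.sample_ids)):
            best, best_surv = cohort, survival
    pt = best.samples_in("PT")
    matrix = best.matrix[pt]

    rng = np.random.default_rng(seed + 500)
    pool = truth.index[(truth["class"] == "null") & ~truth["ar_signature"]].to_numpy()
    sets = [GeneSet("AR_SIGNATURE", "planted androgen-receptor program", ar_members)]
    sets += [GeneSet(f"CONTROL_{i+1}", "random null genes",
                     list(rng.choice(pool, 25, replace=False))) for i in range(3)]
    write_gmt(sets, results / "gene_sets.gmt")

    labels = mean_split(matrix.loc[target])
    enr = gsea_permutation(matrix, labels, sets, n_perm=500, seed=seed)
    table = pd.DataFrame([{"set": r.set_name, "es": r.es, "nes": r.nes,
                           "p_perm": r.p_perm, "fdr_q": r.fdr_q,
                           "leading_edge_size": len(r.leading_edge)} for r in enr]
                         ).set_index("set")
    table.to_csv(results / "enrichment.tsv", sep="\t", float_format="%.4g")

    score = signature_score(matrix, ar_members)
    rho, p = spearman(matrix.loc[target].to_numpy(), score.to_numpy())
    corr = {"cohort": best.cohort_id, "target_gene": str(target),
            "n_primary_tumors": len(pt), "spearman_rho": rho, "spearman_p": p}
    (results / "ar_correlation.json").write_text(json.dumps(corr, indent=1) + "\n")

    print(f"target gene {target} ({best.cohort_id}, {len(pt)} primary tumors, "
          f"{int((labels == 'high').sum())} high / {int((labels == 'low').sum())} low)")
    print(table.to_string())
    print(f"\nSpearman vs AR signature score: rho={rho:.3f}, p={p:.2g}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    main(parser.parse_args().seed)
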