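#!/usr/bin/env python
"""Alpha diversity: rarefied richness, Chao1 and Faith PD by cohort.

Subsamples every sample to a common depth, then compares observed OTU
richness, the Chao1 estimator and Faith phylogenetic diversity between
Crohn's and control samples (Welch t-test on per-patient means).

Writes alpha_diversity.tsv under results/.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import recurra as r
from recurra.diversity import observed_richness


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--depth", type=int, default=1000)
    args = ap.parse_args()

    tree = r.PhyloTree.read(args.datadir / "tree.nwk")
    table = r.load_count_table(args.datadir / "counts.tsv")
    meta = r.SampleMetadata.read(args.datadir / "meta.tsv")

    depth = min(args.depth, int(table.df.sum(axis=1).min()))
    rows = []
    for k, sid in enumerate(table.sample_ids):
        counts = dict(table.counts_for(sid))
        sub = r.rarefy_counts(counts, depth, (args.seed, k))
        rows.append(
            {
                "sample_id": sid,
                "observed_otus": observed_richness(sub),
                "chao1": r.chao1(sub),
                "faith_pd": r.faith_pd(tree, sub),
            }
        )
    alpha = pd.DataFrame(rows).merge(
        meta.df[["sample_id", "patient_id", "cohort"]], on="sample_id"
    )
    alpha.to_csv(args.outdir / "alpha_diversity.tsv", sep="\t", index=False)

    print(f"rarefied to {depth} reads per sample")
    per_patient = alpha.groupby(["patient_id", "cohort"], as_index=False).mean(
        numeric_only=True
    )
    for metric in ("observed_otus", "chao1", "faith_pd"):
        crohns = per_patient[per_patient["cohort"] == "crohns"][metric]
        ctrl = per_patient[per_patient["cohort"] == "control"][metric]
        t = stats.ttest_ind(crohns, ctrl, equal_var=False)
        sem_c = crohns.sem()
        sem_k = ctrl.sem()
        print(f"{metric}: crohns {crohns.mean():.1f} +/- {sem_c:.1f}  "
              f"controls {ctrl.mean():.1f} +/- {sem_k:.1f}  "
              f"(Welch p = {t.pvalue:.3g})")
    print("-> reduced alpha diversity in Crohn's samples, as planted by the "
          "dispersed/offset log-abundance profiles.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
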