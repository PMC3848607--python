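#!/usr/bin/env python
"""Sequencing-error OTU inflation at desk scale.

Simulates deep 16S sequencing of a known reference community, injecting
per-base substitution errors at several rates, dereplicating and
clustering at 97% identity.  Demonstrates that OTU counts inflate far
beyond the reference richness as error rate and depth grow — the reason
deep-coverage surveys report implausibly many OTUs.

Writes otu_inflation.tsv under results/.
"""

import argparse
import sys
from pathlib import Path

import recurra as r
from recurra.seqsim import cluster_otus


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--n-refs", type=int, default=20)
    ap.add_argument("--read-length", type=int, default=100)
    ap.add_argument("--depths", type=int, nargs="+",
                    default=[1000, 10000, 100000])
    ap.add_argument("--error-rates", type=float, nargs="+",
                    default=[0.0, 0.0001, 0.001, 0.005])
    args = ap.parse_args()

    refs = r.simulate_reference_sequences(
        [f"ref{i:03d}" for i in range(args.n_refs)], args.read_length,
        (args.seed, 0),
    )
    ref_otus = cluster_otus(
        r.SequenceSet(refs.ids, [s[: args.read_length] for s in refs.sequences])
    ).n_otus
    print(f"reference community: {len(refs)} sequences -> {ref_otus} OTUs at 97%")

    table = r.inflation_experiment(
        refs, args.read_length, depths=args.depths,
        error_rates=args.error_rates, threshold=0.97, seed=args.seed,
    )
    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "otu_inflation.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    top = table[table["depth"] == max(args.depths)]
    worst = top[top["error_rate"] == max(args.error_rates)]["n_otus"].iloc[0]
    print(f"-> at depth {max(args.depths)} and error rate "
          f"{max(args.error_rates):g}, {worst} OTUs from only {ref_otus} real "
          "taxa: per-base sequencing error inflates OTU counts at deep coverage.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
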