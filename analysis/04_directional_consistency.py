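"""Directional-consistency of the known index SNPs, per scope.

Counts how many catalog index SNPs show risk-allele-oriented effects in
the same direction as reported, and tests the count against chance with
an exact one-sided Binomial(n, 1/2) tail, in each population and in the
cross-ethnic meta-analysis.
"""

import argparse
from pathlib import Path

import pandas as pd

from transrep.consistency import consistency_table, summarize_consistency
from transrep.io import read_catalog

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    args = ap.parse_args()

    catalog = read_catalog(args.cohort / "catalog.tsv")
    pop_meta = pd.read_csv(args.results / "meta_population.tsv", sep="\t")
    cross = pd.read_csv(args.results / "meta_cross_ethnic.tsv", sep="\t")

    summaries = [
        summarize_consistency(pop_meta[pop_meta["scope"] == pop], catalog, pop)
        for pop in pop_meta["scope"].unique()
    ]
    summaries.append(summarize_consistency(cross, catalog, "cross_ethnic"))
    table = consistency_table(summaries)
    table.to_csv(args.results / "consistency.tsv", sep="\t", index=False)

    print(table[["scope", "n", "k", "fraction", "binomial_p", "n_nominal"]]
          .to_string(index=False))
    for s in summaries:
        if s.nominal:
            print(f"{s.scope}: nominally significant & consistent: {', '.join(s.nominal)}")


if __name__ == "__main__":
    main()
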