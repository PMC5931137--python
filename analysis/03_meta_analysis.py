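"""Fixed-effects meta-analysis within and across populations.

Pools the 18 stratum-level results per variant with inverse-variance
weights: first to one estimate per population, then across populations
for variants observed in at least two of them.
"""

import argparse
from pathlib import Path

import pandas as pd

from transrep.meta import cross_ethnic_meta

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    assoc = pd.read_csv(args.results / "assoc.tsv", sep="\t")
    pop_meta, cross = cross_ethnic_meta(assoc)
    pop_meta.to_csv(args.results / "meta_population.tsv", sep="\t", index=False)
    cross.to_csv(args.results / "meta_cross_ethnic.tsv", sep="\t", index=False)

    print(f"population-level estimates: {len(pop_meta)}")
    print(f"cross-ethnic estimates: {len(cross)} "
          f"({len(cross.attrs.get('excluded', []))} variants in <2 populations)")
    top = cross.nsmallest(3, "p")[["variant", "or", "p", "populations_present"]]
    print("strongest cross-ethnic signals:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
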