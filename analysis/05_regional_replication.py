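"""Regional replication through LD proxies and tag-count thresholds.

For each known region: proxies are variants at r2 >= 0.4 with the index
in the reference panel (the first population's genotypes); the effective
number of tests is the count of greedy pairwise tag bins at r2 >= 0.8
among MAF > 1% variants; a region replicates in a scope when any proxy
beats 0.05 / n_tags there.  Also writes a p-vs-position scatter for the
most significant region.
"""

import argparse
from pathlib import Path

import pandas as pd

from transrep.io import read_cohort_dir
from transrep.ld import (
    greedy_tag_bins,
    proxy_set,
    region_call_table,
    regional_replication,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--r2-proxy", type=float, default=0.4)
    ap.add_argument("--r2-tag", type=float, default=0.8)
    args = ap.parse_args()

    data = read_cohort_dir(args.cohort)
    pop_meta = pd.read_csv(args.results / "meta_population.tsv", sep="\t")
    cross = pd.read_csv(args.results / "meta_cross_ethnic.tsv", sep="\t")
    pops = list(data["samples"]["population"].unique())
    panel_ids = data["samples"].loc[
        data["samples"]["population"] == pops[0], "sample"
    ].tolist()
    panel = data["dosages"].subset_samples(panel_ids)

    scopes = {pop: pop_meta[pop_meta["scope"] == pop] for pop in pops}
    scopes["cross_ethnic"] = cross
    tables, bin_rows = [], []
    for entry in data["catalog"]:
        rvars = data["region_variants"][entry.region_id]
        proxies = proxy_set(rvars, entry.index_variant, panel, args.r2_proxy)
        n_tags, bins = greedy_tag_bins(rvars, panel, args.r2_tag)
        for tag, members in bins.items():
            bin_rows.append(
                {"region_id": entry.region_id, "tag": tag, "members": ",".join(members)}
            )
        for scope, meta_df in scopes.items():
            pvals = dict(zip(meta_df["variant"], meta_df["p"]))
            call = regional_replication(entry.region_id, pvals, proxies, n_tags)
            t = region_call_table([call])
            t.insert(0, "scope", scope)
            tables.append(t)
    calls = pd.concat(tables, ignore_index=True)
    calls.to_csv(args.results / "region_calls.tsv", sep="\t", index=False)
    pd.DataFrame(bin_rows).to_csv(args.results / "tag_bins.tsv", sep="\t", index=False)

    for scope in scopes:
        sub = calls[calls["scope"] == scope]
        hits = sub[sub["replicated"]]
        print(f"{scope}: {len(hits)}/{len(sub)} regions replicated "
              f"({', '.join(hits['region_id'])})" if len(hits) else
              f"{scope}: 0/{len(sub)} regions replicated")

    best = calls.loc[calls["best_p"].idxmin()]
    _plot_region(data, cross, pop_meta, best["region_id"],
                 args.results / f"region_{best['region_id']}_scatter.png")
    print(f"scatter written for top region {best['region_id']} (p={best['best_p']:.2g})")


def _plot_region(data, cross, pop_meta, region_id, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    pos = {v.id: v.pos for v in data["variants"]}
    rvars = set(data["region_variants"][region_id])
    fig, ax = plt.subplots(figsize=(6, 3))
    for scope, g in pd.concat([pop_meta, cross]).groupby("scope"):
        g = g[g["variant"].isin(rvars)]
        ax.scatter([pos[v] for v in g["variant"]], -np.log10(g["p"]), s=12, label=scope)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("-log10 p")
    ax.set_title(region_id)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
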