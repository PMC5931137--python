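"""Allele-count genetic risk scores and their association with disease.

Builds the base score over the catalog index SNPs, the modified score I
(per-population region-wide-significant lead substitutions) and the
modified score II (cross-ethnic lead substitutions); compares score
distributions between cases and controls and across populations; and
fits the continuous and quartile logistic models per population.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from transrep.assoc import compute_pcs
from transrep.grs import (
    base_definition,
    build_score,
    compare_distributions,
    grs_association,
    substitute_leads,
)
from transrep.io import read_cohort_dir
from transrep.ld import RegionCall

ROOT = Path(__file__).resolve().parents[1]


def _calls_for_scope(calls_df, scope):
    out = {}
    for _, r in calls_df[calls_df["scope"] == scope].iterrows():
        out[r["region_id"]] = RegionCall(
            region_id=r["region_id"],
            n_tags=int(r["n_tags"]),
            alpha_region=float(r["alpha_region"]),
            proxies=[],
            best_proxy=r["best_proxy"] if isinstance(r["best_proxy"], str) else None,
            best_p=float(r["best_p"]),
            replicated=bool(r["replicated"]),
            status=r["status"],
        )
    return out


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--seed", type=int, default=2024)
    args = ap.parse_args()

    data = read_cohort_dir(args.cohort)
    samples = data["samples"]
    dosages = data["dosages"]
    vmap = {v.id: v for v in data["variants"]}
    catalog = data["catalog"]
    calls_df = pd.read_csv(args.results / "region_calls.tsv", sep="\t")
    pop_meta = pd.read_csv(args.results / "meta_population.tsv", sep="\t")
    cross = pd.read_csv(args.results / "meta_cross_ethnic.tsv", sep="\t")
    pops = list(samples["population"].unique())

    # chip-level block size: smallest positive count of missing score SNPs
    # among samples genotyped on a reduced chip -> those samples are excluded
    score_idx = [dosages.variant_index(e.index_variant) for e in catalog]
    miss = np.isnan(dosages.data[:, score_idx]).sum(axis=1)
    chip_mask = (samples.set_index("sample")["chip"] != "gwas").loc[dosages.samples]
    blocked = miss[chip_mask.to_numpy() & (miss > 0)]
    threshold = int(blocked.min()) if blocked.size else 20

    defs = {"base": base_definition(catalog)}
    profiles = {"base": build_score(dosages, vmap, defs["base"], samples, threshold)}
    mode1 = []
    for pop in pops:
        betas = dict(zip(pop_meta[pop_meta["scope"] == pop]["variant"],
                         pop_meta[pop_meta["scope"] == pop]["beta"]))
        d = substitute_leads(catalog, _calls_for_scope(calls_df, pop), betas, vmap,
                             "modified_I")
        defs[f"modified_I_{pop}"] = d
        prof = build_score(dosages, vmap, d, samples, threshold)
        keep = set(samples.loc[samples["population"] == pop, "sample"])
        mode1.append(prof[prof["sample"].isin(keep)])
    profiles["modified_I"] = pd.concat(mode1, ignore_index=True)
    d2 = substitute_leads(
        catalog, _calls_for_scope(calls_df, "cross_ethnic"),
        dict(zip(cross["variant"], cross["beta"])), vmap, "modified_II",
    )
    defs["modified_II"] = d2
    profiles["modified_II"] = build_score(dosages, vmap, d2, samples, threshold)

    pcs = {}
    for pop in pops:
        sub = dosages.subset_samples(
            samples.loc[samples["population"] == pop, "sample"].tolist()
        )
        pcs[pop] = compute_pcs(
            sub, subset_size=min(10_000, sub.n_variants),
            k=min(10, sub.n_variants - 1), rng=np.random.default_rng(args.seed),
        )

    summaries, hists, assocs, def_rows = [], [], [], []
    for mode, prof in profiles.items():
        s, h = compare_distributions(prof, samples)
        s.insert(0, "mode", mode)
        h.insert(0, "mode", mode)
        summaries.append(s)
        hists.append(h)
        a = grs_association(prof, samples, pcs)
        a.insert(0, "mode", mode)
        assocs.append(a)
    for name, d in defs.items():
        for region, vid, risk in d.entries:
            def_rows.append({"definition": name, "mode": d.mode, "region_id": region,
                             "variant": vid, "risk_allele": risk,
                             "provenance": d.provenance.get(region, "")})
    pd.concat(summaries).to_csv(args.results / "grs_distributions.tsv", sep="\t", index=False)
    pd.concat(hists).to_csv(args.results / "grs_histograms.tsv", sep="\t", index=False)
    grs_assoc = pd.concat(assocs)
    grs_assoc.to_csv(args.results / "grs_association.tsv", sep="\t", index=False)
    pd.DataFrame(def_rows).to_csv(args.results / "score_definitions.tsv", sep="\t", index=False)

    n_excluded = int((~profiles["base"]["included"]).sum())
    print(f"samples excluded from scoring for block missingness: {n_excluded}")
    print("case/control score distributions (base score):")
    s0 = summaries[0]
    print(s0[s0["comparison"].str.contains("case_vs_control")].to_string(index=False))
    print("continuous per-allele ORs:")
    cont = grs_assoc[grs_assoc["term"] == "continuous"]
    print(cont[["mode", "population", "or", "p", "n"]].to_string(index=False))
    _plot_hist(pd.concat(hists), args.results / "grs_histograms.png")


def _plot_hist(hist, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base = hist[hist["mode"] == "base"]
    fig, ax = plt.subplots(figsize=(6, 3.2))
    for (pop, case), g in base.groupby(["population", "case"]):
        style = "-" if case else "--"
        ax.plot(g["bin_left"], g["count"], style, lw=1,
                label=f"{pop} {'case' if case else 'control'}")
    ax.set_xlabel("risk-allele count")
    ax.set_ylabel("samples")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


if __name__ == "__main__":
    main()
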