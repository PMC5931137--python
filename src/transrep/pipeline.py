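"""End-to-end orchestration: simulate -> scan -> meta -> consistency ->
regions -> GRS -> power, with every stage result written to TSV.

Stages communicate only through in-memory frames here and on-disk
TSV/VCF artifacts when run through the CLI, so any stage can be re-run
from the previous stage's files.  A run log records every exclusion.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from transrep import assoc as assoc_mod
from transrep import grs as grs_mod
from transrep.config import SimConfig
from transrep.consistency import consistency_table, summarize_consistency
from transrep.ld import (
    RegionCall,
    greedy_tag_bins,
    proxy_set,
    region_call_table,
    regional_replication,
)
from transrep.meta import cross_ethnic_meta
from transrep.power import powered_fraction
from transrep.simulate import Cohort, simulate_cohort


@dataclass
class RunOptions:
    """Pipeline thresholds and sensitivity-analysis filters."""

    maf_min: float = 0.01
    info_min: float = 0.8
    r2_proxy: float = 0.4
    r2_tag: float = 0.8
    alpha: float = 0.05
    claims_controls_only: bool = False
    exclude_prior_condition_cases: bool = False
    proxy_panel_population: str | None = None  # default: first population
    tag_panel_population: str | None = None
    missing_exclude_threshold: int | None = None  # None: derive from chip plan
    quartiles_from: str = "all"
    seed: int = 0


class RunLog:
    def __init__(self, outdir: Path | None):
        self.outdir = outdir
        self.lines: list[str] = []
        self.exclusions: list[dict] = []

    def info(self, msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        self.lines.append(f"{stamp}\tINFO\t{msg}")

    def exclude(self, records: list[dict]) -> None:
        self.exclusions.extend(records)

    def flush(self) -> None:
        if self.outdir is None:
            return
        (self.outdir / "run.log").write_text("\n".join(self.lines) + "\n")
        pd.DataFrame(self.exclusions).to_csv(
            self.outdir / "exclusions.tsv", sep="\t", index=False
        )


def apply_sample_filters(samples: pd.DataFrame, opts: RunOptions, log: RunLog) -> pd.DataFrame:
    out = samples
    if opts.claims_controls_only:
        before = len(out)
        out = out[(out["case"] == 1) | out["has_claims"]]
        log.info(f"claims filter: dropped {before - len(out)} controls without claims")
    if opts.exclude_prior_condition_cases:
        before = len(out)
        out = out[(out["case"] == 0) | ~out["prior_condition"]]
        log.info(f"prior-condition filter: dropped {before - len(out)} cases")
    return out.reset_index(drop=True)


@dataclass
class PipelineResult:
    cohort: Cohort
    samples: pd.DataFrame
    assoc: pd.DataFrame
    pop_meta: pd.DataFrame
    cross_meta: pd.DataFrame
    consistency: pd.DataFrame
    region_calls: dict[str, list[RegionCall]]
    region_table: pd.DataFrame
    score_definitions: dict[str, object]
    score_summary: pd.DataFrame
    score_hist: pd.DataFrame
    grs_assoc: pd.DataFrame
    power_table: pd.DataFrame
    power_counts: pd.DataFrame
    outdir: Path | None = None


def _region_variant_map(cohort: Cohort) -> dict[str, list[str]]:
    return {
        r.region_id: r.variant_ids() for r in cohort.config.regions
    }


def _panel(cohort: Cohort, pop: str):
    ids = cohort.samples.loc[cohort.samples["population"] == pop, "sample"].tolist()
    return cohort.dosages.subset_samples(ids)


def run_pipeline(
    sim_config: SimConfig | None = None,
    cohort: Cohort | None = None,
    opts: RunOptions | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage on a simulated (or supplied) cohort.

    Either a :class:`SimConfig` to simulate from or a ready
    :class:`Cohort` must be given.  When ``outdir`` is set, every stage
    table, the run log and a JSON summary report are written there.
    """
    if (sim_config is None) == (cohort is None):
        raise ValueError("provide exactly one of sim_config or cohort")
    opts = opts or RunOptions()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log = RunLog(out)

    if cohort is None:
        log.info(f"simulating cohort (seed={sim_config.seed})")
        cohort = simulate_cohort(sim_config)
    samples = apply_sample_filters(cohort.samples, opts, log)
    catalog = cohort.catalog
    vmap = {v.id: v for v in cohort.variants}

    # ---- association scan -------------------------------------------------
    log.info("stage scan: stratified per-SNP logistic regression")
    assoc_df, excl = assoc_mod.scan(
        cohort.dosages,
        samples,
        cohort.variants,
        catalog,
        maf_min=opts.maf_min,
        info_min=opts.info_min,
        pc_subset_size=min(10_000, cohort.dosages.n_variants),
        seed=opts.seed,
    )
    log.exclude(excl)
    if assoc_df.empty:
        raise RuntimeError("association scan produced no usable results")

    # ---- meta-analysis ----------------------------------------------------
    log.info("stage meta: fixed-effects pooling within and across populations")
    pop_meta, cross_meta = cross_ethnic_meta(assoc_df)
    log.exclude(
        [
            {**e, "scope": "cross_ethnic"}
            for e in cross_meta.attrs.get("excluded", [])
        ]
    )

    # ---- directional consistency -----------------------------------------
    log.info("stage consistency: exact binomial direction tests")
    summaries = []
    for pop in samples["population"].unique():
        sub = pop_meta[pop_meta["scope"] == pop]
        summaries.append(summarize_consistency(sub, catalog, pop, opts.alpha))
    summaries.append(
        summarize_consistency(cross_meta, catalog, "cross_ethnic", opts.alpha)
    )
    cons_table = consistency_table(summaries)
    for s in summaries:
        log.exclude([{**e, "scope": s.scope} for e in s.excluded])

    # ---- regional replication --------------------------------------------
    log.info("stage regions: LD proxies, tag bins, region calls")
    pops = list(samples["population"].unique())
    proxy_pop = opts.proxy_panel_population or pops[0]
    tag_pop = opts.tag_panel_population or pops[0]
    proxy_panel = _panel(cohort, proxy_pop)
    tag_panel = _panel(cohort, tag_pop)
    region_vars = _region_variant_map(cohort)
    scopes = {pop: pop_meta[pop_meta["scope"] == pop] for pop in pops}
    scopes["cross_ethnic"] = cross_meta
    region_calls: dict[str, list[RegionCall]] = {s: [] for s in scopes}
    bins_rows = []
    for entry in catalog:
        rvars = region_vars[entry.region_id]
        try:
            proxies = proxy_set(rvars, entry.index_variant, proxy_panel, opts.r2_proxy)
        except ValueError as exc:
            log.info(f"region {entry.region_id}: {exc}")
            continue
        n_tags, bins = greedy_tag_bins(rvars, tag_panel, opts.r2_tag, opts.maf_min)
        if n_tags == 0:
            log.info(f"region {entry.region_id}: no taggable variants")
            continue
        for tag, members in bins.items():
            bins_rows.append(
                {"region_id": entry.region_id, "tag": tag, "members": ",".join(members)}
            )
        for scope, meta_df in scopes.items():
            pvals = dict(zip(meta_df["variant"], meta_df["p"]))
            call = regional_replication(
                entry.region_id, pvals, proxies, n_tags, opts.alpha
            )
            region_calls[scope].append(call)
    region_tables = []
    for scope, calls in region_calls.items():
        t = region_call_table(calls)
        t.insert(0, "scope", scope)
        region_tables.append(t)
    region_table = pd.concat(region_tables, ignore_index=True)

    # ---- genetic risk scores ----------------------------------------------
    log.info("stage grs: three allele-count scores")
    dosages_f = cohort.dosages.subset_samples(samples["sample"].tolist())
    score_vars = {e.index_variant for e in catalog}
    if opts.missing_exclude_threshold is not None:
        miss_threshold = opts.missing_exclude_threshold
    else:
        # exclude any sample missing a whole chip-level block of score SNPs
        block_sizes = [
            len(score_vars.intersection(b.missing_variants))
            for b in cohort.config.chip_plan
        ]
        block_sizes = [b for b in block_sizes if b > 0]
        miss_threshold = min(block_sizes) if block_sizes else 20
        log.info(f"grs: block-missingness exclusion threshold = {miss_threshold}")
    base_def = grs_mod.base_definition(catalog)
    defs: dict[str, object] = {"base": base_def}
    profiles = {
        "base": grs_mod.build_score(
            dosages_f, vmap, base_def, samples, miss_threshold
        )
    }
    # mode I: per-population substitution; mode II: cross-ethnic
    oriented = {}
    for scope, meta_df in scopes.items():
        oriented[scope] = dict(zip(meta_df["variant"], meta_df["beta"]))
    mode1_profiles = []
    for pop in pops:
        calls = {c.region_id: c for c in region_calls[pop]}
        d = grs_mod.substitute_leads(catalog, calls, oriented[pop], vmap, "modified_I")
        defs[f"modified_I_{pop}"] = d
        prof = grs_mod.build_score(
            dosages_f, vmap, d, samples, miss_threshold
        )
        keep = samples.loc[samples["population"] == pop, "sample"]
        mode1_profiles.append(prof[prof["sample"].isin(set(keep))])
    profiles["modified_I"] = pd.concat(mode1_profiles, ignore_index=True)
    calls2 = {c.region_id: c for c in region_calls["cross_ethnic"]}
    d2 = grs_mod.substitute_leads(
        catalog, calls2, oriented["cross_ethnic"], vmap, "modified_II"
    )
    defs["modified_II"] = d2
    profiles["modified_II"] = grs_mod.build_score(
        dosages_f, vmap, d2, samples, miss_threshold
    )

    analyzed = samples[samples["sample"].isin(set(profiles["base"]["sample"]))]
    pcs = {}
    for pop in pops:
        sub_ids = samples.loc[samples["population"] == pop, "sample"].tolist()
        sub = cohort.dosages.subset_samples(sub_ids)
        pcs[pop] = assoc_mod.compute_pcs(
            sub,
            subset_size=min(10_000, sub.n_variants),
            k=min(10, sub.n_variants - 1),
            rng=np.random.default_rng(opts.seed + 1),
        )
    score_rows = []
    hist_frames = []
    assoc_frames = []
    for mode, prof in profiles.items():
        summary, hist = grs_mod.compare_distributions(prof, samples)
        summary.insert(0, "mode", mode)
        hist.insert(0, "mode", mode)
        score_rows.append(summary)
        hist_frames.append(hist)
        ga = grs_mod.grs_association(prof, samples, pcs, opts.quartiles_from)
        ga.insert(0, "mode", mode)
        assoc_frames.append(ga)
    score_summary = pd.concat(score_rows, ignore_index=True)
    score_hist = pd.concat(hist_frames, ignore_index=True)
    grs_assoc = pd.concat(assoc_frames, ignore_index=True)

    # ---- power -------------------------------------------------------------
    log.info("stage power: analytic per-allele power over the catalog")
    cat_rows = []
    truth_idx = cohort.truth.set_index("variant")
    for entry in catalog:
        row = {"index_variant": entry.index_variant, "reported_or": entry.reported_or}
        for pop in pops:
            row[f"freq_{pop}"] = truth_idx.loc[entry.index_variant, f"freq_{pop}"]
        cat_rows.append(row)
    pop_counts = {}
    for pop in pops:
        g = samples[samples["population"] == pop]
        pop_counts[pop] = (int((g["case"] == 1).sum()), int((g["case"] == 0).sum()))
    power_table, power_counts = powered_fraction(
        pd.DataFrame(cat_rows), pop_counts, threshold=0.80, alpha=opts.alpha
    )

    result = PipelineResult(
        cohort=cohort,
        samples=samples,
        assoc=assoc_df,
        pop_meta=pop_meta,
        cross_meta=cross_meta,
        consistency=cons_table,
        region_calls=region_calls,
        region_table=region_table,
        score_definitions=defs,
        score_summary=score_summary,
        score_hist=score_hist,
        grs_assoc=grs_assoc,
        power_table=power_table,
        power_counts=power_counts,
        outdir=out,
    )
    if out is not None:
        _write_outputs(result, pd.DataFrame(bins_rows), log)
    log.flush()
    return result


def _write_outputs(res: PipelineResult, bins: pd.DataFrame, log: RunLog) -> None:
    out = res.outdir
    res.assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
    res.pop_meta.to_csv(out / "meta_population.tsv", sep="\t", index=False)
    res.cross_meta.to_csv(out / "meta_cross_ethnic.tsv", sep="\t", index=False)
    res.consistency.to_csv(out / "consistency.tsv", sep="\t", index=False)
    res.region_table.to_csv(out / "region_calls.tsv", sep="\t", index=False)
    bins.to_csv(out / "tag_bins.tsv", sep="\t", index=False)
    res.score_summary.to_csv(out / "grs_distributions.tsv", sep="\t", index=False)
    res.score_hist.to_csv(out / "grs_histograms.tsv", sep="\t", index=False)
    res.grs_assoc.to_csv(out / "grs_association.tsv", sep="\t", index=False)
    res.power_table.to_csv(out / "power_per_snp.tsv", sep="\t", index=False)
    res.power_counts.to_csv(out / "power_counts.tsv", sep="\t", index=False)
    def_rows = []
    for name, d in res.score_definitions.items():
        for region, vid, risk in d.entries:
            def_rows.append(
                {
                    "definition": name,
                    "mode": d.mode,
                    "region_id": region,
                    "variant": vid,
                    "risk_allele": risk,
                    "provenance": d.provenance.get(region, ""),
                }
            )
    pd.DataFrame(def_rows).to_csv(out / "score_definitions.tsv", sep="\t", index=False)
    report = {
        "consistency": res.consistency.to_dict(orient="records"),
        "regions_replicated": {
            scope: int(sum(c.replicated for c in calls))
            for scope, calls in res.region_calls.items()
        },
        "grs_continuous": res.grs_assoc[
            (res.grs_assoc["term"] == "continuous")
        ][["mode", "population", "or", "p"]].to_dict(orient="records"),
        "power_counts": res.power_counts.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("report written")


def region_scatter_plot(pop_meta: pd.DataFrame, cohort: Cohort, region_id: str, path) -> None:
    """Plain p-value vs position scatter for one region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    region = next(r for r in cohort.config.regions if r.region_id == region_id)
    pos = dict(zip(region.variant_ids(), region.positions()))
    sub = pop_meta[pop_meta["variant"].isin(pos)]
    fig, ax = plt.subplots(figsize=(6, 3))
    for scope, g in sub.groupby("scope"):
        ax.scatter(
            [pos[v] for v in g["variant"]], -np.log10(g["p"]), s=12, label=scope
        )
    ax.axvline(pos[region.index_variant], color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"position (chr{region.chrom})")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
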