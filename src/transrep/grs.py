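"""Allele-count genetic risk scores and their association with disease.

Three unweighted scores are supported: the base score summing risk-allele
dosages over the catalog SNPs; modified score I, which substitutes each
index SNP with the population's region-wide-significant lead proxy when
the region replicated in that population; and modified score II, which
substitutes with the cross-ethnic lead proxy under the same rule.  The
risk allele of a substituted SNP is the allele with positive observed
oriented effect.  Samples missing a chip-level block of score SNPs are
excluded (mirroring array-specific missingness); residual sporadic
missingness is imputed at twice the population risk-allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from transrep.assoc import COVARIATE_COLUMNS, FitError, logistic_irls
from transrep.io import DosageMatrix, LocusCatalogEntry, VariantRecord
from transrep.ld import RegionCall


@dataclass
class ScoreDefinition:
    """Ordered (region, variant, risk allele) triples defining one GRS."""

    entries: list[tuple[str, str, str]]
    mode: str = "base"  # base | modified_I | modified_II
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    def variant_ids(self) -> list[str]:
        return [v for _, v, _ in self.entries]


def base_definition(catalog: list[LocusCatalogEntry]) -> ScoreDefinition:
    return ScoreDefinition(
        entries=[(e.region_id, e.index_variant, e.risk_allele) for e in catalog],
        mode="base",
    )


def substitute_leads(
    catalog: list[LocusCatalogEntry],
    region_calls: dict[str, RegionCall],
    lead_oriented_beta: dict[str, float],
    variants: dict[str, VariantRecord],
    mode: str,
) -> ScoreDefinition:
    """Swap index SNPs for region-wide-significant lead proxies.

    ``region_calls`` maps region id to the :class:`RegionCall` of the
    requested scope (one population for mode I, the cross-ethnic
    meta-analysis for mode II).  For regions whose call replicated, the
    index is replaced by the best proxy and the substituted risk allele
    is the allele with positive observed effect (``lead_oriented_beta``
    holds the lead's beta on the effect-allele scale).  Other regions
    keep the catalog row.
    """
    if mode not in ("modified_I", "modified_II"):
        raise ValueError(f"substitution mode must be modified_I/II, got {mode!r}")
    entries = []
    provenance = {}
    for e in catalog:
        call = region_calls.get(e.region_id)
        if call is not None and call.replicated and call.best_proxy is not None:
            lead = call.best_proxy
            v = variants[lead]
            beta = lead_oriented_beta.get(lead, 0.0)
            risk = v.effect_allele if beta > 0 else v.other_allele
            entries.append((e.region_id, lead, risk))
            provenance[e.region_id] = (
                f"substituted {e.index_variant} -> {lead} (p={call.best_p:.3g})"
            )
        else:
            entries.append((e.region_id, e.index_variant, e.risk_allele))
    return ScoreDefinition(entries=entries, mode=mode, provenance=provenance)


def build_score(
    dosages: DosageMatrix,
    variants: dict[str, VariantRecord],
    definition: ScoreDefinition,
    samples: pd.DataFrame,
    missing_exclude_threshold: int = 20,
) -> pd.DataFrame:
    """Per-sample risk-allele count over the score SNPs.

    Returns columns ``sample``, ``score``, ``n_missing``, ``included``,
    ``reason``.  Samples missing at least ``missing_exclude_threshold``
    score SNPs (chip-level block missingness) are excluded; remaining
    sporadic missing dosages are imputed as 2x the sample's population
    risk-allele frequency.  Scores lie in [0, 2m] for m score SNPs.
    """
    missing_vars = [v for _, v, _ in definition.entries if v not in set(dosages.variants)]
    if missing_vars:
        raise ValueError(f"score variants absent from genotype data: {missing_vars}")
    pop_of = samples.set_index("sample")["population"]
    cols = []
    pop_freq_cols = []
    pops = sorted(samples["population"].unique())
    for _, vid, risk in definition.entries:
        v = variants[vid]
        raw = dosages.column(vid)
        if risk == v.effect_allele:
            col = raw
            freqs = {p: v.freq.get(p, np.nan) for p in pops}
        elif risk == v.other_allele:
            col = 2.0 - raw
            freqs = {p: 1.0 - v.freq.get(p, np.nan) for p in pops}
        else:
            raise ValueError(f"{vid}: risk allele {risk} is not one of its alleles")
        cols.append(col)
        pop_freq_cols.append(freqs)
    mat = np.column_stack(cols)  # samples x score SNPs, risk-allele dosage
    n_missing = np.isnan(mat).sum(axis=1)
    included = n_missing < missing_exclude_threshold

    sample_pops = pop_of.loc[dosages.samples].to_numpy()
    imputed = mat.copy()
    for j, freqs in enumerate(pop_freq_cols):
        col = imputed[:, j]
        nanmask = np.isnan(col)
        if nanmask.any():
            fill = np.array([2.0 * freqs.get(p, np.nan) for p in sample_pops])
            col[nanmask] = fill[nanmask]
    score = imputed.sum(axis=1)
    score[~included] = np.nan
    return pd.DataFrame(
        {
            "sample": dosages.samples,
            "score": score,
            "n_missing": n_missing,
            "included": included,
            "reason": np.where(included, "", "block_missingness"),
        }
    )


def compare_distributions(
    profiles: pd.DataFrame, samples: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case/control score summaries per population, Welch t-tests, histograms.

    Returns (summary, histogram) frames.  The summary holds one row per
    population (case vs control within the population) plus one row per
    population pair comparing overall score distributions.
    """
    df = profiles.merge(samples[["sample", "population", "case"]], on="sample")
    df = df[df["included"]]
    rows = []
    for pop, g in df.groupby("population", sort=True):
        ca = g.loc[g["case"] == 1, "score"]
        co = g.loc[g["case"] == 0, "score"]
        if len(ca) < 2 or len(co) < 2:
            raise ValueError(f"{pop}: need >= 2 samples per case/control cell")
        if ca.std() == 0 and co.std() == 0:
            p = float("nan")
        else:
            p = float(stats.ttest_ind(ca, co, equal_var=False).pvalue)
        rows.append(
            {
                "comparison": f"{pop}:case_vs_control",
                "mean_a": round(ca.mean(), 2),
                "sd_a": round(ca.std(), 2),
                "n_a": len(ca),
                "mean_b": round(co.mean(), 2),
                "sd_b": round(co.std(), 2),
                "n_b": len(co),
                "p": p,
            }
        )
    pops = sorted(df["population"].unique())
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a = df.loc[df["population"] == pops[i], "score"]
            b = df.loc[df["population"] == pops[j], "score"]
            rows.append(
                {
                    "comparison": f"{pops[i]}_vs_{pops[j]}",
                    "mean_a": round(a.mean(), 2),
                    "sd_a": round(a.std(), 2),
                    "n_a": len(a),
                    "mean_b": round(b.mean(), 2),
                    "sd_b": round(b.std(), 2),
                    "n_b": len(b),
                    "p": float(stats.ttest_ind(a, b, equal_var=False).pvalue),
                }
            )
    lo = np.floor(df["score"].min())
    hi = np.ceil(df["score"].max())
    edges = np.arange(lo, hi + 2)
    hist_rows = []
    for (pop, case), g in df.groupby(["population", "case"], sort=True):
        counts, _ = np.histogram(g["score"], bins=edges)
        for left, c in zip(edges[:-1], counts):
            hist_rows.append(
                {
                    "population": pop,
                    "case": case,
                    "bin_left": float(left),
                    "bin_right": float(left + 1),
                    "count": int(c),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


def grs_association(
    profiles: pd.DataFrame,
    samples: pd.DataFrame,
    covariates: dict[str, pd.DataFrame],
    quartiles_from: str = "all",
) -> pd.DataFrame:
    """Continuous and quartile GRS logistic associations per population.

    The continuous model adds the raw score as a single adjusted term
    (OR per risk allele).  Quartile cut-points come from the analyzed
    within-population sample — cases and controls combined by default,
    or controls only with ``quartiles_from="controls"``.  Quartile 1 is
    the reference (OR fixed at 1).  ``covariates`` maps population to a
    per-sample frame (age, sex, BMI, PCs) indexed like the sample table.
    """
    if quartiles_from not in ("all", "controls"):
        raise ValueError("quartiles_from must be 'all' or 'controls'")
    df = profiles.merge(
        samples[["sample", "population", "case"] + COVARIATE_COLUMNS], on="sample"
    )
    df = df[df["included"] & df["score"].notna()]
    rows = []
    for pop, g in df.groupby("population", sort=True):
        cov = covariates[pop].loc[g["sample"]]
        X_cov = np.column_stack(
            [g[COVARIATE_COLUMNS].to_numpy(dtype=float), cov.to_numpy(dtype=float)]
        )
        y = g["case"].to_numpy(dtype=float)

        Xc = np.column_stack([np.ones(len(g)), g["score"].to_numpy(float), X_cov])
        beta, se, conv = logistic_irls(Xc, y)
        z = beta[1] / se[1]
        rows.append(
            {
                "population": pop,
                "term": "continuous",
                "or": float(np.exp(beta[1])),
                "beta": float(beta[1]),
                "se": float(se[1]),
                "p": float(2 * stats.norm.sf(abs(z))),
                "n": len(g),
                "usable": bool(conv),
            }
        )

        basis = g if quartiles_from == "all" else g[g["case"] == 0]
        cuts = np.quantile(basis["score"], [0.25, 0.5, 0.75])
        quart = np.searchsorted(cuts, g["score"].to_numpy(float), side="right")
        rows.append(
            {
                "population": pop,
                "term": "quartile_1",
                "or": 1.0,
                "beta": 0.0,
                "se": float("nan"),
                "p": float("nan"),
                "n": int((quart == 0).sum()),
                "usable": True,
            }
        )
        dummies = np.column_stack([(quart == q).astype(float) for q in (1, 2, 3)])
        Xq = np.column_stack([np.ones(len(g)), dummies, X_cov])
        try:
            qbeta, qse, qconv = logistic_irls(Xq, y)
        except FitError:
            qbeta = np.full(Xq.shape[1], np.nan)
            qse = np.full(Xq.shape[1], np.nan)
            qconv = False
        for q in (1, 2, 3):
            usable = qconv and np.isfinite(qse[q]) and qse[q] > 0
            n_cases_q = int(((quart == q) & (y == 1)).sum())
            rows.append(
                {
                    "population": pop,
                    "term": f"quartile_{q + 1}",
                    "or": float(np.exp(qbeta[q])) if usable else float("nan"),
                    "beta": float(qbeta[q]),
                    "se": float(qse[q]),
                    "p": float(2 * stats.norm.sf(abs(qbeta[q] / qse[q])))
                    if usable
                    else float("nan"),
                    "n": int((quart == q).sum()),
                    "usable": usable and n_cases_q > 0,
                }
            )
    return pd.DataFrame(rows)
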