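"""Self-calibration experiments: parameter recovery, test size, null runs.

These routines exercise the package's own machinery on data simulated at
known truth and summarize how faithfully the truth is recovered.  They
back both the test suite and the reproducibility script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from transrep.assoc import fit_snp_logistic
from transrep.config import null_config
from transrep.consistency import summarize_consistency
from transrep.grs import build_score, grs_association
from transrep.io import DosageMatrix, VariantRecord
from transrep.ld import greedy_tag_bins, proxy_set, regional_replication
from transrep.meta import cross_ethnic_meta
from transrep.simulate import assign_phenotypes, simulate_cohort


def recover_snp_log_or(
    n_reps: int = 200,
    or_true: float = 1.15,
    n_cases: int = 2000,
    n_controls: int = 4000,
    maf: float = 0.30,
    seed: int = 0,
) -> dict:
    """Bias of the per-SNP log-OR estimate under case-control subsampling.

    Each replicate simulates a source cohort under the logistic model,
    subsamples to exact case/control counts, and refits the per-allele
    effect.  Returns the mean estimated beta, its bias from log(OR), and
    the fraction of replicates whose 95% CI covers the truth.
    """
    rng = np.random.default_rng(seed)
    beta_true = np.log(or_true)
    pool = int(2.2 * (n_cases + n_controls))
    betas = np.empty(n_reps)
    covered = 0
    for r in range(n_reps):
        dos = rng.binomial(2, maf, size=(pool, 1)).astype(float)
        picks, _ = assign_phenotypes(
            dos, [beta_true], np.zeros(pool), -0.55,
            [("s", n_cases, n_controls)], rng,
        )
        idx = picks["pool_index"].to_numpy()
        res = fit_snp_logistic(dos[idx, 0], picks["case"].to_numpy(float))
        betas[r] = res.beta
        lo, hi = res.beta - 1.959964 * res.se, res.beta + 1.959964 * res.se
        covered += lo <= beta_true <= hi
    return {
        "mean_beta": float(betas.mean()),
        "bias": float(betas.mean() - beta_true),
        "ci_coverage": covered / n_reps,
        "n_reps": n_reps,
    }


def recover_grs_or(
    n_reps: int = 100,
    or_true: float = 1.03,
    n: int = 6000,
    m: int = 71,
    seed: int = 0,
) -> dict:
    """Recovery of a continuous per-allele GRS odds ratio.

    Each replicate builds an m-SNP allele-count score through the score
    module and fits the continuous covariate-adjusted logistic model;
    returns the mean estimated OR over replicates.
    """
    rng = np.random.default_rng(seed)
    beta_true = np.log(or_true)
    ors = np.empty(n_reps)
    sample_ids = [f"s{i}" for i in range(n)]
    variants = {
        f"v{j}": VariantRecord(f"v{j}", "1", 100 + j, "A", "G", freq={"P1": 0.3})
        for j in range(m)
    }
    from transrep.grs import ScoreDefinition

    definition = ScoreDefinition([(f"r{j}", f"v{j}", "A") for j in range(m)])
    pcs = {"P1": pd.DataFrame(index=pd.Index(sample_ids))}
    for r in range(n_reps):
        freqs = rng.uniform(0.1, 0.5, size=m)
        dos = rng.binomial(2, freqs, size=(n, m)).astype(float)
        dm = DosageMatrix(sample_ids, list(variants), dos)
        samples = pd.DataFrame(
            {
                "sample": sample_ids,
                "population": "P1",
                "age": rng.normal(60, 8, n).round(2),
                "sex": rng.integers(0, 2, n),
                "bmi": rng.normal(27, 4, n).round(2),
            }
        )
        score_true = dos.sum(axis=1)
        lp = beta_true * (score_true - score_true.mean())
        samples["case"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        prof = build_score(dm, variants, definition, samples)
        res = grs_association(prof, samples, pcs)
        ors[r] = res.loc[res["term"] == "continuous", "or"].iloc[0]
    return {"mean_or": float(ors.mean()), "n_reps": n_reps}


def wald_type1_error(
    n_snp_strata: int = 4000,
    n_per_stratum: int = 500,
    case_fraction: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical size of the covariate-adjusted per-SNP Wald test at null."""
    rng = np.random.default_rng(seed)
    n_cases = int(n_per_stratum * case_fraction)
    y = np.zeros(n_per_stratum)
    y[:n_cases] = 1.0
    rejections = 0
    used = 0
    for _ in range(n_snp_strata):
        maf = rng.uniform(0.05, 0.5)
        d = rng.binomial(2, maf, size=n_per_stratum).astype(float)
        cov = pd.DataFrame(
            {
                "age": rng.normal(60, 8, n_per_stratum),
                "sex": rng.integers(0, 2, n_per_stratum),
                "bmi": rng.normal(27, 4, n_per_stratum),
            }
        )
        res = fit_snp_logistic(d, y, cov)
        if res.converged and np.isfinite(res.p):
            used += 1
            rejections += res.p < alpha
    return {
        "rejection_rate": rejections / used,
        "n_tests": used,
        "alpha": alpha,
    }


def null_end_to_end(
    n_reps: int = 50,
    seed: int = 0,
    **config_kwargs,
) -> dict:
    """Full-chain null calibration on the reduced fixture.

    Runs scan -> meta -> consistency -> regional replication on cohorts
    simulated with every genetic effect at zero, and pools the
    directional-consistency fraction and the per-region false
    replication rate over replicates.
    """
    from transrep.assoc import scan

    k_total = n_total = 0
    replicated = tested = 0
    for r in range(n_reps):
        cfg = null_config(seed=seed + r, **config_kwargs)
        cohort = simulate_cohort(cfg)
        assoc, _ = scan(
            cohort.dosages, cohort.samples, cohort.variants, cohort.catalog,
            seed=seed + r,
        )
        pop_meta, cross = cross_ethnic_meta(assoc)
        for pop in cfg.population_labels:
            s = summarize_consistency(
                pop_meta[pop_meta["scope"] == pop], cohort.catalog, pop
            )
            k_total += s.k
            n_total += s.n
        # region calls per population scope, against the first population panel
        panel_ids = cohort.samples.loc[
            cohort.samples["population"] == cfg.population_labels[0], "sample"
        ].tolist()
        panel = cohort.dosages.subset_samples(panel_ids)
        region_vars = {rg.region_id: rg.variant_ids() for rg in cfg.regions}
        for entry in cohort.catalog:
            try:
                proxies = proxy_set(
                    region_vars[entry.region_id], entry.index_variant, panel
                )
            except ValueError:
                continue
            n_tags, _ = greedy_tag_bins(region_vars[entry.region_id], panel)
            if n_tags == 0:
                continue
            for pop in cfg.population_labels:
                sub = pop_meta[pop_meta["scope"] == pop]
                pvals = dict(zip(sub["variant"], sub["p"]))
                call = regional_replication(
                    entry.region_id, pvals, proxies, n_tags
                )
                if call.status == "tested":
                    tested += 1
                    replicated += call.replicated
    return {
        "consistency_fraction": k_total / n_total,
        "n_direction_calls": n_total,
        "false_replication_rate": replicated / tested,
        "n_region_calls": tested,
        "n_reps": n_reps,
    }
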