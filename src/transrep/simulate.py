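"""Multi-population case-control cohort simulator.

Allele-frequency divergence follows the Balding-Nichols model: each
population's frequency is a Beta draw with mean equal to the ancestral
frequency and variance ``Fst * p * (1-p)``.  Within a region, haplotypes
come from a latent-Gaussian threshold model: a multivariate normal with
correlation ``exp(-distance / ld_decay_length)`` is thresholded at each
variant's frequency quantile.  Thresholding attenuates correlation, so
the latent correlation of the designated index-functional pair is
calibrated by a one-dimensional root search to hit the target genotype
r².  Disease status follows a logistic model that is log-additive in the
functional-variant dosages, with age, sex and BMI effects; cases and
controls are then subsampled from the source population to exact
per-stratum counts, mimicking a cohort-nested case-control design.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from transrep.config import InfoModel, RegionSpec, SimConfig
from transrep.io import DosageMatrix, LocusCatalogEntry, VariantRecord

_MAX_FREQ_RETRIES = 100
_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


class SimulationError(RuntimeError):
    pass


def simulate_frequencies(
    ancestral_freq: float,
    fst: float,
    n_pops: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-population allele frequencies under the Balding-Nichols model.

    Draws from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and
    variance ``F p (1-p)``.  ``fst = 0`` returns the ancestral frequency
    for every population.  Degenerate draws (numerically 0 or 1) are
    rejected and redrawn a bounded number of times.
    """
    if not 0 < ancestral_freq < 1:
        raise ValueError(f"ancestral frequency {ancestral_freq} outside (0, 1)")
    if not 0 <= fst < 1:
        raise ValueError(f"Fst {fst} outside [0, 1)")
    if fst == 0:
        return np.full(n_pops, ancestral_freq)
    a = ancestral_freq * (1 - fst) / fst
    b = (1 - ancestral_freq) * (1 - fst) / fst
    out = rng.beta(a, b, size=n_pops)
    for _ in range(_MAX_FREQ_RETRIES):
        bad = (out <= 0.0) | (out >= 1.0)
        if not bad.any():
            return out
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
    raise SimulationError(
        f"could not draw non-degenerate frequencies (p={ancestral_freq}, Fst={fst})"
    )


# ---------------------------------------------------------------------------
# Latent-Gaussian LD
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(48)


def _bvn_joint_upper(t1: float, t2: float, rho: float) -> float:
    """P(X > t1, Y > t2) for standard bivariate normal with correlation rho.

    Drezner-Wesolowsky integral representation, Gauss-Legendre quadrature.
    """
    if rho >= 1.0 - 1e-12:  # identical latent variable
        return float(min(stats.norm.sf(t1), stats.norm.sf(t2)))
    h, k = -t1, -t2  # P(X > t1, Y > t2) = P(-X <= -t1, -Y <= -t2), same rho
    base = stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 0.0:
        return base
    r = 0.5 * rho * (_GL_NODES + 1.0)  # nodes mapped to [0, rho]
    w = 0.5 * rho * _GL_WEIGHTS
    integrand = np.exp(
        -(h * h - 2.0 * r * h * k + k * k) / (2.0 * (1.0 - r * r))
    ) / np.sqrt(1.0 - r * r)
    return float(base + np.sum(w * integrand) / (2.0 * math.pi))


def thresholded_r2(rho: float, p1: float, p2: float) -> float:
    """Genotype r² of two binary variables from thresholding correlated normals."""
    t1, t2 = stats.norm.isf(p1), stats.norm.isf(p2)
    p11 = _bvn_joint_upper(t1, t2, rho)
    d = p11 - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


def calibrate_latent_rho(target_r2: float, p1: float, p2: float) -> tuple[float, float]:
    """Latent correlation whose thresholded r² matches the target.

    Returns ``(rho, achieved_r2)``.  When the target is infeasible for the
    given frequency mismatch (thresholding caps attainable r²), a warning
    is issued and the maximum-correlation solution is returned.
    """
    if target_r2 <= 0:
        return 0.0, 0.0
    max_r2 = thresholded_r2(1.0, p1, p2)  # identical latents (min(p1,p2) overlap)
    if target_r2 >= max_r2 - 1e-9:
        if target_r2 > max_r2 + 0.01:
            warnings.warn(
                f"target r2={target_r2:.3f} infeasible for freqs ({p1:.3f}, {p2:.3f}); "
                f"achieved {max_r2:.3f}",
                stacklevel=2,
            )
        return 1.0, max_r2
    hi = 1.0 - 1e-7
    if thresholded_r2(hi, p1, p2) <= target_r2:
        return 1.0, max_r2
    rho = brentq(lambda r: thresholded_r2(r, p1, p2) - target_r2, 0.0, hi, xtol=1e-6)
    return float(rho), target_r2


def _region_latent_corr(region: RegionSpec, p_index: float, p_functional: float) -> np.ndarray:
    """Distance-decay latent correlation with the index-functional entry calibrated."""
    pos = region.positions().astype(float)
    ids = region.variant_ids()
    sigma = np.exp(-np.abs(pos[:, None] - pos[None, :]) / region.ld_decay_length)
    i, j = ids.index(region.index_variant), ids.index(region.functional_variant)
    if i != j:
        rho, _ = calibrate_latent_rho(region.target_r2, p_index, p_functional)
        # model the functional latent as rho * (index latent) + noise: its
        # correlation to every other variant is inherited through the index,
        # which keeps the matrix positive semi-definite by construction
        sigma[j, :] = rho * sigma[i, :]
        sigma[:, j] = sigma[j, :]
        sigma[j, j] = 1.0
        sigma[i, j] = sigma[j, i] = rho
        w, v = np.linalg.eigh(sigma)
        if w.min() < 1e-9:  # numerical safety only
            w = np.clip(w, 1e-9, None)
            sigma = (v * w) @ v.T
            d = np.sqrt(np.diag(sigma))
            sigma = sigma / np.outer(d, d)
    return sigma


def simulate_haplotypes(
    region: RegionSpec,
    pop_freqs: np.ndarray,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """0/1 haplotype matrix (n_haplotypes x n_variants) for one population.

    ``pop_freqs`` gives this population's allele-1 frequency per variant.
    Haplotypes pair consecutively into diploid individuals, so the count
    must be even.
    """
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (pairs form diploids)")
    pop_freqs = np.asarray(pop_freqs, dtype=float)
    if pop_freqs.shape != (region.n_variants,):
        raise ValueError("need one frequency per region variant")
    ids = region.variant_ids()
    i, j = ids.index(region.index_variant), ids.index(region.functional_variant)
    sigma = _region_latent_corr(region, pop_freqs[i], pop_freqs[j])
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((n_haplotypes, region.n_variants)) @ chol.T
    thresholds = stats.norm.isf(pop_freqs)
    return (z > thresholds).astype(np.int8)


def haplotypes_to_dosages(haplotypes: np.ndarray) -> np.ndarray:
    """Sum consecutive haplotype pairs into diploid dosages in {0, 1, 2}."""
    return (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def assign_phenotypes(
    dosages: np.ndarray,
    effects: np.ndarray,
    covariate_lp: np.ndarray,
    baseline_log_odds: float,
    strata_targets: list[tuple[str, int, int]],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, float]:
    """Draw case labels from the logistic model and subsample exact stratum counts.

    ``dosages`` is the source-population genotype matrix, ``effects`` the
    per-variant log-odds (aligned to columns), and ``covariate_lp`` the
    per-sample covariate contribution to the linear predictor.  Returns a
    frame with columns ``pool_index``, ``stratum``, ``case`` and the
    realized pre-subsampling prevalence.  Raises :class:`SimulationError`
    when the source population cannot supply the target counts.
    """
    effects = np.asarray(effects, dtype=float)
    lp = baseline_log_odds + covariate_lp + dosages @ effects
    prob = 1.0 / (1.0 + np.exp(-lp))
    y = rng.random(len(prob)) < prob
    prevalence = float(np.mean(y))

    case_pool = rng.permutation(np.flatnonzero(y))
    control_pool = rng.permutation(np.flatnonzero(~y))
    need_cases = sum(t[1] for t in strata_targets)
    need_controls = sum(t[2] for t in strata_targets)
    if len(case_pool) < need_cases or len(control_pool) < need_controls:
        raise SimulationError(
            f"source population supplied {len(case_pool)} cases / "
            f"{len(control_pool)} controls; targets need {need_cases} / {need_controls} "
            f"(realized prevalence {prevalence:.3f})"
        )
    rows = []
    ci = ki = 0
    for label, n_ca, n_co in strata_targets:
        for idx in case_pool[ci : ci + n_ca]:
            rows.append((int(idx), label, 1))
        ci += n_ca
        for idx in control_pool[ki : ki + n_co]:
            rows.append((int(idx), label, 0))
        ki += n_co
    return pd.DataFrame(rows, columns=["pool_index", "stratum", "case"]), prevalence


# ---------------------------------------------------------------------------
# Genotyping artifacts
# ---------------------------------------------------------------------------


def apply_genotyping_artifacts(
    dosages: DosageMatrix,
    chip_plan: list[tuple[str, list[str], list[str]]],
    info_model: InfoModel,
    strata_of_sample: pd.Series,
    rng: np.random.Generator,
) -> tuple[DosageMatrix, dict[str, dict[str, float]], pd.Series]:
    """Impose chip-style block missingness and draw imputation INFO scores.

    ``chip_plan`` holds resolved blocks ``(name, sample_ids, variant_ids)``;
    the named cells are set missing.  INFO scores are drawn per variant and
    stratum from the configured law, a fraction deliberately below 0.8 so
    downstream quality filters are exercised.  Returns the modified matrix,
    the variant -> stratum -> INFO mapping, and each sample's chip label.
    """
    known_samples = set(dosages.samples)
    known_variants = set(dosages.variants)
    data = dosages.data.copy()
    chip_label = pd.Series("gwas", index=dosages.samples, name="chip")
    for name, sample_ids, variant_ids in chip_plan:
        unknown_s = set(sample_ids) - known_samples
        unknown_v = set(variant_ids) - known_variants
        if unknown_s or unknown_v:
            raise ValueError(
                f"chip block {name!r} references unknown "
                f"samples {sorted(unknown_s)[:3]} / variants {sorted(unknown_v)[:3]}"
            )
        si = dosages.sample_index(sample_ids)
        vi = [dosages.variant_index(v) for v in variant_ids]
        data[np.ix_(si, vi)] = np.nan
        chip_label.iloc[si] = name

    strata = list(dict.fromkeys(strata_of_sample))
    info: dict[str, dict[str, float]] = {}
    lo0, lo1 = info_model.low_range
    hi0, hi1 = info_model.high_range
    for vid in dosages.variants:
        if vid in info_model.forced:
            info[vid] = {s: float(info_model.forced[vid]) for s in strata}
            continue
        low = rng.random(len(strata)) < info_model.low_fraction
        draw = np.where(
            low,
            rng.uniform(lo0, lo1, size=len(strata)),
            rng.uniform(hi0, hi1, size=len(strata)),
        )
        info[vid] = dict(zip(strata, draw.round(4)))
    out = DosageMatrix(list(dosages.samples), list(dosages.variants), data)
    return out, info, chip_label


# ---------------------------------------------------------------------------
# Whole-cohort driver
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A simulated multi-population case-control dataset plus ground truth."""

    config: SimConfig
    variants: list[VariantRecord]
    dosages: DosageMatrix
    samples: pd.DataFrame  # io.SAMPLE_COLUMNS plus "chip"
    catalog: list[LocusCatalogEntry]
    truth: pd.DataFrame  # per variant: region, true beta, per-pop freqs
    region_truth: pd.DataFrame  # per region x population: achieved index-functional r2

    def population_samples(self, label: str) -> pd.DataFrame:
        return self.samples[self.samples["population"] == label]


def _catalog_for_regions(
    regions: list[RegionSpec],
    alleles: dict[str, tuple[str, str]],
    ancestral: dict[str, float],
) -> list[LocusCatalogEntry]:
    entries = []
    for r in regions:
        eff, _ = alleles[r.index_variant]
        # discovery-study OR for the index: functional effect attenuated by LD
        reported = math.exp(abs(math.log(r.functional_or)) * math.sqrt(r.target_r2))
        entries.append(
            LocusCatalogEntry(
                region_id=r.region_id,
                index_variant=r.index_variant,
                risk_allele=eff,
                reported_or=reported if r.functional_or != 1.0 else 1.12,
                chrom=r.chrom,
                start=r.start,
                end=r.end,
                source_population="EUR",
                risk_allele_freq=ancestral[r.index_variant],
            )
        )
    return entries


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort a fixed seed reproduces exactly."""
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_hap, rng_cov, rng_phen, rng_art = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    pops = config.populations
    n_pops = len(pops)
    variant_ids = config.all_variant_ids()
    alleles = {
        vid: _ALLELE_PAIRS[k % len(_ALLELE_PAIRS)] for k, vid in enumerate(variant_ids)
    }
    ancestral = {
        vid: f
        for r in config.regions
        for vid, f in zip(r.variant_ids(), r.ancestral_freqs)
    }

    # Balding-Nichols population frequencies, per region variant
    pop_freqs: dict[str, dict[str, np.ndarray]] = {}  # region -> pop -> freqs
    for region in config.regions:
        per_pop = np.empty((n_pops, region.n_variants))
        for j, f in enumerate(region.ancestral_freqs):
            draws = np.empty(n_pops)
            for i, p in enumerate(pops):
                draws[i] = simulate_frequencies(f, p.fst, 1, rng_freq)[0]
            per_pop[:, j] = draws
        ids = region.variant_ids()
        i_idx = ids.index(region.index_variant)
        i_fun = ids.index(region.functional_variant)
        # linked index/functional alleles drift together: share the draw so
        # the target r2 stays attainable after thresholding
        per_pop[:, i_fun] = per_pop[:, i_idx]
        pop_freqs[region.region_id] = {
            p.label: per_pop[i] for i, p in enumerate(pops)
        }

    sample_frames = []
    dosage_blocks = []
    region_truth_rows = []
    for p in pops:
        pool_n = int(math.ceil(config.pool_factor * (p.n_cases + p.n_controls)))
        pool_dos = np.empty((pool_n, len(variant_ids)), dtype=np.int8)
        col = 0
        for region in config.regions:
            hap = simulate_haplotypes(
                region, pop_freqs[region.region_id][p.label], 2 * pool_n, rng_hap
            )
            block = haplotypes_to_dosages(hap)
            pool_dos[:, col : col + region.n_variants] = block
            ids = region.variant_ids()
            i, j = ids.index(region.index_variant), ids.index(region.functional_variant)
            if i != j:
                gi, gj = block[:, i].astype(float), block[:, j].astype(float)
                if gi.std() > 0 and gj.std() > 0:
                    achieved = float(np.corrcoef(gi, gj)[0, 1] ** 2)
                else:
                    achieved = float("nan")
            else:
                achieved = 1.0
            region_truth_rows.append(
                {
                    "region_id": region.region_id,
                    "population": p.label,
                    "target_r2": region.target_r2,
                    "achieved_r2": achieved,
                }
            )
            col += region.n_variants

        cov = config.covariates
        age = rng_cov.normal(cov.age_mean, cov.age_sd, size=pool_n)
        bmi = rng_cov.normal(cov.bmi_mean, cov.bmi_sd, size=pool_n)
        sex = (rng_cov.random(pool_n) < cov.male_fraction).astype(int)
        covariate_lp = cov.beta_age * age + cov.beta_sex * sex + cov.beta_bmi * bmi

        effects = np.zeros(len(variant_ids))
        for region in config.regions:
            if region.functional_or != 1.0:
                k = variant_ids.index(region.functional_variant)
                effects[k] = math.log(region.functional_or)

        targets = [(s.label, s.n_cases, s.n_controls) for s in p.strata]
        picks, _prev = assign_phenotypes(
            pool_dos.astype(float),
            effects,
            covariate_lp,
            config.baseline_log_odds,
            targets,
            rng_phen,
        )
        idx = picks["pool_index"].to_numpy()
        frame = pd.DataFrame(
            {
                "sample": [f"{p.label}_{i:06d}" for i in range(len(idx))],
                "population": p.label,
                "stratum": picks["stratum"].to_numpy(),
                "sex": sex[idx],
                "age": age[idx].round(2),
                "bmi": bmi[idx].round(2),
                "case": picks["case"].to_numpy(),
            }
        )
        sample_frames.append(frame)
        dosage_blocks.append(pool_dos[idx].astype(float))

    samples = pd.concat(sample_frames, ignore_index=True)
    samples["has_claims"] = np.where(
        samples["case"] == 1,
        True,
        rng_phen.random(len(samples)) < config.claims_fraction,
    )
    samples["prior_condition"] = (
        rng_phen.random(len(samples)) < config.prior_condition_fraction
    )
    dosages = DosageMatrix(
        samples["sample"].tolist(), variant_ids, np.vstack(dosage_blocks)
    )

    # chip blocks -> concrete sample subsets
    resolved = []
    for block in config.chip_plan:
        mask = samples["population"].isin(block.populations).to_numpy()
        members = samples.loc[mask, "sample"].to_numpy()
        take = rng_art.random(len(members)) < block.sample_fraction
        resolved.append((block.name, members[take].tolist(), block.missing_variants))
    dosages, info, chip_label = apply_genotyping_artifacts(
        dosages,
        resolved,
        config.info_model,
        samples.set_index("sample")["stratum"],
        rng_art,
    )
    samples["chip"] = chip_label.loc[samples["sample"]].to_numpy()

    # realized per-population effect-allele frequencies
    variants = []
    freq_rows = {}
    for p in pops:
        sub_idx = dosages.sample_index(samples.loc[samples["population"] == p.label, "sample"])
        with np.errstate(invalid="ignore"):
            freq_rows[p.label] = np.nanmean(dosages.data[sub_idx], axis=0) / 2.0
    effects_by_id = {
        r.functional_variant: math.log(r.functional_or)
        for r in config.regions
        if r.functional_or != 1.0
    }
    truth_rows = []
    for region in config.regions:
        for j, vid in enumerate(region.variant_ids()):
            k = variant_ids.index(vid)
            eff, oth = alleles[vid]
            variants.append(
                VariantRecord(
                    id=vid,
                    chrom=region.chrom,
                    pos=int(region.positions()[j]),
                    effect_allele=eff,
                    other_allele=oth,
                    freq={p.label: float(freq_rows[p.label][k]) for p in pops},
                    info=info[vid],
                )
            )
            truth_rows.append(
                {
                    "variant": vid,
                    "region_id": region.region_id,
                    "true_beta": effects_by_id.get(vid, 0.0),
                    "is_index": vid == region.index_variant,
                    "is_functional": vid == region.functional_variant,
                    "ancestral_freq": ancestral[vid],
                    **{
                        f"freq_{p.label}": float(freq_rows[p.label][k]) for p in pops
                    },
                    **{
                        f"bn_freq_{p.label}": float(
                            pop_freqs[region.region_id][p.label][j]
                        )
                        for p in pops
                    },
                }
            )

    catalog = _catalog_for_regions(config.regions, alleles, ancestral)
    return Cohort(
        config=config,
        variants=variants,
        dosages=dosages,
        samples=samples,
        catalog=catalog,
        truth=pd.DataFrame(truth_rows),
        region_truth=pd.DataFrame(region_truth_rows),
    )


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort as VCF + TSV artifacts; returns the path map."""
    from pathlib import Path

    from transrep import io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": str(out / "genotypes.vcf"),
        "samples": str(out / "samples.tsv"),
        "catalog": str(out / "catalog.tsv"),
        "truth": str(out / "truth.tsv"),
        "region_truth": str(out / "region_truth.tsv"),
        "info": str(out / "info_scores.tsv"),
    }
    io.write_vcf(cohort.variants, cohort.dosages, paths["genotypes"])
    io.write_samples(cohort.samples, paths["samples"])
    io.write_catalog(cohort.catalog, paths["catalog"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    cohort.region_truth.to_csv(paths["region_truth"], sep="\t", index=False)
    io.write_info_table(cohort.variants, paths["info"])
    return paths
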