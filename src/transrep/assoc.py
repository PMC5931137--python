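"""Per-SNP log-additive logistic association within case-control strata.

Each variant is tested one stratum at a time with unconditional logistic
regression of case status on effect-allele dosage, adjusted for age,
sex, BMI and the first 10 principal components of genotype.  Fitting is
maximum likelihood by iteratively reweighted least squares; the dosage
term's Wald statistic provides beta, SE and the two-sided p-value.
Variants are filtered to MAF >= 1% within the population (cases and
controls pooled) and imputation INFO > 0.8 within the stratum.  Missing
dosages are handled per SNP as complete-case analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from transrep.io import DosageMatrix, LocusCatalogEntry, VariantRecord, align_to_catalog

MAF_MIN = 0.01
INFO_MIN = 0.8
COVARIATE_COLUMNS = ["age", "sex", "bmi"]


class FitError(RuntimeError):
    pass


@dataclass
class AssocResult:
    """One variant's association in one stratum (effect on the log-odds scale)."""

    variant: str
    stratum: str
    beta: float
    se: float
    p: float
    n: int
    maf: float
    info: float
    converged: bool

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))


def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """ML logistic fit; returns (coefficients, standard errors, converged).

    ``X`` must already include an intercept column.  Convergence is
    declared when the largest coefficient change drops below ``tol``.
    Quasi-separation shows up as non-convergence or exploding
    coefficients and is reported through the flag.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        z = eta + (y - mu) / w
        XtW = X.T * w
        XtWX = XtW @ X
        try:
            new = np.linalg.solve(XtWX, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix: {exc}") from exc
        step = np.max(np.abs(new - beta))
        beta = new
        if step < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 30:
        converged = False  # effectively separated
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular information matrix: {exc}") from exc
    return beta, se, converged


def fit_snp_logistic(
    dosage: np.ndarray,
    case: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> AssocResult:
    """Wald test of the per-allele (log-additive) dosage effect.

    Samples with missing dosage are dropped for this SNP.  Requires at
    least two cases and two controls among the analyzed samples.
    """
    dosage = np.asarray(dosage, dtype=float)
    case = np.asarray(case, dtype=float)
    keep = ~np.isnan(dosage)
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float)
        keep &= ~np.isnan(cov).any(axis=1)
    d, y = dosage[keep], case[keep]
    n = int(keep.sum())
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise FitError("need at least 2 cases and 2 controls with observed dosage")
    cols = [np.ones(n), d]
    if covariates is not None:
        cols.append(covariates.to_numpy(dtype=float)[keep])
    X = np.column_stack(cols)
    beta, se, converged = logistic_irls(X, y)
    b, s = float(beta[1]), float(se[1])
    if s <= 0 or not np.isfinite(s):
        converged = False
        s = float("nan")
        p = float("nan")
    else:
        z = b / s
        p = float(2.0 * stats.norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    f = float(np.mean(d) / 2.0)
    return AssocResult(
        variant="",
        stratum="",
        beta=b,
        se=s,
        p=p,
        n=n,
        maf=min(f, 1 - f),
        info=float("nan"),
        converged=bool(converged),
    )


def compute_pcs(
    dosages: DosageMatrix,
    subset_size: int = 10_000,
    maf_min: float = 0.05,
    callrate_min: float = 0.95,
    k: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Principal components of genotype over a random variant subset.

    Eligible variants have folded frequency above ``maf_min`` and call
    rate above ``callrate_min``; ``subset_size`` of them are sampled at
    random (all of them, with a warning, when fewer are eligible).
    Columns of the standardized dosage matrix (missing values replaced by
    the column mean, i.e. zero after centring) are decomposed by SVD; the
    unit-norm left singular vectors, ordered by decreasing singular
    value, are returned as PC1..PCk.
    """
    import warnings

    rng = np.random.default_rng() if rng is None else rng
    freq = dosages.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    eligible = np.flatnonzero((maf > maf_min) & (dosages.callrate() > callrate_min))
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} eligible variants for {k} PCs")
    if len(eligible) > subset_size:
        eligible = rng.choice(eligible, size=subset_size, replace=False)
    elif len(eligible) < subset_size:
        warnings.warn(
            f"only {len(eligible)} eligible variants (< subset_size={subset_size}); using all",
            stacklevel=2,
        )
    G = dosages.data[:, np.sort(eligible)].copy()
    mu = np.nanmean(G, axis=0)
    sd = np.nanstd(G, axis=0)
    sd[sd == 0] = 1.0
    G = (G - mu) / sd
    G[np.isnan(G)] = 0.0
    u, s, _ = np.linalg.svd(G, full_matrices=False)
    pcs = u[:, :k]
    return pd.DataFrame(
        pcs, index=dosages.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )


def _population_maf(dosages: DosageMatrix, sample_mask: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        f = np.nanmean(dosages.data[sample_mask], axis=0) / 2.0
    return np.minimum(f, 1 - f)


def scan(
    dosages: DosageMatrix,
    samples: pd.DataFrame,
    variants: list[VariantRecord],
    catalog: list[LocusCatalogEntry] | None = None,
    maf_min: float = MAF_MIN,
    info_min: float = INFO_MIN,
    n_pcs: int = 10,
    pc_subset_size: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Stratified per-SNP association scan with the study's filters.

    Returns the association table (one row per stratum x passing variant)
    and a machine-readable exclusion log.  Principal components are
    computed per population, since every analysis is population-
    stratified.  Effects of catalog index variants are reported both on
    the effect-allele scale (``beta``) and oriented to the reported risk
    allele (``beta_oriented``, ``direction``).
    """
    rng = np.random.default_rng(seed)
    vmap = {v.id: v for v in variants}
    orientation: dict[str, int | str] = {}
    exclusions: list[dict] = []
    if catalog:
        for entry in catalog:
            v = vmap.get(entry.index_variant)
            if v is None:
                exclusions.append(
                    {
                        "variant": entry.index_variant,
                        "scope": "catalog",
                        "reason": "index_variant_absent",
                    }
                )
                continue
            orientation[v.id] = align_to_catalog(v, entry)

    rows = []
    for pop, pop_samples in samples.groupby("population", sort=False):
        sub = dosages.subset_samples(pop_samples["sample"].tolist())
        pop_maf = _population_maf(sub, np.ones(sub.n_samples, dtype=bool))
        try:
            pcs = compute_pcs(
                sub, subset_size=pc_subset_size, k=n_pcs, rng=rng
            )
        except ValueError:
            pcs = pd.DataFrame(index=sub.samples)
        for stratum, strat_samples in pop_samples.groupby("stratum", sort=False):
            if strat_samples.empty:
                continue
            sidx = sub.sample_index(strat_samples["sample"].tolist())
            y = strat_samples["case"].to_numpy(dtype=float)
            if (y == 1).sum() < 2 or (y == 0).sum() < 2:
                exclusions.append(
                    {"variant": "*", "scope": stratum, "reason": "stratum_too_small"}
                )
                continue
            cov = pd.concat(
                [
                    strat_samples[COVARIATE_COLUMNS].reset_index(drop=True),
                    pcs.iloc[sidx].reset_index(drop=True),
                ],
                axis=1,
            )
            for j, vid in enumerate(dosages.variants):
                if pop_maf[j] < maf_min or np.isnan(pop_maf[j]):
                    exclusions.append(
                        {"variant": vid, "scope": f"{pop}:{stratum}", "reason": "maf_lt_min"}
                    )
                    continue
                info = vmap[vid].info.get(stratum, 1.0) if vid in vmap else 1.0
                if info <= info_min:
                    exclusions.append(
                        {"variant": vid, "scope": f"{pop}:{stratum}", "reason": "info_le_min"}
                    )
                    continue
                d = sub.data[sidx, j]
                if np.all(np.isnan(d)):
                    exclusions.append(
                        {"variant": vid, "scope": f"{pop}:{stratum}", "reason": "all_missing"}
                    )
                    continue
                dd = d[~np.isnan(d)]
                if np.nanstd(dd) == 0:
                    exclusions.append(
                        {"variant": vid, "scope": f"{pop}:{stratum}", "reason": "monomorphic"}
                    )
                    continue
                try:
                    res = fit_snp_logistic(d, y, cov)
                except FitError as exc:
                    exclusions.append(
                        {
                            "variant": vid,
                            "scope": f"{pop}:{stratum}",
                            "reason": f"fit_failed:{exc}",
                        }
                    )
                    continue
                if not res.converged or not np.isfinite(res.p):
                    exclusions.append(
                        {
                            "variant": vid,
                            "scope": f"{pop}:{stratum}",
                            "reason": "nonconvergence_or_separation",
                        }
                    )
                    continue
                orient = orientation.get(vid, +1)
                oriented = np.nan if orient == "ambiguous" else orient * res.beta
                rows.append(
                    {
                        "variant": vid,
                        "population": pop,
                        "stratum": stratum,
                        "effect_allele": vmap[vid].effect_allele if vid in vmap else "NA",
                        "beta": res.beta,
                        "se": res.se,
                        "p": res.p,
                        "or": res.or_,
                        "n": res.n,
                        "maf": pop_maf[j],
                        "info": info,
                        "orientation": orient,
                        "beta_oriented": oriented,
                    }
                )
    return pd.DataFrame(rows), exclusions
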