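"""Fixed-effects inverse-variance meta-analysis of stratum-level results.

Pooling is on the effect (log-odds) scale with weights 1/SE², the
STDERR scheme: the pooled estimate is the precision-weighted mean and
its variance the reciprocal total precision.  Because fixed-effects
pooling is associative, combining strata within populations and then
populations across ethnic groups equals a single-stage pool over all
strata.  A sample-size-weighted z-score scheme is available behind a
flag.  Cochran's Q and I² are reported for every pool but never used to
filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MetaResult:
    variant: str
    scope: str  # population label or "cross_ethnic"
    beta: float
    se: float
    p: float
    n_strata: int
    populations_present: list[str] = field(default_factory=list)
    q: float = 0.0
    i2: float = 0.0
    n: int = 0


def inverse_variance_meta(
    betas,
    ses,
    variant: str = "",
    scope: str = "",
    ns=None,
) -> MetaResult:
    """Precision-weighted fixed-effects pool of (beta, se) pairs."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0:
        raise ValueError("empty input to meta-analysis")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))
    q = float(np.sum(w * (betas - beta) ** 2))
    k = betas.size
    i2 = float(max(0.0, (q - (k - 1)) / q)) if q > 0 and k > 1 else 0.0
    return MetaResult(
        variant=variant,
        scope=scope,
        beta=beta,
        se=se,
        p=p,
        n_strata=k,
        q=q,
        i2=i2,
        n=0 if ns is None else int(np.sum(ns)),
    )


def sample_size_weighted_meta(betas, ses, ns, variant: str = "", scope: str = "") -> MetaResult:
    """METAL's z-score scheme: weights proportional to sqrt(n), sign from beta."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ns = np.asarray(ns, dtype=float)
    z = betas / ses
    w = np.sqrt(ns)
    zc = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    p = float(np.clip(2.0 * stats.norm.sf(abs(zc)), np.nextafter(0, 1), 1.0))
    # no effect-scale estimate under this scheme; report the z and p
    return MetaResult(
        variant=variant,
        scope=scope,
        beta=float(np.sign(zc)),
        se=float("nan"),
        p=p,
        n_strata=betas.size,
        n=int(ns.sum()),
    )


def _meta_frame(results: list[MetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": r.variant,
                "scope": r.scope,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "or": float(np.exp(r.beta)),
                "n_strata": r.n_strata,
                "n": r.n,
                "populations_present": ",".join(r.populations_present),
                "q": r.q,
                "i2": r.i2,
            }
            for r in results
        ]
    )


def population_meta(assoc: pd.DataFrame) -> pd.DataFrame:
    """Combine stratum results into one row per (population, variant)."""
    results = []
    for (pop, vid), grp in assoc.groupby(["population", "variant"], sort=False):
        r = inverse_variance_meta(
            grp["beta"].to_numpy(), grp["se"].to_numpy(), variant=vid, scope=pop,
            ns=grp["n"].to_numpy(),
        )
        r.populations_present = [pop]
        results.append(r)
    df = _meta_frame(results)
    if df.empty:
        return df
    extra = assoc.groupby(["population", "variant"], sort=False).agg(
        orientation=("orientation", "first"), maf=("maf", "mean")
    )
    df = df.merge(
        extra, left_on=["scope", "variant"], right_index=True, how="left"
    )
    df["beta_oriented"] = np.where(
        df["orientation"] == "ambiguous", np.nan, df["beta"] * df["orientation"].replace("ambiguous", np.nan).astype(float)
    )
    return df


def cross_ethnic_meta(
    assoc: pd.DataFrame, min_populations: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage pool: within-population meta, then across populations.

    Variants observed in fewer than ``min_populations`` populations are
    excluded from the cross-ethnic table with a reason code; the
    population-level table and the exclusion-annotated cross-ethnic
    table are both returned.
    """
    pop_df = population_meta(assoc)
    results = []
    excluded = []
    for vid, grp in pop_df.groupby("variant", sort=False):
        pops = sorted(grp["scope"].unique())
        if len(pops) < min_populations:
            excluded.append(
                {"variant": vid, "reason": f"present_in_{len(pops)}_population(s)"}
            )
            continue
        r = inverse_variance_meta(
            grp["beta"].to_numpy(),
            grp["se"].to_numpy(),
            variant=vid,
            scope="cross_ethnic",
            ns=grp["n"].to_numpy(),
        )
        r.n_strata = int(grp["n_strata"].sum())
        r.populations_present = pops
        results.append(r)
    cross = _meta_frame(results)
    if not cross.empty:
        orient = pop_df.groupby("variant")["orientation"].first()
        cross = cross.merge(orient, left_on="variant", right_index=True, how="left")
        cross["beta_oriented"] = np.where(
            cross["orientation"] == "ambiguous",
            np.nan,
            cross["beta"]
            * cross["orientation"].replace("ambiguous", np.nan).astype(float),
        )
    if excluded:
        cross.attrs["excluded"] = excluded
    return pop_df, cross
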