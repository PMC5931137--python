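"""Directional-consistency test for known risk loci.

For each catalog index SNP the estimated effect is oriented to the
reported risk allele; the SNP is consistent when the oriented log-odds
is positive (all reported ORs exceed 1 after risk-allele orientation).
Under the null of no shared signal each SNP is consistent with
probability 1/2, so the count of consistent SNPs is tested against
Binomial(n, 1/2) with an exact one-sided upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import binom

from transrep.io import LocusCatalogEntry


@dataclass
class ConsistencySummary:
    scope: str
    n: int  # catalog SNPs evaluated in this scope
    k: int  # directionally consistent
    fraction: float
    p: float  # one-sided exact binomial upper tail
    nominal: list[str] = field(default_factory=list)  # consistent with p < 0.05
    excluded: list[dict] = field(default_factory=list)


def direction_consistent(oriented_beta: float) -> bool:
    """True iff the risk-allele-oriented effect is positive.

    A beta of exactly zero counts as inconsistent (conservative; a
    probability-zero event for continuous estimates).
    """
    return oriented_beta > 0


def binomial_consistency(k: int, n: int) -> float:
    """Exact one-sided upper tail P(X >= k), X ~ Binomial(n, 1/2)."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial arguments k={k}, n={n}")
    return float(binom.sf(k - 1, n, 0.5))


def summarize_consistency(
    meta: pd.DataFrame,
    catalog: list[LocusCatalogEntry],
    scope: str,
    alpha_nominal: float = 0.05,
) -> ConsistencySummary:
    """Count consistent index SNPs in one scope and test against chance.

    ``meta`` must carry ``variant``, ``p`` and ``beta_oriented`` columns
    (a population-level or cross-ethnic meta table already restricted to
    the scope).  Catalog SNPs absent from the table (MAF/INFO-filtered)
    or with ambiguous orientation are excluded from n and logged.
    """
    by_variant = meta.set_index("variant")
    k = 0
    n = 0
    nominal: list[str] = []
    excluded: list[dict] = []
    for entry in catalog:
        vid = entry.index_variant
        if vid not in by_variant.index:
            excluded.append({"variant": vid, "reason": "filtered_or_absent"})
            continue
        row = by_variant.loc[vid]
        ob = row["beta_oriented"]
        if pd.isna(ob):
            excluded.append({"variant": vid, "reason": "ambiguous_orientation"})
            continue
        n += 1
        if direction_consistent(float(ob)):
            k += 1
            if float(row["p"]) < alpha_nominal:
                nominal.append(vid)
    p = binomial_consistency(k, n) if n >= 1 else float("nan")
    return ConsistencySummary(
        scope=scope,
        n=n,
        k=k,
        fraction=k / n if n else float("nan"),
        p=p,
        nominal=nominal,
        excluded=excluded,
    )


def consistency_table(summaries: list[ConsistencySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": s.scope,
                "n": s.n,
                "k": s.k,
                "fraction": s.fraction,
                "binomial_p": s.p,
                "n_nominal": len(s.nominal),
                "nominal_snps": ",".join(s.nominal),
            }
            for s in summaries
        ]
    )
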