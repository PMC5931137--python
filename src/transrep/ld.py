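"""LD computation, proxy selection, greedy tag binning, regional replication.

r² is the squared Pearson correlation of dosages (the Rogers-Huff
composite estimator), which coincides with haplotype r² when the input
is phased allele indicators.  Proxies of an index SNP are the region
variants with r² >= 0.4 to it in a designated reference panel.  The
effective number of tests per region is the number of greedy pairwise
tag bins at r² >= 0.8 among variants with MAF > 1%, and a region
replicates when any proxy's p-value beats 0.05 divided by that count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from transrep.io import DosageMatrix

R2_PROXY = 0.4
R2_TAG = 0.8


class MonomorphicError(ValueError):
    """LD is undefined against a monomorphic variant."""


def r2_from_dosages(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least 2 pairwise-complete observations")
    if x.std() == 0 or y.std() == 0:
        raise MonomorphicError("r2 undefined for a monomorphic variant")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(panel: DosageMatrix, variant_ids: list[str]) -> np.ndarray:
    """r² matrix over the named variants; NaN where undefined."""
    cols = np.column_stack([panel.column(v) for v in variant_ids])
    m = cols.shape[1]
    out = np.full((m, m), np.nan)
    for i in range(m):
        out[i, i] = 1.0
        for j in range(i + 1, m):
            try:
                out[i, j] = out[j, i] = r2_from_dosages(cols[:, i], cols[:, j])
            except (MonomorphicError, ValueError):
                pass
    return out


def proxy_set(
    region_variants: list[str],
    index_id: str,
    panel: DosageMatrix,
    r2_min: float = R2_PROXY,
) -> list[str]:
    """Region variants with r² to the index >= the threshold (index included)."""
    if index_id not in panel.variants:
        raise ValueError(f"index variant {index_id} absent from reference panel")
    x = panel.column(index_id)
    out = []
    for vid in region_variants:
        if vid == index_id:
            out.append(vid)  # r2 with itself is 1
            continue
        if vid not in panel.variants:
            continue
        try:
            r2 = r2_from_dosages(x, panel.column(vid))
        except (MonomorphicError, ValueError):
            continue
        if r2 >= r2_min:
            out.append(vid)
    return out


def greedy_tag_bins(
    region_variants: list[str],
    panel: DosageMatrix,
    r2_tag: float = R2_TAG,
    maf_min: float = 0.01,
) -> tuple[int, dict[str, list[str]]]:
    """Greedy pairwise tag-SNP binning (Haploview-style).

    Among region variants with panel MAF > ``maf_min``, repeatedly pick
    the variant covering the most untagged variants at r² >= ``r2_tag``
    (itself included), make it a tag, remove its bin, and repeat.  Ties
    break by higher MAF, then lower position (here: variant order).
    Returns the bin count and the tag -> members map; bins partition the
    eligible set.
    """
    freqs = {}
    eligible = []
    for vid in region_variants:
        if vid not in panel.variants:
            continue
        col = panel.column(vid)
        col = col[~np.isnan(col)]
        if col.size == 0 or col.std() == 0:
            continue
        f = float(col.mean() / 2.0)
        maf = min(f, 1 - f)
        if maf > maf_min:
            eligible.append(vid)
            freqs[vid] = maf
    if not eligible:
        return 0, {}
    r2 = _pairwise_r2(panel, eligible)
    order = {vid: k for k, vid in enumerate(eligible)}
    untagged = set(eligible)
    bins: dict[str, list[str]] = {}
    while untagged:
        best = None
        best_cover: set[str] = set()
        for vid in untagged:
            i = order[vid]
            cover = {
                w
                for w in untagged
                if w == vid or (not np.isnan(r2[i, order[w]]) and r2[i, order[w]] >= r2_tag)
            }
            key = (len(cover), freqs[vid], -order[vid])
            if best is None or key > best_key:
                best, best_key, best_cover = vid, key, cover
        bins[best] = sorted(best_cover, key=lambda w: order[w])
        untagged -= best_cover
    return len(bins), bins


@dataclass
class RegionCall:
    """Regional replication verdict for one known locus."""

    region_id: str
    n_tags: int
    alpha_region: float
    proxies: list[str]
    best_proxy: str | None
    best_p: float
    replicated: bool
    status: str = "tested"  # "tested" | "untestable"
    tested_proxies: list[str] = field(default_factory=list)


def regional_replication(
    region_id: str,
    proxy_pvalues: dict[str, float],
    proxies: list[str],
    n_tags: int,
    alpha: float = 0.05,
) -> RegionCall:
    """Call replication when any proxy beats the tag-count-derived threshold.

    ``proxy_pvalues`` must already be restricted to variants passing the
    INFO quality rule; proxies absent from it are treated as filtered
    out.  When every proxy is filtered, the call is "untestable" rather
    than a failure to replicate.
    """
    if not proxies:
        raise ValueError(f"{region_id}: proxy set is empty")
    if n_tags < 1:
        raise ValueError(f"{region_id}: n_tags must be >= 1")
    alpha_region = alpha / n_tags
    tested = [v for v in proxies if v in proxy_pvalues and np.isfinite(proxy_pvalues[v])]
    if not tested:
        return RegionCall(
            region_id=region_id,
            n_tags=n_tags,
            alpha_region=alpha_region,
            proxies=list(proxies),
            best_proxy=None,
            best_p=float("nan"),
            replicated=False,
            status="untestable",
        )
    best = min(tested, key=lambda v: proxy_pvalues[v])
    best_p = float(proxy_pvalues[best])
    return RegionCall(
        region_id=region_id,
        n_tags=n_tags,
        alpha_region=alpha_region,
        proxies=list(proxies),
        best_proxy=best,
        best_p=best_p,
        replicated=best_p < alpha_region,
        tested_proxies=tested,
    )


def region_call_table(calls: list[RegionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": c.region_id,
                "n_tags": c.n_tags,
                "alpha_region": c.alpha_region,
                "n_proxies": len(c.proxies),
                "best_proxy": c.best_proxy or "",
                "best_p": c.best_p,
                "replicated": c.replicated,
                "status": c.status,
            }
            for c in calls
        ]
    )
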