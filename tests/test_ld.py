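"""LD estimation, proxy selection, greedy tag binning, region calls."""

import itertools

import numpy as np
import pytest

from transrep.io import DosageMatrix
from transrep.ld import (
    MonomorphicError,
    greedy_tag_bins,
    proxy_set,
    r2_from_dosages,
    regional_replication,
)


def _haplotype_dosages(hap_counts):
    """Expand {(a1,a2): count} haplotype tables into paired diploid dosages."""
    haps = []
    for (a, b), c in hap_counts.items():
        haps.extend([(a, b)] * c)
    haps = np.array(haps, dtype=float)
    # pair consecutive haplotypes into individuals
    x = haps[0::2, 0] + haps[1::2, 0]
    y = haps[0::2, 1] + haps[1::2, 1]
    return x, y


class TestR2:
    def test_self_correlation_is_one(self, rng):
        x = rng.binomial(2, 0.3, 100).astype(float)
        assert r2_from_dosages(x, x) == pytest.approx(1.0)

    def test_complete_coupling(self):
        x, y = _haplotype_dosages({(1, 1): 50, (0, 0): 50})
        assert r2_from_dosages(x, y) == pytest.approx(1.0)

    def test_linkage_equilibrium_four_haplotypes(self):
        x, y = _haplotype_dosages({(1, 1): 25, (1, 0): 25, (0, 1): 25, (0, 0): 25})
        assert r2_from_dosages(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_d_squared_on_enumerable_tables(self):
        """On phased haplotype indicators r2 equals D^2/(pA qA pB qB)."""
        tables = [
            {(1, 1): 40, (1, 0): 10, (0, 1): 10, (0, 0): 40},
            {(1, 1): 30, (1, 0): 20, (0, 1): 5, (0, 0): 45},
            {(1, 1): 10, (1, 0): 40, (0, 1): 40, (0, 0): 10},
        ]
        for t in tables:
            n = sum(t.values())
            pa = (t[(1, 1)] + t[(1, 0)]) / n
            pb = (t[(1, 1)] + t[(0, 1)]) / n
            d = t[(1, 1)] / n - pa * pb
            expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
            haps = []
            for (a, b), c in t.items():
                haps.extend([(a, b)] * c)
            haps = np.array(haps, dtype=float)
            got = r2_from_dosages(haps[:, 0], haps[:, 1])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_signalled(self):
        with pytest.raises(MonomorphicError):
            r2_from_dosages(np.ones(10), np.arange(10, dtype=float) % 3)

    def test_pairwise_complete_filtering(self, rng):
        x = rng.binomial(2, 0.4, 200).astype(float)
        y = x.copy()
        y[:50] = np.nan
        assert r2_from_dosages(x, y) == pytest.approx(1.0)


def _panel_from_latent(rng, n, corrs):
    """Panel whose columns are thresholded latents correlated with column 0."""
    m = len(corrs) + 1
    z0 = rng.standard_normal(2 * n)
    cols = [z0]
    for c in corrs:
        cols.append(c * z0 + np.sqrt(1 - c * c) * rng.standard_normal(2 * n))
    hap = (np.column_stack(cols) > 0).astype(float)
    dos = hap[0::2] + hap[1::2]
    return DosageMatrix(
        [f"s{i}" for i in range(n)], [f"v{j}" for j in range(m)], dos
    )


class TestProxies:
    def test_index_alone(self, rng):
        panel = _panel_from_latent(rng, 500, [])
        assert proxy_set(["v0"], "v0", panel) == ["v0"]

    def test_threshold_inclusive_boundary(self, rng):
        panel = _panel_from_latent(rng, 3000, [0.9, 0.3])
        r2_near = r2_from_dosages(panel.column("v0"), panel.column("v1"))
        r2_far = r2_from_dosages(panel.column("v0"), panel.column("v2"))
        # set the threshold exactly at the stronger pair's r2: inclusive
        got = proxy_set(["v0", "v1", "v2"], "v0", panel, r2_min=r2_near)
        assert "v1" in got
        got2 = proxy_set(["v0", "v1", "v2"], "v0", panel, r2_min=r2_far + 1e-9)
        assert "v2" not in got2

    def test_matches_brute_force(self, rng):
        panel = _panel_from_latent(rng, 2000, [0.95, 0.8, 0.5, 0.2, 0.05])
        ids = list(panel.variants)
        got = proxy_set(ids, "v0", panel, 0.4)
        brute = [
            v for v in ids
            if v == "v0" or r2_from_dosages(panel.column("v0"), panel.column(v)) >= 0.4
        ]
        assert got == brute

    def test_missing_index_rejected(self, rng):
        panel = _panel_from_latent(rng, 100, [0.5])
        with pytest.raises(ValueError, match="absent"):
            proxy_set(["v0"], "vX", panel)


from oracles import brute_force_greedy_bins  # noqa: E402  (tests dir on sys.path)


class TestTagBins:
    def test_one_bin_when_all_correlated(self, rng):
        # latent corr must be very high: thresholding attenuates genotype r2
        panel = _panel_from_latent(rng, 4000, [0.999, 0.998])
        n_tags, bins = greedy_tag_bins(list(panel.variants), panel, 0.8)
        assert n_tags == 1

    def test_singletons_when_uncorrelated(self, rng):
        panel = _panel_from_latent(rng, 4000, [0.1, 0.05, 0.0])
        n_tags, bins = greedy_tag_bins(list(panel.variants), panel, 0.8)
        assert n_tags == 4
        assert all(len(m) == 1 for m in bins.values())

    def test_bins_partition_eligible_set(self, rng):
        panel = _panel_from_latent(rng, 2000, [0.95, 0.9, 0.6, 0.3, 0.85, 0.1])
        _, bins = greedy_tag_bins(list(panel.variants), panel, 0.8)
        members = list(itertools.chain.from_iterable(bins.values()))
        assert sorted(members) == sorted(set(members))
        assert set(members) == set(panel.variants)
        for tag in bins:
            assert tag in bins[tag]

    def test_n_tags_monotone_in_threshold(self, rng):
        panel = _panel_from_latent(rng, 2000, [0.95, 0.9, 0.6, 0.3, 0.85, 0.1])
        counts = [
            greedy_tag_bins(list(panel.variants), panel, t)[0]
            for t in (0.5, 0.7, 0.8, 0.9, 0.99)
        ]
        assert counts == sorted(counts)

    def test_matches_independent_brute_force(self, rng):
        for rep in range(5):
            corrs = rng.uniform(0, 1, size=7)
            panel = _panel_from_latent(rng, 1500, list(corrs))
            ids = [
                v for v in panel.variants
                if min(panel.column(v).mean() / 2, 1 - panel.column(v).mean() / 2) > 0.01
            ]
            m = len(ids)
            r2 = [[np.nan] * m for _ in range(m)]
            for i in range(m):
                for j in range(m):
                    r2[i][j] = r2_from_dosages(panel.column(ids[i]), panel.column(ids[j]))
            maf = {
                v: min(panel.column(v).mean() / 2, 1 - panel.column(v).mean() / 2)
                for v in ids
            }
            expected = brute_force_greedy_bins(ids, r2, maf, 0.8)
            n_tags, bins = greedy_tag_bins(list(panel.variants), panel, 0.8)
            assert n_tags == len(expected)
            assert bins == expected


class TestRegionCall:
    def test_single_tag_nominal_threshold(self):
        call = regional_replication("r", {"v0": 0.049}, ["v0"], n_tags=1)
        assert call.replicated and call.alpha_region == pytest.approx(0.05)

    def test_threshold_scales_with_tag_count(self):
        call = regional_replication("r", {"v0": 0.006}, ["v0"], n_tags=10)
        assert not call.replicated  # threshold 0.005
        call2 = regional_replication("r", {"v0": 0.004}, ["v0"], n_tags=10)
        assert call2.replicated

    def test_best_proxy_recorded(self):
        pv = {"v0": 0.2, "v1": 0.001, "v2": 0.05}
        call = regional_replication("r", pv, ["v0", "v1", "v2"], n_tags=2)
        assert call.best_proxy == "v1" and call.best_p == pytest.approx(0.001)

    def test_all_proxies_filtered_is_untestable(self):
        call = regional_replication("r", {}, ["v0", "v1"], n_tags=3)
        assert call.status == "untestable" and not call.replicated

    def test_empty_proxies_rejected(self):
        with pytest.raises(ValueError):
            regional_replication("r", {"v0": 0.1}, [], n_tags=1)
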