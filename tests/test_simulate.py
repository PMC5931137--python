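"""Synthetic-cohort generator: frequency law, LD targets, phenotype contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transrep.config import InfoModel, RegionSpec, small_config
from transrep.io import DosageMatrix
from transrep.simulate import (
    SimulationError,
    apply_genotyping_artifacts,
    assign_phenotypes,
    calibrate_latent_rho,
    haplotypes_to_dosages,
    simulate_cohort,
    simulate_frequencies,
    simulate_haplotypes,
    thresholded_r2,
)


class TestFrequencies:
    def test_zero_fst_identity(self, rng):
        np.testing.assert_array_equal(
            simulate_frequencies(0.3, 0.0, 3, rng), [0.3, 0.3, 0.3]
        )

    def test_balding_nichols_moments(self, rng):
        draws = simulate_frequencies(0.3, 0.1, 10_000, rng)
        # Beta(p(1-F)/F, (1-p)(1-F)/F): mean p, variance F p (1-p) = 0.021
        assert draws.mean() == pytest.approx(0.3, abs=0.01)
        assert draws.var() == pytest.approx(0.021, abs=0.002)

    def test_high_fst_concentrates_at_extremes(self, rng):
        draws = simulate_frequencies(0.5, 0.99, 5000, rng)
        # shape parameters < 1: mass piles near 0 and 1
        assert np.mean((draws < 0.05) | (draws > 0.95)) > 0.9

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_frequencies(0.0, 0.1, 3, rng)
        with pytest.raises(ValueError):
            simulate_frequencies(0.3, 1.0, 3, rng)


def _region(n_variants=2, spacing=0, decay=10_000.0, target_r2=0.0, freqs=None):
    freqs = freqs or [0.3] * n_variants
    return RegionSpec(
        region_id="rX",
        chrom="1",
        start=1000,
        end=1000 + max(1, spacing * (n_variants - 1)),
        n_variants=n_variants,
        ancestral_freqs=freqs,
        ld_decay_length=decay,
        index_variant="rX_v00",
        functional_variant=f"rX_v{n_variants - 1:02d}",
        target_r2=target_r2,
        functional_or=1.0,
    )


class TestHaplotypes:
    def test_zero_distance_equal_freq_gives_r2_one(self, rng):
        region = _region(spacing=0, target_r2=1.0)
        h = simulate_haplotypes(region, np.array([0.3, 0.3]), 4000, rng)
        r2 = np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2
        assert r2 > 0.99

    def test_distant_variants_independent(self, rng):
        region = _region(spacing=1_000_000, decay=1000.0, target_r2=0.0)
        h = simulate_haplotypes(region, np.array([0.3, 0.3]), 20_000, rng)
        r2 = np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2
        assert r2 < 0.01

    def test_target_r2_hit_at_large_n(self, rng):
        region = _region(spacing=50_000, decay=100_000.0, target_r2=0.8)
        h = simulate_haplotypes(region, np.array([0.3, 0.3]), 20_000, rng)
        r2 = np.corrcoef(h[:, 0], h[:, 1])[0, 1] ** 2
        assert 0.75 <= r2 <= 0.85

    def test_column_frequencies_within_binomial_bounds(self, rng):
        freqs = np.array([0.1, 0.25, 0.4])
        region = _region(n_variants=3, spacing=10_000, freqs=list(freqs))
        n = 20_000
        h = simulate_haplotypes(region, freqs, n, rng)
        got = h.mean(axis=0)
        sd = np.sqrt(freqs * (1 - freqs) / n)
        assert np.all(np.abs(got - freqs) < 3 * sd)

    def test_odd_haplotype_count_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_haplotypes(_region(), np.array([0.3, 0.3]), 101, rng)

    def test_infeasible_target_warns_and_caps(self):
        # very mismatched frequencies cannot reach r2 = 0.9 after thresholding
        with pytest.warns(UserWarning, match="infeasible"):
            rho, achieved = calibrate_latent_rho(0.9, 0.05, 0.5)
        assert achieved < 0.9
        assert achieved == pytest.approx(thresholded_r2(rho, 0.05, 0.5), abs=1e-6)

    def test_dosages_are_0_1_2(self, rng):
        h = simulate_haplotypes(_region(), np.array([0.3, 0.3]), 200, rng)
        d = haplotypes_to_dosages(h)
        assert set(np.unique(d)) <= {0, 1, 2}
        assert d.shape == (100, 2)


class TestPhenotypes:
    def test_null_model_prevalence_half(self, rng):
        n = 20_000
        dos = rng.integers(0, 3, size=(n, 1)).astype(float)
        _, prev = assign_phenotypes(
            dos, [0.0], np.zeros(n), 0.0, [("s1", 100, 100)], rng
        )
        assert prev == pytest.approx(0.5, abs=0.02)

    def test_exact_subsampling_counts(self, rng):
        n = 5000
        dos = rng.integers(0, 3, size=(n, 1)).astype(float)
        picks, _ = assign_phenotypes(
            dos, [0.0], np.zeros(n), 0.0,
            [("s1", 100, 200), ("s2", 150, 50)], rng,
        )
        counts = picks.groupby(["stratum", "case"]).size()
        assert counts.loc[("s1", 1)] == 100 and counts.loc[("s1", 0)] == 200
        assert counts.loc[("s2", 1)] == 150 and counts.loc[("s2", 0)] == 50
        assert picks["pool_index"].is_unique

    def test_unreachable_targets_signal(self, rng):
        n = 200
        dos = np.zeros((n, 1))
        with pytest.raises(SimulationError, match="prevalence"):
            assign_phenotypes(dos, [0.0], np.zeros(n), -10.0, [("s1", 150, 10)], rng)


class TestArtifacts:
    def _matrix(self, n=30, m=10):
        rng = np.random.default_rng(0)
        return DosageMatrix(
            [f"s{i}" for i in range(n)],
            [f"v{j}" for j in range(m)],
            rng.integers(0, 3, size=(n, m)).astype(float),
        )

    def test_empty_plan_is_identity(self, rng):
        dm = self._matrix()
        strata = pd.Series(["a"] * 15 + ["b"] * 15, index=dm.samples)
        out, info, chip = apply_genotyping_artifacts(dm, [], InfoModel(), strata, rng)
        np.testing.assert_array_equal(out.data, dm.data)
        assert set(info) == set(dm.variants)
        assert (chip == "gwas").all()

    def test_exactly_designated_cells_missing(self, rng):
        dm = self._matrix()
        strata = pd.Series(["a"] * 30, index=dm.samples)
        block_samples = [f"s{i}" for i in range(9)]  # 30% subset
        block_vars = ["v1", "v4"]
        out, _, chip = apply_genotyping_artifacts(
            dm, [("chipA", block_samples, block_vars)], InfoModel(), strata, rng
        )
        miss = np.isnan(out.data)
        expected = np.zeros_like(miss)
        expected[np.ix_(range(9), [1, 4])] = True
        np.testing.assert_array_equal(miss, expected)
        assert (chip.iloc[:9] == "chipA").all()

    def test_unknown_ids_rejected(self, rng):
        dm = self._matrix()
        strata = pd.Series(["a"] * 30, index=dm.samples)
        with pytest.raises(ValueError, match="unknown"):
            apply_genotyping_artifacts(
                dm, [("bad", ["nope"], ["v1"])], InfoModel(), strata, rng
            )

    def test_forced_info_score_applied(self, rng):
        dm = self._matrix()
        strata = pd.Series(["a"] * 15 + ["b"] * 15, index=dm.samples)
        _, info, _ = apply_genotyping_artifacts(
            dm, [], InfoModel(forced={"v3": 0.5}), strata, rng
        )
        assert info["v3"] == {"a": 0.5, "b": 0.5}


class TestCohort:
    def test_same_seed_identical_outputs(self):
        cfg = small_config(seed=42, n_regions=2, n_variants=4, n_cases=40, n_controls=60)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(a.dosages.data, nan=-9), np.nan_to_num(b.dosages.data, nan=-9)
        )
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_stratum_counts_and_structure(self, small_cohort):
        cfg = small_cohort.config
        for pop in cfg.populations:
            for s in pop.strata:
                g = small_cohort.samples[small_cohort.samples["stratum"] == s.label]
                assert (g["case"] == 1).sum() == s.n_cases
                assert (g["case"] == 0).sum() == s.n_controls

    def test_dosages_hard_calls_or_missing(self, small_cohort):
        vals = small_cohort.dosages.data
        finite = vals[~np.isnan(vals)]
        assert set(np.unique(finite)) <= {0.0, 1.0, 2.0}

    def test_chip_block_missingness_matches_plan(self, small_cohort):
        cfg = small_cohort.config
        block = cfg.chip_plan[0]
        chip_samples = small_cohort.samples.loc[
            small_cohort.samples["chip"] == block.name, "sample"
        ]
        assert len(chip_samples) > 0
        idx = small_cohort.dosages.sample_index(chip_samples)
        for vid in block.missing_variants:
            col = small_cohort.dosages.column(vid)
            assert np.isnan(col[idx]).all()

    def test_achieved_r2_near_target(self, small_cohort):
        rt = small_cohort.region_truth
        assert (rt["achieved_r2"] - rt["target_r2"]).abs().max() < 0.1

    def test_realized_frequencies_track_balding_nichols_draws(self, rng):
        """Cohort-sample frequencies match binomial sampling noise around the
        population draw (controls+cases pooled, null effects)."""
        cfg = small_config(
            seed=9, n_regions=4, n_variants=4, n_cases=300, n_controls=300,
            functional_or=1.0, n_effect_regions=0,
        )
        cohort = simulate_cohort(cfg)
        n_covered = 0
        n_total = 0
        for pop in cfg.population_labels:
            sub = cohort.samples[cohort.samples["population"] == pop]
            idx = cohort.dosages.sample_index(sub["sample"])
            freqs = np.nanmean(cohort.dosages.data[idx], axis=0) / 2
            for j, vid in enumerate(cohort.dosages.variants):
                p_hat = freqs[j]
                n_al = 2 * len(sub)
                lo, hi = stats.binom.interval(0.999, n_al, p_hat)
                truth_f = cohort.truth.set_index("variant").loc[vid, f"bn_freq_{pop}"]
                n_total += 1
                n_covered += lo / n_al <= truth_f <= hi / n_al
        assert n_covered / n_total > 0.97
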