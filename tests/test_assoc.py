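"""Per-SNP logistic association: closed-form oracles, PCs, filter contracts."""

import numpy as np
import pandas as pd
import pytest

from transrep.assoc import FitError, compute_pcs, fit_snp_logistic, scan
from transrep.config import small_config
from transrep.io import DosageMatrix
from transrep.simulate import simulate_cohort


def _two_by_two_log_or(d, y):
    """Closed-form 2x2 contingency log odds ratio for binary dosage."""
    a = np.sum((d == 1) & (y == 1))
    b = np.sum((d == 0) & (y == 1))
    c = np.sum((d == 1) & (y == 0))
    e = np.sum((d == 0) & (y == 0))
    return np.log(a * e / (b * c))


def test_binary_dosage_matches_contingency_table_oracle(rng):
    d = rng.integers(0, 2, size=2000).astype(float)
    p = 1 / (1 + np.exp(-(-0.4 + 0.6 * d)))
    y = (rng.random(2000) < p).astype(float)
    res = fit_snp_logistic(d, y)
    assert res.beta == pytest.approx(_two_by_two_log_or(d, y), abs=1e-6)


def test_matches_statsmodels_with_covariates(rng):
    sm = pytest.importorskip("statsmodels.api")
    n = 1500
    d = rng.binomial(2, 0.3, size=n).astype(float)
    cov = pd.DataFrame(
        {"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n), "bmi": rng.normal(27, 4, n)}
    )
    lp = -1 + 0.25 * d + 0.02 * cov["age"] + 0.3 * cov["sex"]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    res = fit_snp_logistic(d, y, cov)
    X = sm.add_constant(np.column_stack([d, cov]))
    fit = sm.Logit(y, X).fit(disp=0)
    assert res.beta == pytest.approx(fit.params[1], abs=1e-6)
    assert res.se == pytest.approx(fit.bse[1], rel=1e-4)
    assert res.p == pytest.approx(fit.pvalues[1], rel=1e-3)


def test_covariate_location_shift_leaves_dosage_beta_unchanged(rng):
    n = 1000
    d = rng.binomial(2, 0.3, size=n).astype(float)
    cov = pd.DataFrame({"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n),
                        "bmi": rng.normal(27, 4, n)})
    y = (rng.random(n) < 0.4).astype(float)
    r1 = fit_snp_logistic(d, y, cov)
    r2 = fit_snp_logistic(d, y, cov.assign(age=cov["age"] + 1000))
    assert r1.beta == pytest.approx(r2.beta, abs=1e-7)
    assert r1.se == pytest.approx(r2.se, abs=1e-7)


def test_missing_dosage_complete_case(rng):
    n = 800
    d = rng.binomial(2, 0.3, size=n).astype(float)
    y = (rng.random(n) < 0.5).astype(float)
    d_miss = d.copy()
    d_miss[:100] = np.nan
    res = fit_snp_logistic(d_miss, y)
    ref = fit_snp_logistic(d[100:], y[100:])
    assert res.n == n - 100
    assert res.beta == pytest.approx(ref.beta, abs=1e-12)


def test_effect_recovery_at_or_1_15(rng):
    """Mean estimated beta over replicates stays close to log(1.15)."""
    betas = []
    for _ in range(40):
        n = 4000
        d = rng.binomial(2, 0.3, size=n).astype(float)
        lp = -0.3 + np.log(1.15) * d
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        betas.append(fit_snp_logistic(d, y).beta)
    assert np.mean(betas) == pytest.approx(np.log(1.15), abs=0.02)


def test_too_few_cases_rejected(rng):
    d = rng.binomial(2, 0.3, 50).astype(float)
    y = np.zeros(50)
    y[0] = 1
    with pytest.raises(FitError):
        fit_snp_logistic(d, y)


def test_permuted_labels_sign_symmetric(rng):
    """Under label permutation the estimate has no preferred sign."""
    n = 600
    d = rng.binomial(2, 0.3, size=n).astype(float)
    y = np.zeros(n)
    y[:200] = 1
    signs = []
    for _ in range(400):
        yp = rng.permutation(y)
        signs.append(fit_snp_logistic(d, yp).beta > 0)
    assert np.mean(signs) == pytest.approx(0.5, abs=0.055)


class TestPCs:
    def _matrix(self, rng, n=300, m=80):
        return DosageMatrix(
            [f"s{i}" for i in range(n)],
            [f"v{j}" for j in range(m)],
            rng.binomial(2, 0.3, size=(n, m)).astype(float),
        )

    def test_orthonormal_and_k_columns(self, rng):
        pcs = compute_pcs(self._matrix(rng), subset_size=80, k=10, rng=rng)
        assert pcs.shape[1] == 10
        gram = pcs.to_numpy().T @ pcs.to_numpy()
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)

    def test_pc1_separates_two_populations(self, rng):
        """Two subpopulations at Fst ~0.1 separate on PC1 by sign."""
        m = 400
        anc = rng.uniform(0.2, 0.8, size=m)
        f1 = np.clip(rng.beta(anc * 9, (1 - anc) * 9), 0.01, 0.99)
        f2 = np.clip(rng.beta(anc * 9, (1 - anc) * 9), 0.01, 0.99)
        g1 = rng.binomial(2, f1, size=(250, m)).astype(float)
        g2 = rng.binomial(2, f2, size=(250, m)).astype(float)
        dm = DosageMatrix(
            [f"s{i}" for i in range(500)], [f"v{j}" for j in range(m)],
            np.vstack([g1, g2]),
        )
        pcs = compute_pcs(dm, subset_size=m, k=5, rng=rng)
        pc1 = pcs["PC1"].to_numpy()
        labels = np.array([0] * 250 + [1] * 250)
        side = (pc1 > np.median(pc1)).astype(int)
        acc = max(np.mean(side == labels), np.mean(side != labels))
        assert acc > 0.99

    def test_small_pool_warns_and_uses_all(self, rng):
        with pytest.warns(UserWarning, match="using all"):
            pcs = compute_pcs(self._matrix(rng, m=50), subset_size=10_000, k=5, rng=rng)
        assert pcs.shape[1] == 5


@pytest.fixture(scope="module")
def scanned():
    cfg = small_config(seed=21, n_regions=4, n_variants=6, n_cases=120, n_controls=200)
    # force one variant's INFO below threshold everywhere, and make one
    # non-anchor variant rare enough to trip the 1% MAF filter
    cfg.info_model.forced = {"r01_v01": 0.5}
    cfg.regions[1].ancestral_freqs[0] = 0.003
    cohort = simulate_cohort(cfg)
    table, excl = scan(
        cohort.dosages, cohort.samples, cohort.variants, cohort.catalog, seed=21
    )
    return cohort, table, excl


class TestScan:

    def test_low_info_variant_absent(self, scanned):
        _, table, excl = scanned
        assert "r01_v01" not in set(table["variant"])
        reasons = {e["reason"] for e in excl if e["variant"] == "r01_v01"}
        assert "info_le_min" in reasons

    def test_low_maf_variant_excluded_per_population(self, scanned):
        cohort, table, excl = scanned
        rare = [
            (pop, v.id)
            for v in cohort.variants
            for pop in v.freq
            if v.maf(pop) < 0.01
        ]
        assert rare, "fixture should contain at least one population-rare variant"
        for pop, vid in rare:
            assert table[(table["variant"] == vid) & (table["population"] == pop)].empty

    def test_row_count_matches_independent_recount(self, scanned):
        """One row per (stratum, variant passing that population's MAF filter
        and that stratum's INFO filter) -- recounted independently."""
        cohort, table, excl = scanned
        expected = 0
        strata = cohort.samples[["population", "stratum"]].drop_duplicates()
        failed = {
            (e["scope"], e["variant"])
            for e in excl
            if e["reason"] in ("nonconvergence_or_separation", "monomorphic", "all_missing")
            or e["reason"].startswith("fit_failed")
        }
        for _, row in strata.iterrows():
            pop, stratum = row["population"], row["stratum"]
            for v in cohort.variants:
                if v.maf(pop) >= 0.01 and v.info[stratum] > 0.8 \
                        and (f"{pop}:{stratum}", v.id) not in failed:
                    expected += 1
        assert len(table) == expected

    def test_oriented_beta_respects_catalog_orientation(self, scanned):
        cohort, table, _ = scanned
        flipped = table[table["orientation"] == -1]
        if not flipped.empty:
            np.testing.assert_allclose(
                flipped["beta_oriented"], -flipped["beta"], atol=1e-12
            )
        kept = table[table["orientation"] == 1]
        np.testing.assert_allclose(kept["beta_oriented"], kept["beta"], atol=1e-12)
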