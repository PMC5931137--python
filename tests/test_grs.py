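"""Allele-count risk scores: hand sums, missingness policy, associations."""

import numpy as np
import pandas as pd
import pytest

from transrep.grs import (
    ScoreDefinition,
    base_definition,
    build_score,
    compare_distributions,
    grs_association,
    substitute_leads,
)
from transrep.io import DosageMatrix, LocusCatalogEntry, VariantRecord
from transrep.ld import RegionCall


def _variants(m, freq=0.3):
    return {
        f"v{j}": VariantRecord(
            f"v{j}", "1", 100 + j, "A", "G", freq={"P1": freq, "P2": freq}
        )
        for j in range(m)
    }


def _samples(n, pop="P1"):
    # covariates vary deterministically so adjusted fits stay full-rank
    return pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "population": pop,
            "case": [i % 2 for i in range(n)],
            "age": [55.0 + (i % 13) for i in range(n)],
            "sex": [(i // 2) % 2 for i in range(n)],
            "bmi": [24.0 + (i % 7) for i in range(n)],
        }
    )


def _matrix(data, m):
    data = np.asarray(data, dtype=float)
    return DosageMatrix([f"s{i}" for i in range(data.shape[0])], [f"v{j}" for j in range(m)], data)


def _definition(m, risk="A"):
    return ScoreDefinition([(f"r{j}", f"v{j}", risk) for j in range(m)])


class TestBuildScore:
    def test_all_zero_dosage(self):
        dm = _matrix(np.zeros((3, 4)), 4)
        prof = build_score(dm, _variants(4), _definition(4), _samples(3))
        np.testing.assert_array_equal(prof["score"], 0.0)

    def test_upper_bound_2m(self):
        dm = _matrix(np.full((3, 5), 2.0), 5)
        prof = build_score(dm, _variants(5), _definition(5), _samples(3))
        np.testing.assert_array_equal(prof["score"], 10.0)

    def test_hand_sum_two_snps(self):
        dm = _matrix([[1.0, 2.0]], 2)
        prof = build_score(dm, _variants(2), _definition(2), _samples(1))
        assert prof.loc[0, "score"] == pytest.approx(3.0)

    def test_risk_on_other_allele_flips_dosage(self):
        dm = _matrix([[1.5, 0.5]], 2)
        prof = build_score(dm, _variants(2), _definition(2, risk="G"), _samples(1))
        # risk allele G: contribution is 2 - dosage
        assert prof.loc[0, "score"] == pytest.approx((2 - 1.5) + (2 - 0.5))

    def test_block_missingness_excludes_sample(self):
        data = np.full((4, 6), 1.0)
        data[0, :3] = np.nan  # 3 missing >= threshold
        data[1, 0] = np.nan  # sporadic
        dm = _matrix(data, 6)
        prof = build_score(
            dm, _variants(6), _definition(6), _samples(4), missing_exclude_threshold=3
        )
        assert not prof.loc[0, "included"]
        assert prof.loc[0, "reason"] == "block_missingness"
        assert np.isnan(prof.loc[0, "score"])
        # sporadic missing imputed at 2 * population risk-allele frequency
        assert prof.loc[1, "included"]
        assert prof.loc[1, "score"] == pytest.approx(5 + 2 * 0.3)

    def test_additivity_of_concatenated_definitions(self, rng):
        data = rng.integers(0, 3, size=(10, 6)).astype(float)
        dm = _matrix(data, 6)
        v = _variants(6)
        s = _samples(10)
        d1 = ScoreDefinition([(f"r{j}", f"v{j}", "A") for j in range(3)])
        d2 = ScoreDefinition([(f"r{j}", f"v{j}", "A") for j in range(3, 6)])
        whole = ScoreDefinition(d1.entries + d2.entries)
        np.testing.assert_allclose(
            build_score(dm, v, whole, s)["score"],
            build_score(dm, v, d1, s)["score"] + build_score(dm, v, d2, s)["score"],
        )

    def test_absent_variant_listed_in_error(self):
        dm = _matrix(np.zeros((2, 2)), 2)
        d = ScoreDefinition([("r0", "v0", "A"), ("rX", "v_missing", "A")])
        with pytest.raises(ValueError, match="v_missing"):
            build_score(dm, _variants(2), d, _samples(2))

    def test_permuting_sample_order_leaves_scores_unchanged(self, rng):
        data = rng.integers(0, 3, size=(8, 4)).astype(float)
        dm = _matrix(data, 4)
        s = _samples(8)
        prof = build_score(dm, _variants(4), _definition(4), s)
        perm = rng.permutation(8)
        dm2 = DosageMatrix([f"s{i}" for i in perm], dm.variants, data[perm])
        prof2 = build_score(dm2, _variants(4), _definition(4), s)
        merged = prof.merge(prof2, on="sample", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["score_a"], merged["score_b"])


class TestSubstitution:
    def _catalog(self):
        return [
            LocusCatalogEntry("r0", "v0", "A", 1.2, "1", 1, 1000),
            LocusCatalogEntry("r1", "v1", "A", 1.3, "1", 2000, 3000),
        ]

    def test_no_replication_is_noop(self):
        cat = self._catalog()
        calls = {
            "r0": RegionCall("r0", 2, 0.025, ["v0"], "v0", 0.5, False),
        }
        d = substitute_leads(cat, calls, {}, _variants(2), "modified_I")
        assert d.entries == base_definition(cat).entries
        assert d.mode == "modified_I"

    def test_replicated_region_swaps_lead_and_risk_allele(self):
        cat = self._catalog()
        v = _variants(3)
        calls = {
            "r0": RegionCall("r0", 2, 0.025, ["v0", "v2"], "v2", 0.001, True),
        }
        d = substitute_leads(cat, calls, {"v2": -0.2}, v, "modified_II")
        assert d.entries[0] == ("r0", "v2", "G")  # negative beta -> other allele
        assert d.entries[1] == ("r1", "v1", "A")
        assert "r0" in d.provenance

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            substitute_leads(self._catalog(), {}, {}, _variants(2), "base")


class TestDistributions:
    def test_identical_groups_p_one(self):
        prof = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(8)], "score": [5.0] * 8,
             "n_missing": 0, "included": True}
        )
        summary, hist = compare_distributions(prof, _samples(8))
        row = summary[summary["comparison"] == "P1:case_vs_control"].iloc[0]
        assert np.isnan(row["p"])  # degenerate variance flagged, not crashed
        assert hist["count"].sum() == 8

    def test_separated_groups_tiny_p(self, rng):
        n = 40
        s = _samples(n)
        scores = np.where(s["case"] == 1, 50.0, 10.0) + rng.normal(0, 1, n)
        prof = pd.DataFrame(
            {"sample": s["sample"], "score": scores, "n_missing": 0, "included": True}
        )
        summary, _ = compare_distributions(prof, s)
        row = summary[summary["comparison"] == "P1:case_vs_control"].iloc[0]
        assert row["p"] < 1e-10

    def test_welch_t_matches_closed_form(self, rng):
        n = 60
        s = _samples(n)
        scores = rng.normal(60, 5, n) + 2 * s["case"].to_numpy()
        prof = pd.DataFrame(
            {"sample": s["sample"], "score": scores, "n_missing": 0, "included": True}
        )
        summary, _ = compare_distributions(prof, s)
        row = summary[summary["comparison"] == "P1:case_vs_control"].iloc[0]
        ca = scores[s["case"] == 1]
        co = scores[s["case"] == 0]
        t = (ca.mean() - co.mean()) / np.sqrt(ca.var(ddof=1) / len(ca) + co.var(ddof=1) / len(co))
        from scipy import stats as st

        df = (ca.var(ddof=1) / len(ca) + co.var(ddof=1) / len(co)) ** 2 / (
            (ca.var(ddof=1) / len(ca)) ** 2 / (len(ca) - 1)
            + (co.var(ddof=1) / len(co)) ** 2 / (len(co) - 1)
        )
        expected = 2 * st.t.sf(abs(t), df)
        assert row["p"] == pytest.approx(expected, rel=1e-10)


class TestAssociation:
    def _setup(self, rng, beta_score=0.0, n=2000):
        s = _samples(n)
        score = rng.binomial(2 * 30, 0.35, size=n).astype(float)
        lp = -0.1 + beta_score * score
        s["case"] = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        prof = pd.DataFrame(
            {"sample": s["sample"], "score": score, "n_missing": 0, "included": True}
        )
        pcs = {"P1": pd.DataFrame(np.zeros((n, 0)), index=s["sample"])}
        return prof, s, pcs

    def test_null_continuous_or_near_one(self, rng):
        prof, s, pcs = self._setup(rng, beta_score=0.0)
        res = grs_association(prof, s, pcs)
        row = res[(res["term"] == "continuous")].iloc[0]
        assert row["or"] == pytest.approx(1.0, abs=0.02)

    def test_quartile_one_is_reference(self, rng):
        prof, s, pcs = self._setup(rng, beta_score=0.05)
        res = grs_association(prof, s, pcs)
        q1 = res[res["term"] == "quartile_1"].iloc[0]
        assert q1["or"] == 1.0 and q1["beta"] == 0.0

    def test_effect_recovered(self, rng):
        prof, s, pcs = self._setup(rng, beta_score=np.log(1.05), n=4000)
        res = grs_association(prof, s, pcs)
        row = res[(res["term"] == "continuous")].iloc[0]
        assert np.log(row["or"]) == pytest.approx(np.log(1.05), abs=0.02)
        q4 = res[res["term"] == "quartile_4"].iloc[0]
        assert q4["or"] > 1.0
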