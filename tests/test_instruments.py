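import itertools

import numpy as np
import pandas as pd
import pytest

from mrlipids import instruments as ins
from mrlipids.simulate import SimulationConfig, generate_cohort


def brute_force_slope(g, y):
    g = np.asarray(g, float)
    y = np.asarray(y, float)
    return float(((g - g.mean()) * (y - y.mean())).sum() / ((g - g.mean()) ** 2).sum())


class TestPerSnpBeta:
    def test_constant_outcome_gives_zero_slope(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ins.per_snp_alcohol_beta(g, np.full(6, 3.0)) == pytest.approx(0.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 200)
        y = 0.2 * g + rng.normal(0, 1, 200)
        assert ins.per_snp_alcohol_beta(g, y) == pytest.approx(brute_force_slope(g, y), abs=1e-10)

    def test_constant_dosage_rejected(self):
        with pytest.raises(ValueError):
            ins.per_snp_alcohol_beta(np.ones(50), np.random.default_rng(1).normal(size=50))

    def test_recovers_large_effect_at_scale(self):
        # simulate a strong rare-variant effect and recover it
        rng = np.random.default_rng(7)
        n, beta = 200_000, 0.33
        g = rng.binomial(2, 0.01, n)
        y = beta * g + rng.normal(0, 1.5, n)
        se = 1.5 / (g.std() * np.sqrt(n))
        assert abs(ins.per_snp_alcohol_beta(g, y) - beta) < 3 * se


class TestOrientation:
    def _variant(self):
        return ins.VariantRecord(snp_id="rsX", maf=0.3, raising_allele="A",
                                 functional_class="exonic")

    def test_positive_slope_unchanged(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, 500).astype(float)
        y = 0.3 * g + rng.normal(0, 1, 500)
        oriented, rec = ins.orient_alleles(self._variant(), g, y)
        np.testing.assert_array_equal(oriented, g)
        assert rec.raising_allele == "A"

    def test_flip_is_involution(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 500).astype(float)
        y = 0.3 * g + rng.normal(0, 1, 500)
        flipped_input = 2.0 - g
        oriented, _ = ins.orient_alleles(self._variant(), flipped_input, y)
        np.testing.assert_array_equal(oriented, g)
        # idempotent: orienting an oriented vector changes nothing
        again, _ = ins.orient_alleles(self._variant(), oriented, y)
        np.testing.assert_array_equal(again, oriented)


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1])
        assert ins.ld_r2(g, g) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.3, 50_000)
        b = rng.binomial(2, 0.4, 50_000)
        assert ins.ld_r2(a, b) < 0.001

    def test_copy_with_noise_hits_target(self):
        # replace a fraction f of entries with independent draws:
        # corr = 1 - f, so f = 1 - sqrt(0.96) targets r2 = 0.96
        rng = np.random.default_rng(5)
        n = 40_000
        a = rng.binomial(2, 0.3, n)
        b = a.copy()
        f = 1 - np.sqrt(0.96)
        swap = rng.random(n) < f
        b[swap] = rng.binomial(2, 0.3, swap.sum())
        assert ins.ld_r2(a, b) == pytest.approx(0.96, abs=0.02)

    def test_matches_brute_force_pearson(self):
        a = np.array([0, 1, 2, 2, 1, 0, 1, 2])
        b = np.array([0, 1, 1, 2, 1, 0, 0, 2])
        r = np.corrcoef(a, b)[0, 1]
        assert ins.ld_r2(a, b) == pytest.approx(r * r, abs=1e-12)


def _screening_fixture(seed=0, n=5000):
    """Six candidates: one in near-perfect LD with another (r2 ~ 0.96),
    one correlated with BMI (r ~ 0.15), the rest clean."""
    rng = np.random.default_rng(seed)
    dosages = pd.DataFrame({
        "rsA": rng.binomial(2, 0.3, n),
        "rsB": rng.binomial(2, 0.2, n),
        "rsC": rng.binomial(2, 0.4, n),
        "rsD": rng.binomial(2, 0.25, n),
    })
    # rsE duplicates rsA with a little noise -> r2 ~ 0.96
    e = dosages["rsA"].to_numpy().copy()
    swap = rng.random(n) < (1 - np.sqrt(0.96))
    e[swap] = rng.binomial(2, 0.3, swap.sum())
    dosages["rsE"] = e
    # rsF correlated with BMI at r ~ 0.15
    f = rng.binomial(2, 0.3, n)
    dosages["rsF"] = f
    sd_g = f.std()
    bmi = 27 + 0.15 * 4.9 * (f - f.mean()) / sd_g + np.sqrt(1 - 0.15**2) * rng.normal(0, 4.9, n)
    confounders = pd.DataFrame({
        "smoking": rng.integers(0, 3, n),
        "bmi": bmi,
        "whr": rng.normal(0.9, 0.1, n),
        "diabetes": rng.binomial(1, 0.09, n),
    })
    candidates = [
        ins.VariantRecord("rsA", maf=0.3, functional_class="exonic", source_sample_size=10_000),
        ins.VariantRecord("rsB", maf=0.2, functional_class="intronic", source_sample_size=20_000),
        ins.VariantRecord("rsC", maf=0.4, functional_class="exonic", source_sample_size=5_000),
        ins.VariantRecord("rsD", maf=0.25, functional_class="intergenic", source_sample_size=50_000),
        ins.VariantRecord("rsE", maf=0.3, functional_class="intronic", source_sample_size=90_000),
        ins.VariantRecord("rsF", maf=0.3, functional_class="exonic", source_sample_size=30_000),
    ]
    return candidates, dosages, confounders


class TestScreening:
    def test_clean_candidates_all_pass(self):
        rng = np.random.default_rng(10)
        n = 4000
        dosages = pd.DataFrame({f"rs{i}": rng.binomial(2, 0.3, n) for i in range(5)})
        conf = pd.DataFrame({
            "smoking": rng.integers(0, 3, n), "bmi": rng.normal(27, 5, n),
            "whr": rng.normal(0.9, 0.1, n), "diabetes": rng.binomial(1, 0.1, n),
        })
        cands = [ins.VariantRecord(f"rs{i}", maf=0.3) for i in range(5)]
        report, survivors = ins.screen_candidates(cands, dosages, None, conf)
        assert [v.snp_id for v in survivors] == [f"rs{i}" for i in range(5)]
        assert all(d.reason == "pass" for d in report.decisions)

    def test_planted_failures_detected(self):
        candidates, dosages, conf = _screening_fixture()
        report, survivors = ins.screen_candidates(candidates, dosages, None, conf)
        reasons = {d.snp_id: d.reason for d in report.decisions}
        assert reasons["rsF"] == "fail_confounder_corr"
        # rsA (exonic) is kept over its high-LD copy rsE (intronic)
        assert reasons["rsA"] == "pass"
        assert reasons["rsE"] == "pruned_pairwise"
        assert {v.snp_id for v in survivors} == {"rsA", "rsB", "rsC", "rsD"}

    def test_lipid_locus_ld_fails(self):
        candidates, dosages, conf = _screening_fixture(seed=3)
        lipid_loci = pd.DataFrame({"lipid_locus_1": dosages["rsB"]})
        report, survivors = ins.screen_candidates(candidates, dosages, lipid_loci, conf)
        reasons = {d.snp_id: d.reason for d in report.decisions}
        assert reasons["rsB"] == "fail_ld_lipid_locus"
        assert "rsB" not in {v.snp_id for v in survivors}

    def test_duplicated_snp_resolved_by_functional_class(self):
        rng = np.random.default_rng(11)
        n = 2000
        g = rng.binomial(2, 0.3, n)
        dosages = pd.DataFrame({"rsP": g, "rsQ": g})
        conf = pd.DataFrame({
            "smoking": rng.integers(0, 3, n), "bmi": rng.normal(27, 5, n),
            "whr": rng.normal(0.9, 0.1, n), "diabetes": rng.binomial(1, 0.1, n),
        })
        cands = [ins.VariantRecord("rsP", maf=0.3, functional_class="intergenic"),
                 ins.VariantRecord("rsQ", maf=0.3, functional_class="exonic")]
        report, survivors = ins.screen_candidates(cands, dosages, None, conf)
        assert [v.snp_id for v in survivors] == ["rsQ"]

    def test_order_invariance(self):
        candidates, dosages, conf = _screening_fixture(seed=1)
        _, baseline = ins.screen_candidates(candidates, dosages, None, conf)
        base_ids = {v.snp_id for v in baseline}
        for perm in itertools.islice(itertools.permutations(candidates), 0, 720, 97):
            _, survivors = ins.screen_candidates(list(perm), dosages, None, conf)
            assert {v.snp_id for v in survivors} == base_ids

    def test_every_candidate_decided_exactly_once(self):
        candidates, dosages, conf = _screening_fixture(seed=2)
        report, _ = ins.screen_candidates(candidates, dosages, None, conf)
        assert sorted(d.snp_id for d in report.decisions) == sorted(v.snp_id for v in candidates)

    def test_empty_candidates_and_missing_confounder_column(self):
        _, dosages, conf = _screening_fixture()
        with pytest.raises(ValueError):
            ins.screen_candidates([], dosages, None, conf)
        with pytest.raises(KeyError):
            ins.screen_candidates(
                [ins.VariantRecord("rsA", maf=0.3)], dosages, None, conf.drop(columns=["bmi"]))


class TestScore:
    def test_bounds_and_extremes(self):
        dosages = pd.DataFrame(np.zeros((4, 5)), columns=list("abcde"))
        survivors = [ins.VariantRecord(s, maf=0.3) for s in "abcde"]
        score = ins.build_score(dosages, survivors)
        assert (score.values == 0).all()
        score2 = ins.build_score(dosages + 2.0, survivors)
        assert (score2.values == 10).all()
        assert score2.max_value == 10

    def test_missing_dosage_gives_missing_score(self):
        dosages = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 1.0]})
        survivors = [ins.VariantRecord(s, maf=0.3) for s in "ab"]
        score = ins.build_score(dosages, survivors)
        assert score.values.iloc[0] == 3.0
        assert np.isnan(score.values.iloc[1])

    def test_empty_survivor_set_rejected(self):
        with pytest.raises(ValueError):
            ins.build_score(pd.DataFrame({"a": [1.0]}), [])

    def test_score_variance_matches_binomial_sum(self):
        cfg = SimulationConfig(n_individuals=50_000, seed=21)
        cohort, _ = generate_cohort(cfg)
        score = cohort[list(cfg.snp_ids)].sum(axis=1)
        expected = sum(2 * p * (1 - p) for p in cfg.snp_mafs)
        assert score.var() == pytest.approx(expected, rel=0.05)

    def test_score_alcohol_slope_positive_order_of_per_snp_effects(self, scored_cohort):
        slope = ins.per_snp_alcohol_beta(
            scored_cohort["score_unweighted"], scored_cohort["derived_log_alcohol"])
        assert 0.0 < slope < 0.3
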