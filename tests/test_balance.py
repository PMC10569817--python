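"""Undersampling candidate scoring, best-of-M selection, strata, SMOTE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortbalance import (
    BalanceError,
    class_counts,
    score_candidate,
    select_balanced_undersample,
    smote_oversample,
    stratified_undersample,
)
from cohortbalance.balance import _candidate_rngs
from conftest import make_cohort


# ---------------------------------------------------------------------------
# Independent oracles (distinct computation routes from the implementation)
# ---------------------------------------------------------------------------

def chi2_gof_oracle(observed, expected):
    """Hand-computed Pearson GOF statistic + chi2 survival function."""
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return stat, float(stats.chi2.sf(stat, df=len(observed) - 1))


def ks_2samp_oracle(x, y):
    """Brute-force ECDF double loop for D, finite-n Kolmogorov sf for p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = 0.0
    for t in np.concatenate([x, y]):
        d = max(d, abs(np.mean(x <= t) - np.mean(y <= t)))
    n, m = len(x), len(y)
    en = n * m / (n + m)
    return d, float(stats.kstwo.sf(d, int(np.round(en))))


def score_oracle(candidate_df, population_df, cohort, variables):
    """Re-score a candidate from first principles."""
    total = 0.0
    for name in variables:
        var = cohort.variable(name)
        if var.kind == "categorical":
            obs = [int((candidate_df[name] == l).sum()) for l in var.levels]
            pop = [int((population_df[name] == l).sum()) for l in var.levels]
            exp = [p / sum(pop) * sum(obs) for p in pop]
            total += chi2_gof_oracle(obs, exp)[1]
        else:
            total += ks_2samp_oracle(candidate_df[name], population_df[name])[1]
    return total


def _imbalanced_cohort(n=400, event_frac=0.1, seed=0):
    rng = np.random.default_rng(seed)
    n_event = int(n * event_frac)
    return make_cohort(
        {
            "age": rng.normal(66, 7, n),
            "bmi": rng.normal(28, 5, n),
            "sex": list(rng.choice(["M", "F"], n)),
            "smk": list(rng.choice(["No", "Yes"], n, p=[0.9, 0.1])),
            "event": ["Yes"] * n_event + ["No"] * (n - n_event),
        }
    )


class TestScoreCandidate:
    def test_whole_population_scores_p_one_per_categorical(self):
        cohort = _imbalanced_cohort()
        maj = cohort.records[cohort.records["event"] == "No"]
        cand = score_candidate(maj, maj, cohort, ["sex", "smk", "age"])
        assert cand.pvalues["sex"] == pytest.approx(1.0)
        assert cand.pvalues["smk"] == pytest.approx(1.0)
        assert cand.pvalues["age"] == pytest.approx(1.0)  # identical samples
        assert cand.score == pytest.approx(sum(cand.pvalues.values()))

    def test_exact_expected_counts_give_chi2_zero(self):
        # population proportions (0.9, 0.1); candidate counts (45, 5)
        pop = make_cohort(
            {"v": ["a"] * 900 + ["b"] * 100, "event": ["No"] * 999 + ["Yes"]}
        )
        maj = pop.records[pop.records["event"] == "No"]
        cand_rows = pd.concat(
            [maj[maj["v"] == "a"].head(45), maj[maj["v"] == "b"].head(5)]
        )
        cand = score_candidate(cand_rows, pop.records, pop, ["v"])
        assert cand.pvalues["v"] == pytest.approx(1.0, abs=1e-12)

    def test_ks_route_matches_brute_force_oracle(self, rng):
        x = rng.normal(0, 1, 200)
        y = rng.normal(0.15, 1.1, 2000)
        d_ref, p_ref = ks_2samp_oracle(x, y)
        d, p = stats.ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(d_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-8)

    def test_empty_candidate_rejected(self):
        cohort = _imbalanced_cohort()
        maj = cohort.records[cohort.records["event"] == "No"]
        with pytest.raises(BalanceError, match="empty"):
            score_candidate(maj.iloc[:0], maj, cohort, ["sex"])

    def test_pvalues_match_reference_on_random_fixtures(self, rng):
        """chi2 GOF and KS p-values agree with independent routes to 1e-8."""
        for _ in range(100):
            n_cand = int(rng.integers(30, 120))
            n_pop = int(rng.integers(300, 1200))
            pop_df = pd.DataFrame(
                {
                    "cat": rng.choice(["a", "b", "c"], n_pop, p=[0.5, 0.3, 0.2]),
                    "num": rng.normal(rng.normal(), 1 + rng.random(), n_pop),
                }
            )
            pos = rng.choice(n_pop, n_cand, replace=False)
            cand_df = pop_df.iloc[pos]
            cohort = make_cohort(
                {
                    "cat": list(pop_df["cat"]),
                    "num": pop_df["num"].to_numpy(),
                    "event": ["Yes"] + ["No"] * (n_pop - 1),
                }
            )
            cand = score_candidate(cand_df, pop_df, cohort, ["cat", "num"])
            obs = [int((cand_df["cat"] == l).sum()) for l in ("a", "b", "c")]
            popc = [int((pop_df["cat"] == l).sum()) for l in ("a", "b", "c")]
            exp = [p / sum(popc) * sum(obs) for p in popc]
            assert cand.pvalues["cat"] == pytest.approx(chi2_gof_oracle(obs, exp)[1], abs=1e-8)
            assert cand.pvalues["num"] == pytest.approx(
                ks_2samp_oracle(cand_df["num"], pop_df["num"])[1], abs=1e-8
            )


class TestSelectBalancedUndersample:
    def test_m_one_returns_single_candidate(self):
        cohort = _imbalanced_cohort()
        res = select_balanced_undersample(cohort, m=1, seed=5)
        assert res.n_candidates == 1
        assert len(res.candidate_scores) == 1
        assert res.selected.score == res.candidate_scores[0]

    def test_balanced_output_size_and_classes(self):
        cohort = _imbalanced_cohort(n=500, event_frac=0.08)
        res = select_balanced_undersample(cohort, m=3, seed=0)
        n_maj, n_min, _ = class_counts(cohort)
        assert res.balanced.n == 2 * n_min
        assert class_counts(res.balanced)[:2] == (n_min, n_min)

    def test_selected_is_exhaustive_max_by_independent_rescoring(self):
        cohort = _imbalanced_cohort(n=500, event_frac=0.08, seed=3)
        m, seed = 20, 9
        res = select_balanced_undersample(cohort, m=m, seed=seed)
        maj = cohort.records[cohort.records["event"] == "No"].reset_index(drop=True)
        variables = ["age", "bmi", "sex", "smk"]
        n_min = class_counts(cohort)[1]
        oracle_scores = []
        for rng_c in _candidate_rngs(seed, m):
            pos = rng_c.choice(len(maj), size=n_min, replace=False)
            oracle_scores.append(score_oracle(maj.iloc[pos], maj, cohort, variables))
        assert res.selected.score == pytest.approx(max(oracle_scores), abs=1e-8)
        assert all(res.selected.score >= s - 1e-8 for s in oracle_scores)

    def test_reproducible_bit_exact(self):
        cohort = _imbalanced_cohort(seed=4)
        a = select_balanced_undersample(cohort, m=5, seed=42)
        b = select_balanced_undersample(cohort, m=5, seed=42)
        pd.testing.assert_frame_equal(a.balanced.records, b.balanced.records)
        assert a.selected.score == b.selected.score
        assert np.array_equal(a.selected.row_indices, b.selected.row_indices)

    def test_undersampling_uses_only_real_rows(self):
        cohort = _imbalanced_cohort(seed=2)
        res = select_balanced_undersample(cohort, m=2, seed=1)
        maj = cohort.records[cohort.records["event"] == "No"]
        sampled = res.balanced.records[res.balanced.records["event"] == "No"]
        merged = sampled.merge(maj.drop_duplicates(), how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_minority_larger_than_majority_is_error(self):
        cohort = make_cohort({"x": [1.0] * 10, "event": ["Yes"] * 7 + ["No"] * 3})
        with pytest.raises(BalanceError):
            select_balanced_undersample(cohort, m=1, seed=0)

    def test_best_of_many_stochastically_dominates_m_one(self):
        """Mean selected score with m=100 >= with m=1 over 50 replicates."""
        cohort = _imbalanced_cohort(n=500, event_frac=0.06, seed=6)
        variables = ["age", "bmi", "sex", "smk"]
        s100, s1 = [], []
        for rep in range(50):
            s100.append(
                select_balanced_undersample(cohort, m=100, variables=variables, seed=rep).selected.score
            )
            s1.append(
                select_balanced_undersample(cohort, m=1, variables=variables, seed=rep).selected.score
            )
        assert np.mean(s100) >= np.mean(s1)


class TestStratifiedUndersample:
    def _strata_cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 600
        n_event = 40
        return make_cohort(
            {
                "age_band": list(rng.choice(["young", "old"], n, p=[0.45, 0.55])),
                "sex": list(rng.choice(["M", "F"], n)),
                "bmi": rng.normal(28, 5, n),
                "event": ["Yes"] * n_event + ["No"] * (n - n_event),
            }
        )

    def test_quotas_match_minority_exactly(self):
        cohort = self._strata_cohort()
        res = stratified_undersample(cohort, ["age_band", "sex"], m=4, seed=1)
        bal = res.balanced.records
        minority = bal[bal["event"] == "Yes"]
        sampled = bal[bal["event"] == "No"]
        tab_min = minority.groupby(["age_band", "sex"]).size()
        tab_smp = sampled.groupby(["age_band", "sex"]).size()
        pd.testing.assert_series_equal(tab_min, tab_smp, check_names=False)

    def test_strata_chi2_statistic_is_zero(self):
        cohort = self._strata_cohort(seed=1)
        res = stratified_undersample(cohort, ["age_band", "sex"], m=2, seed=2)
        bal = res.balanced.records
        tab = pd.crosstab(
            bal["event"], bal["age_band"] + "/" + bal["sex"]
        ).to_numpy()
        chi2 = stats.chi2_contingency(tab, correction=False)[0]
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_selected_beats_all_candidates_by_oracle(self):
        cohort = self._strata_cohort(seed=2)
        res = stratified_undersample(cohort, ["age_band", "sex"], m=10, seed=3)
        assert res.selected.score == pytest.approx(max(res.candidate_scores), abs=1e-12)
        # stratum variables are excluded from scoring
        assert set(res.selected.pvalues) == {"bmi"}

    def test_insufficient_stratum_is_error_naming_stratum(self):
        cohort = make_cohort(
            {
                "g": ["a"] * 5 + ["b"] * 5,
                "event": ["Yes", "Yes", "Yes", "No", "No"] + ["No"] * 5,
            }
        )
        with pytest.raises(BalanceError, match="stratum"):
            stratified_undersample(cohort, ["g"], m=1, seed=0)


class TestSmote:
    def test_identical_minority_points_reproduce_themselves(self):
        cohort = make_cohort(
            {
                "x": [1.0, 1.0] + [0.0] * 8,
                "y": [2.0, 2.0] + [5.0] * 8,
                "event": ["Yes", "Yes"] + ["No"] * 8,
            }
        )
        res = smote_oversample(cohort, k=1, seed=0)
        synth = res.balanced.records.iloc[10:]
        assert (synth["x"] == 1.0).all() and (synth["y"] == 2.0).all()

    def test_two_point_segment_convexity(self):
        cohort = make_cohort(
            {
                "x": [0.0, 1.0] + [10.0] * 12,
                "y": [0.0, 1.0] + [-5.0] * 12,
                "event": ["Yes", "Yes"] + ["No"] * 12,
            }
        )
        res = smote_oversample(cohort, k=1, seed=1)
        synth = res.balanced.records.iloc[14:]
        assert np.allclose(synth["x"], synth["y"], atol=1e-12)
        assert ((synth["x"] >= 0) & (synth["x"] <= 1)).all()

    def test_parent_tracking_segment_oracle(self, rng):
        """Each synthetic point lies on the segment between its parents."""
        n_min, n_maj = 200, 500
        df = {
            "a": np.concatenate([rng.normal(0, 1, n_min), rng.normal(2, 1, n_maj)]),
            "b": np.concatenate([rng.normal(0, 1, n_min), rng.normal(2, 1, n_maj)]),
            "c": np.concatenate([rng.normal(0, 1, n_min), rng.normal(2, 1, n_maj)]),
            "event": ["Yes"] * n_min + ["No"] * n_maj,
        }
        cohort = make_cohort(df)
        res = smote_oversample(cohort, k=5, seed=2)
        Z = res.encoded_minority
        for z, (i, j, lam) in zip(res.synthetic_encoded, res.synthetic_parents):
            pi, pj = Z[int(i)], Z[int(j)]
            d = np.linalg.norm(pi - z) + np.linalg.norm(z - pj) - np.linalg.norm(pi - pj)
            assert abs(d) < 1e-10

    def test_output_balanced_and_k_validation(self):
        cohort = make_cohort(
            {"x": [0.0, 1.0, 2.0] + [5.0] * 9, "event": ["Yes"] * 3 + ["No"] * 9}
        )
        res = smote_oversample(cohort, k=2, seed=0)
        n_maj, n_min, _ = class_counts(res.balanced)
        assert n_maj == n_min == 9
        with pytest.raises(BalanceError):
            smote_oversample(cohort, k=3, seed=0)
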