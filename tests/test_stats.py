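"""ANOVA, Tukey, permutation multivariate test, correlations, stepwise MLR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adlkin.errors import ValidationError
from adlkin.features import PARAMETERS
from adlkin.stats import (
    build_cohort_table,
    cohen_d,
    inter_task_correlation,
    multivariate_group_test,
    one_way_anova,
    pooled_mean,
    stepwise_mlr,
    task_average,
    tukey_posthoc,
)


def make_table(rng, n=27, effect=None):
    """Feature table with Gaussian parameters; `effect` shifts a column by group."""
    groups = np.array(["R"] * 8 + ["P"] * 13 + ["F"] * 6)[:n]
    table = pd.DataFrame({"group": groups, "fried_score": rng.integers(0, 6, n)})
    for p in PARAMETERS:
        for suffix in ("TEA", "GARDEN", "avg"):
            table[f"{p}_{suffix}"] = rng.normal(size=n)
    if effect:
        shift = {"R": 0.0, "P": 1.0, "F": 2.0}
        for col, size in effect.items():
            table[col] += size * np.vectorize(shift.get)(groups)
    return table


class TestAnova:
    def test_textbook_hand_computation(self):
        # groups [1,2,3], [2,3,4], [6,7,8]: SSB=42/df2, SSW=6/df6 -> F=21
        values = np.array([1, 2, 3, 2, 3, 4, 6, 7, 8], float)
        groups = np.repeat(["a", "b", "c"], 3)
        gc = one_way_anova(values, groups)
        assert gc.F == pytest.approx(21.0, abs=1e-9)
        assert gc.p == pytest.approx(0.001953125, abs=1e-9)
        assert gc.eta2p == pytest.approx(42 / 48, abs=1e-12)
        assert gc.df == (2, 6)

    def test_matches_scipy_on_random_data(self, rng):
        values = rng.normal(size=30)
        groups = rng.choice(["a", "b", "c"], size=30)
        gc = one_way_anova(values, groups)
        F, p = sps.f_oneway(*(values[groups == g] for g in "abc"))
        assert gc.F == pytest.approx(F, rel=1e-12)
        assert gc.p == pytest.approx(p, rel=1e-12)

    def test_separated_groups_eta_is_one(self):
        gc = one_way_anova([1, 1, 2, 2], ["a", "a", "b", "b"])
        assert gc.eta2p == 1.0
        assert gc.p == 0.0

    def test_constant_data_f_is_zero(self):
        gc = one_way_anova([3, 3, 3, 3], ["a", "a", "b", "b"])
        assert gc.F == 0.0
        assert gc.eta2p == 0.0

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_eta2p_invariant_under_affine_response(self, rng):
        values = rng.normal(size=24)
        groups = rng.choice(["a", "b", "c"], size=24)
        g1 = one_way_anova(values, groups)
        g2 = one_way_anova(5.0 - 3.0 * values, groups)
        assert g2.eta2p == pytest.approx(g1.eta2p, rel=1e-12)
        assert g2.F == pytest.approx(g1.F, rel=1e-12)


class TestTukey:
    def test_one_pooled_sd_difference(self):
        x = np.array([0.0, 1.0, 2.0])
        y = x + 1.0
        assert abs(cohen_d(x, y)) == pytest.approx(1.0)

    def test_identical_groups_p_near_one(self, rng):
        base = rng.normal(size=8)
        values = np.concatenate([base, base])
        groups = np.repeat(["R", "P"], 8)
        posthoc = tukey_posthoc(values, groups)
        assert posthoc[0][1] == pytest.approx(1.0, abs=1e-6)

    def test_matches_studentized_range_oracle(self, rng):
        values = rng.normal(size=27) + np.repeat([0.0, 0.8, 1.6], 9)
        groups = np.repeat(["R", "P", "F"], 9)
        posthoc = {pair: p for pair, p, _ in tukey_posthoc(values, groups)}
        # independent recomputation from the studentized range distribution
        samples = {g: values[groups == g] for g in ("R", "P", "F")}
        dfw = 27 - 3
        msw = sum(((s - s.mean()) ** 2).sum() for s in samples.values()) / dfw
        for a, b in (("R", "P"), ("R", "F"), ("P", "F")):
            sa, sb = samples[a], samples[b]
            q = abs(sa.mean() - sb.mean()) / np.sqrt(
                msw / 2 * (1 / sa.size + 1 / sb.size)
            )
            p_oracle = sps.studentized_range.sf(q, 3, dfw)
            assert posthoc[f"{a}-{b}"] == pytest.approx(p_oracle, abs=1e-6)


class TestMultivariate:
    def test_zero_permutations_rejected(self, rng):
        with pytest.raises(ValidationError):
            multivariate_group_test(make_table(rng), n_perm=0)

    def test_few_permutations_warn(self, rng):
        with pytest.warns(UserWarning):
            multivariate_group_test(make_table(rng), n_perm=50, seed=0)

    def test_null_p_is_not_extreme(self, rng):
        table = make_table(rng)
        _, p = multivariate_group_test(table, n_perm=500, seed=1)
        assert 0.001 < p

    def test_planted_effect_detected(self, rng):
        table = make_table(
            rng, effect={"STD_avg": 1.5, "MPA_avg": 1.5, "PPS_avg": 1.5}
        )
        _, p = multivariate_group_test(table, n_perm=2000, seed=2)
        assert p < 0.01

    def test_reproducible_under_seed(self, rng):
        table = make_table(rng)
        r1 = multivariate_group_test(table, n_perm=300, seed=7)
        r2 = multivariate_group_test(table, n_perm=300, seed=7)
        assert r1 == r2


class TestCorrelation:
    def _table(self, x, y):
        df = pd.DataFrame({"TD_TEA": x, "TD_GARDEN": y})
        return df

    def test_identical_columns(self, rng):
        x = rng.normal(size=10)
        r = inter_task_correlation(self._table(x, x), "TD")
        assert r.r == pytest.approx(1.0)

    def test_negated_column(self, rng):
        x = rng.normal(size=10)
        r = inter_task_correlation(self._table(x, -x), "TD")
        assert r.r == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        r = inter_task_correlation(self._table([1, 2, 3], [5, 5, 5]), "TD")
        assert np.isnan(r.r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            inter_task_correlation(self._table([1, 2], [3, 4]), "TD")

    def test_bivariate_normal_recovery(self, rng):
        rho, n, reps = 0.6, 27, 1000
        cov = [[1, rho], [rho, 1]]
        rs = []
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            r = inter_task_correlation(self._table(xy[:, 0], xy[:, 1]), "TD")
            rs.append(r.r)
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)


class TestStepwise:
    def test_single_true_predictor_recovered(self, rng):
        table = make_table(rng)
        table["fried_score"] = 2.0 * table["STD_avg"] + rng.normal(0, 0.05, len(table))
        model = stepwise_mlr(table, scope="task_average")
        assert "STD" in model.selected
        assert model.R2 > 0.95

    def test_no_signal_often_empty_and_never_crashes(self, rng):
        table = make_table(rng)
        model = stepwise_mlr(table, scope="task_average")
        assert model.R2 >= 0.0  # may be empty or a small false entry

    def test_null_false_entry_rate_matches_familywise_expectation(self, rng):
        # with 9 independent noise predictors the chance that the first
        # forward step enters anything is 1 - 0.95^9 ~ 0.37
        reps, entered = 250, 0
        for _ in range(reps):
            table = make_table(rng)
            table["fried_score"] = rng.normal(size=len(table))
            model = stepwise_mlr(table, scope="task_average")
            entered += bool(model.selected)
        expected = 1 - 0.95**9
        assert entered / reps == pytest.approx(expected, abs=0.09)

    def test_std_signal_yields_negative_beta(self, rng):
        # cohorts in which peak-height variability (STD) alone tracks
        # frailty produce a retained STD with negative standardized weight
        table = make_table(rng)
        y = table["fried_score"].astype(float)
        table["STD_avg"] = -0.6 * (y - y.mean()) / y.std() + rng.normal(0, 0.5, len(y))
        model = stepwise_mlr(table, scope="task_average")
        assert model.selected == ["STD"]
        assert model.beta_std["STD"] < 0
        assert all(v < 5.0 for v in model.vif.values())

    def test_collinear_predictor_excluded_by_vif(self, rng):
        table = make_table(rng)
        y = rng.normal(size=len(table))
        table["fried_score"] = y
        table["STD_avg"] = y + rng.normal(0, 0.3, len(y))
        # make MPA a near-copy of STD: must not join STD in the model
        table["MPA_avg"] = table["STD_avg"] + rng.normal(0, 0.05, len(y))
        model = stepwise_mlr(table, scope="task_average")
        assert not {"STD", "MPA"} <= set(model.selected)
        assert all(v < 5.0 for v in model.vif.values())


class TestTableOps:
    def test_task_average_arithmetic(self, rng):
        table = make_table(rng, n=4)
        table.loc[0, "TD_TEA"], table.loc[0, "TD_GARDEN"] = 137.0, 96.0
        out = task_average(table)
        assert out.loc[0, "TD_avg"] == pytest.approx(116.5)

    def test_missing_task_flagged(self, rng):
        table = make_table(rng, n=5)
        table.loc[2, "RA_GARDEN"] = np.nan
        out = task_average(table)
        assert not out.loc[2, "complete"]
        assert np.isnan(out.loc[2, "RA_avg"])
        assert out["complete"].sum() == 4

    def test_build_cohort_table_rejects_duplicates(self):
        feats = pd.DataFrame(
            {
                "participant_id": ["a", "a"],
                "task": ["TEA", "TEA"],
                **{p: [1.0, 2.0] for p in PARAMETERS},
            }
        )
        manifest = pd.DataFrame(
            {"participant_id": ["a"], "group": ["R"], "fried_score": [0]}
        )
        with pytest.raises(ValidationError):
            build_cohort_table(feats, manifest)

    def test_pooled_mean(self):
        assert pooled_mean([1.0, 3.0], [1, 1]) == 2.0
        assert pooled_mean([78.4, 79.8, 89.8], [8, 13, 6]) == pytest.approx(81.6, abs=0.05)
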