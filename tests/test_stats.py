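import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sst

from hdsemg.stats import (
    anova_two_way_within,
    mann_whitney,
    normality_gate,
    pearson_correlation,
)


def r_oracle_fixture() -> pd.DataFrame:
    """Deterministic balanced 2x2x(3 levels) design with a sex shift and a
    level trend; oracle F/p values frozen from R `aov` with
    Error(subject/level) on this exact table."""
    rng = np.random.default_rng(42)
    rows, sid = [], 0
    for age in ["older", "young"]:
        for sex in ["female", "male"]:
            for _ in range(4):
                sid += 1
                base = rng.normal(0, 1)
                for i, lvl in enumerate([25, 50, 75]):
                    rows.append(
                        {"subject": f"S{sid:02d}", "age_group": age, "sex": sex,
                         "level": lvl, "feature": "f",
                         "value": base + 0.5 * i + rng.normal(0, 0.5)
                         + (0.8 if sex == "male" else 0)}
                    )
    return pd.DataFrame(rows)


# F and p per effect from R 4.3.3: summary(aov(value ~ age_group*sex*level
# + Error(subject/level))) on r_oracle_fixture().
R_ORACLE = {
    "age_group": (0.10041, 0.75679),
    "sex": (2.19613, 0.16414),
    "age_group:sex": (1.79620, 0.20500),
    "level": (46.48387, 5.5685e-09),
    "age_group:level": (5.01320, 0.015161),
    "sex:level": (0.47034, 0.630426),
    "age_group:sex:level": (0.69211, 0.510231),
}


class TestNormalityGate:
    def test_normal_samples_route_parametric_in_most_seeds(self):
        hits = 0
        seeds = range(50)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {"age_group": "young", "sex": "male", "level": 50,
                 "feature": "f", "value": rng.standard_normal(10)}
            )
            hits += normality_gate(table, "f").route == "parametric"
        assert hits >= 0.9 * len(seeds)

    def test_two_point_mixture_routes_nonparametric(self):
        table = pd.DataFrame(
            {"age_group": "young", "sex": "male", "level": 50, "feature": "f",
             "value": [0.0, 10.0] * 6}
        )
        assert normality_gate(table, "f").route == "nonparametric"

    def test_small_cell_flagged_and_nonparametric(self):
        table = pd.DataFrame(
            {"age_group": ["young"] * 2, "sex": "male", "level": 50,
             "feature": "f", "value": [1.0, 2.0]}
        )
        gate = normality_gate(table, "f")
        assert gate.route == "nonparametric"
        assert gate.cells.flagged.all()

    def test_gate_is_per_cell(self):
        rng = np.random.default_rng(0)
        rows = []
        for sex, values in [("male", rng.standard_normal(10)),
                            ("female", np.repeat([0.0, 50.0], 5))]:
            for v in values:
                rows.append({"age_group": "young", "sex": sex, "level": 50,
                             "feature": "f", "value": v})
        gate = normality_gate(pd.DataFrame(rows), "f")
        assert gate.route == "nonparametric"
        assert gate.cells.normal.sum() == 1


class TestSplitPlotAnova:
    def test_matches_r_aov_oracle(self):
        res = anova_two_way_within(r_oracle_fixture(), "f")
        eff = res.effects.set_index("effect")
        for name, (F, p) in R_ORACLE.items():
            assert eff.loc[name, "F"] == pytest.approx(F, rel=1e-4), name
            assert eff.loc[name, "p"] == pytest.approx(p, rel=1e-3), name

    def test_gg_epsilon_bounds(self):
        res = anova_two_way_within(r_oracle_fixture(), "f")
        assert 1.0 / 2 <= res.epsilon_gg <= 1.0
        gg = res.effects.dropna(subset=["p_gg"])
        gg = gg[gg["F"] >= 1.0]  # shrinking both dfs is conservative only for F > 1
        assert (gg["p_gg"] >= gg["p"] - 1e-12).all()

    def test_missing_cell_named_in_error(self):
        df = r_oracle_fixture()
        df = df[~((df.subject == "S01") & (df.level == 75))]
        with pytest.raises(ValueError, match="S01"):
            anova_two_way_within(df, "f")

    def test_single_level_degenerates_to_between_anova(self):
        df = r_oracle_fixture()
        res = anova_two_way_within(df[df.level == 25], "f")
        assert res.within_degenerate
        assert set(res.effects.effect) == {"age_group", "sex", "age_group:sex"}

    def test_posthoc_family_on_injected_interaction(self):
        """A sex effect present only in the young group produces an
        age-by-sex interaction; the focused per-level comparisons form one
        Bonferroni family whose size is emitted."""
        rng = np.random.default_rng(7)
        rows, sid = [], 0
        for age in ["older", "young"]:
            for sex in ["female", "male"]:
                shift = 3.0 if (age == "young" and sex == "male") else 0.0
                for _ in range(6):
                    sid += 1
                    for lvl in [25, 50]:
                        rows.append({"subject": sid, "age_group": age, "sex": sex,
                                     "level": lvl, "feature": "f",
                                     "value": shift + rng.standard_normal()})
        res = anova_two_way_within(pd.DataFrame(rows), "f")
        assert res.p("age_group:sex") < 0.05
        ph = res.posthoc
        assert ph is not None
        assert (ph.m == len(ph)).all() and len(ph) == 2 * 4  # 2 levels x 4 comparisons
        assert (ph.p_bonferroni >= ph.p - 1e-15).all() and (ph.p_bonferroni <= 1).all()
        young_ms = ph[(ph.fixed == "age_group=young")]
        assert (young_ms.p_bonferroni < 0.05).all()

    def test_injected_sex_effect_power_matches_analytic(self):
        """Simulated detection rate of a between-subject sex shift agrees
        with the noncentral-F power calculation within 10 points."""
        delta, sig_s, sig_e, n, w = 1.0, 1.0, 0.5, 8, 2
        rng = np.random.default_rng(2024)
        hits, reps = 0, 200
        for _ in range(reps):
            rows, sid = [], 0
            for age in ["o", "y"]:
                for sex in ["f", "m"]:
                    eff = delta / 2 if sex == "m" else -delta / 2
                    for _ in range(n):
                        sid += 1
                        b = rng.normal(0, sig_s)
                        for wi in range(w):
                            rows.append({"subject": sid, "age_group": age, "sex": sex,
                                         "level": wi, "feature": "f",
                                         "value": eff + b + rng.normal(0, sig_e)})
            res = anova_two_way_within(pd.DataFrame(rows), posthoc=False)
            hits += res.p("sex") < 0.05
        subj_var = sig_s**2 + sig_e**2 / w
        lam = 2 * n * delta**2 / (2 * subj_var)
        crit = sst.f.isf(0.05, 1, 4 * (n - 1))
        analytic = sst.ncf.sf(crit, 1, 4 * (n - 1), lam)
        assert hits / reps == pytest.approx(analytic, abs=0.10)


def exact_two_sided_mw_p(x, y):
    """Enumeration oracle: exact two-sided Mann-Whitney p by listing every
    assignment of the pooled ranks to the first group."""
    pooled = sorted(x) + sorted(y)
    n1 = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    n1n2 = len(x) * len(y)
    dev = abs(u_obs - n1n2 / 2)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = sum(1 for xi in gx for yi in gy if xi > yi)
        total += 1
        count += abs(u - n1n2 / 2) >= dev - 1e-12
    return count / total


class TestMannWhitney:
    def test_exact_small_sample_matches_enumeration(self):
        x, y = [1, 2, 3], [4, 5, 6]
        res = mann_whitney(x, y)
        assert res.method == "exact"
        assert res.U == 0.0
        assert res.p == pytest.approx(0.1, abs=1e-12)
        assert res.p == pytest.approx(exact_two_sided_mw_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("x,y", [([1, 4, 2, 8], [3, 5, 7]), ([0.1, 0.9], [0.5, 0.2, 1.4])])
    def test_exact_path_agrees_with_oracle(self, x, y):
        res = mann_whitney(x, y)
        assert res.p == pytest.approx(exact_two_sided_mw_p(x, y), abs=1e-12)

    def test_identical_groups_fully_tied_give_p_one(self):
        res = mann_whitney([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.p == 1.0 and res.method == "degenerate"

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = np.round(rng.standard_normal(30), 1)  # rounding induces ties
        y = np.round(rng.standard_normal(30), 1)
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        assert 0 < res.p <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_samples_have_small_r(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r, _ = pearson_correlation(rng.standard_normal(1000), rng.standard_normal(1000))
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
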