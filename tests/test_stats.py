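"""Statistical layer: test selection, Williams' test, Hommel, regressions."""

import itertools

import numpy as np
import pandas as pd
import pytest

import nocturne as nt
from nocturne.errors import ConfigurationError, DegenerateDesign, DegenerateInput
from nocturne.stats import VariableSpec

rng = np.random.default_rng(2024)


# --------------------------------------------------------------------------
# group comparisons
# --------------------------------------------------------------------------

def test_fisher_chosen_when_expected_counts_low():
    df = pd.DataFrame({
        "grp": ["a"] * 8 + ["b"] * 8,
        "flag": [True, True, True, False, False, False, False, False]
                + [False] * 7 + [True],
    })
    (res,) = nt.compare_groups(df, "grp", [VariableSpec("flag", "categorical")])
    assert res.test == "fisher_exact"


def test_chi_squared_for_ample_counts():
    df = pd.DataFrame({
        "grp": ["a"] * 40 + ["b"] * 40,
        "flag": ([True] * 20 + [False] * 20) * 2,
    })
    (res,) = nt.compare_groups(df, "grp", [VariableSpec("flag", "categorical")])
    assert res.test == "chi_squared"
    assert res.p == pytest.approx(1.0)


def test_identical_groups_give_maximal_p_and_bonferroni_q():
    df = pd.DataFrame({"grp": ["a"] * 10 + ["b"] * 10,
                       "x": list(range(10)) * 2,
                       "y": list(range(10)) * 2})
    res = nt.compare_groups(df, "grp", [VariableSpec("x", "continuous"),
                                        VariableSpec("y", "continuous")])
    for r in res:
        assert r.p > 0.99
        assert r.q == min(1.0, 2 * r.p)
        assert r.q >= r.p


def test_kruskal_for_three_groups_and_config_errors():
    df = pd.DataFrame({"grp": ["a"] * 9 + ["b"] * 9 + ["c"] * 9,
                       "x": rng.normal(size=27)})
    (res,) = nt.compare_groups(df, "grp", [VariableSpec("x", "continuous")])
    assert res.test == "kruskal_wallis"
    with pytest.raises(ConfigurationError):
        nt.compare_groups(df, "grp", [VariableSpec("missing", "continuous")])
    with pytest.raises(ConfigurationError):
        nt.compare_groups(df[df.grp == "a"], "grp",
                          [VariableSpec("x", "continuous")])


# --------------------------------------------------------------------------
# Williams' test and correlation differences
# --------------------------------------------------------------------------

def test_williams_zero_under_equality():
    t, df, p = nt.williams_test(0.4, 0.4, 0.6, 79)
    assert t == 0.0 and df == 76 and p == pytest.approx(1.0)


def test_williams_antisymmetry():
    t1, _, p1 = nt.williams_test(0.55, 0.43, 0.9, 79)
    t2, _, p2 = nt.williams_test(0.43, 0.55, 0.9, 79)
    assert t1 == pytest.approx(-t2)
    assert p1 == pytest.approx(p2)


def test_williams_detects_table_sized_difference():
    # strongly dependent predictors, difference 0.12 at n = 79
    t, df, p = nt.williams_test(0.55, 0.43, 0.9, 79)
    assert t > 0 and p < 0.05


def test_williams_rejects_degenerate_input():
    with pytest.raises(DegenerateInput):
        nt.williams_test(0.9, -0.9, 0.9, 30)      # not a correlation matrix
    with pytest.raises(DegenerateInput):
        nt.williams_test(0.5, 0.4, 0.3, 3)
    with pytest.raises(DegenerateInput):
        nt.williams_test(1.0, 0.4, 0.3, 30)


def test_correlation_difference_reporting():
    assert nt.correlation_difference(0.36, 0.24) == pytest.approx((0.12, 50.0))
    absolute, _ = nt.correlation_difference(0.55, 0.43)
    assert absolute == pytest.approx(0.12)
    assert nt.correlation_difference(0.3, 0.3) == (0.0, 0.0)
    absolute, relative = nt.correlation_difference(0.3, 0.0)
    assert relative is None


# --------------------------------------------------------------------------
# Hommel adjustment
# --------------------------------------------------------------------------

def closed_testing_hommel(pvals):
    """Brute-force closed testing with Simes local tests (oracle)."""
    m = len(pvals)
    adjusted = []
    for i in range(m):
        worst = 0.0
        for size in range(1, m + 1):
            for sub in itertools.combinations(range(m), size):
                if i not in sub:
                    continue
                ps = sorted(pvals[j] for j in sub)
                simes = min(len(ps) * ps[k] / (k + 1) for k in range(len(ps)))
                worst = max(worst, simes)
        adjusted.append(min(1.0, worst))
    return np.array(adjusted)


def test_hommel_single_p_unchanged():
    assert nt.hommel_adjust([0.037]) == pytest.approx([0.037])


@pytest.mark.parametrize("pvals", [
    (0.01, 0.02, 0.03),
    (0.04, 0.04, 0.04),
    (0.005, 0.2, 0.2, 0.5),
    (0.9, 0.01, 0.3, 0.04, 0.7),
])
def test_hommel_equals_closed_testing(pvals):
    got = nt.hommel_adjust(list(pvals))
    want = closed_testing_hommel(list(pvals))
    assert got == pytest.approx(want, abs=1e-12)


def test_hommel_dominance_and_monotonicity():
    for _ in range(50):
        p = rng.uniform(size=rng.integers(2, 6))
        adj = nt.hommel_adjust(p)
        bon = nt.bonferroni_adjust(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= bon + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)   # monotone in raw p
    with pytest.raises(ValueError):
        nt.hommel_adjust([0.5, 1.5])


# --------------------------------------------------------------------------
# adjusted regressions
# --------------------------------------------------------------------------

def recovery_table(n=500, coef=2.0, seed=0, outlier=False):
    g = np.random.default_rng(seed)
    df = pd.DataFrame({
        "osi": g.normal(10.9, 1.0, n),
        "age": g.normal(58, 11, n),
        "sex": g.choice(["male", "female"], n),
        "bmi": g.normal(28, 4, n),
        "diabetes": g.random(n) < 0.3,
        "smoking_history": g.random(n) < 0.4,
    })
    df["y"] = coef * df["osi"] + g.normal(0, 2.0, n)
    if outlier:
        df.loc[int(df["osi"].idxmax()), "y"] += 60.0
    return df


def test_regression_recovers_planted_coefficient():
    model = nt.adjusted_regression(recovery_table(), "y")
    assert model.exposure_coef == pytest.approx(2.0, abs=0.2)
    assert all(v < 2.0 for v in model.vif.values())
    assert model.exposure_p < 1e-6


def test_duplicate_confounder_rejected():
    df = recovery_table(n=100)
    df["bmi"] = df["age"]
    with pytest.raises(DegenerateDesign):
        nt.adjusted_regression(df, "y")


def test_sensitivity_removes_planted_outlier_and_is_deterministic():
    df = recovery_table(n=200, seed=3, outlier=True)
    lever = int(df["osi"].idxmax())
    base, trimmed = nt.sensitivity_rerun(df, "y")
    assert lever in trimmed.removed_rows
    truth_gap_base = abs(base.exposure_coef - 2.0)
    truth_gap_trim = abs(trimmed.exposure_coef - 2.0)
    assert truth_gap_trim <= truth_gap_base
    _, trimmed2 = nt.sensitivity_rerun(df, "y")
    assert trimmed2.removed_rows == trimmed.removed_rows


def test_sensitivity_noop_without_outliers():
    # replicated balanced design (low, even leverage) with bounded noise:
    # nothing trips the influence rules, so the re-fit is the base fit
    block = pd.DataFrame({
        "osi": np.tile([9.5, 10.5, 11.5, 12.5], 3),
        "age": np.tile([50.0, 58, 66], 4),
        "sex": ["male", "female"] * 6,
        "bmi": np.tile([24.0, 28, 32, 26, 30, 27], 2),
        "diabetes": [True] * 6 + [False] * 6,
        "smoking_history": ([False] * 3 + [True] * 3) * 2,
    })
    df = pd.concat([block] * 10, ignore_index=True)
    g = np.random.default_rng(0)
    df["y"] = 2.0 * df["osi"] + 0.8 * g.uniform(-1, 1, len(df))
    base, trimmed = nt.sensitivity_rerun(df, "y")
    assert trimmed.removed_rows == []
    assert trimmed.params.equals(base.params)


def test_adjust_family_sets_hommel_p():
    models = [nt.adjusted_regression(recovery_table(seed=s, coef=c), "y")
              for s, c in ((1, 2.0), (2, 0.0), (3, 0.1))]
    nt.adjust_family(models)
    for m in models:
        assert m.hommel_adjusted_p >= m.exposure_p - 1e-15
        assert m.hommel_adjusted_p <= min(1.0, 3 * m.exposure_p) + 1e-15
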