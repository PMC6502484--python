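import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ricegs import genio, phenoadjust
from ricegs.cvengine import (
    CvScenario,
    anova_z,
    fisher_z,
    inverse_fisher_z,
    make_partitions,
    predictive_ability,
    run_cv,
)
from ricegs.errors import ConfigError, DataError


@pytest.mark.parametrize("n,n_train,n_valid", [(280, 224, 56), (204, 163, 41)])
def test_partition_sizes_match_study_counts(n, n_train, n_valid):
    plan = make_partitions([f"A{i}" for i in range(n)], train_frac=0.8,
                           n_reps=3, seed=0)
    for train, valid in plan.partitions:
        assert len(train) == n_train
        assert len(valid) == n_valid


def test_partition_property_and_reproducibility():
    ids = [f"A{i}" for i in range(50)]
    p1 = make_partitions(ids, n_reps=5, seed=7)
    p2 = make_partitions(ids, n_reps=5, seed=7)
    for (t1, v1), (t2, v2) in zip(p1.partitions, p2.partitions):
        assert sorted(t1 + v1) == sorted(ids)
        assert set(t1).isdisjoint(v1)
        assert t1 == t2 and v1 == v2
    # different replicates differ
    assert p1.partitions[0][0] != p1.partitions[1][0]
    with pytest.raises(ConfigError):
        make_partitions(ids, n_reps=0, seed=1)


def test_predictive_ability_limits_and_oracle():
    obs = [1.0, 2.0, 3.0, 4.0]
    assert predictive_ability(obs, obs) == pytest.approx(1.0)
    assert predictive_ability([-x for x in obs], obs) == pytest.approx(-1.0)
    pred, o = [1, 2, 3, 4], [1, 2, 2, 4]
    expected = np.corrcoef(pred, o)[0, 1]
    assert predictive_ability(pred, o) == pytest.approx(expected, abs=1e-12)
    with pytest.warns(UserWarning):
        assert np.isnan(predictive_ability([1, 1, 1], [1, 2, 3]))
    with pytest.raises(DataError):
        predictive_ability([1, 2], [1, 2])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.floats(min_value=-0.999, max_value=0.999))
def test_fisher_z_round_trip_property(r):
    assert abs(inverse_fisher_z(fisher_z(r)) - r) < 1e-9
    # monotone: z preserves the order of r
    assert fisher_z(min(r + 1e-4, 0.9995)) >= fisher_z(r)


def test_fisher_z_values_and_round_trip():
    assert fisher_z(0.0) == 0.0
    assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-14)
    for r in np.linspace(-0.99, 0.99, 21):
        assert abs(inverse_fisher_z(fisher_z(r)) - r) < 1e-12
    with pytest.raises(ValueError):
        fisher_z(1.0)


@pytest.fixture(scope="module")
def cv_setup(small_panel):
    cfg, g, truth, fieldbooks = small_panel
    y_adj = {}
    for env in cfg.env_labels:
        fit = phenoadjust.fit_adjustment_model(fieldbooks[env], env, "trait")
        y_adj[env] = phenoadjust.adjusted_means(fit, fieldbooks[env], env, "trait").y_adj
    gf = genio.filter_loci(g)
    premiss = genio.locus_stats(gf)
    gi = genio.impute_missing(gf)
    plan = make_partitions(gi.accession_ids, n_reps=3, seed=5)
    return gi, premiss, y_adj, plan, truth


def test_cv2_with_no_helpers_reduces_to_cv1(cv_setup):
    gi, premiss, y_adj, plan, _ = cv_setup
    kw = dict(target_env="E1", model="gblup", marker_mode="ld_derived",
              ld_r2_max=1.0, ld_min_maf=0.0)
    r1 = run_cv(CvScenario(scheme="CV1", **kw), plan, y_adj, gi, premiss)
    r2 = run_cv(CvScenario(scheme="CV2", helper_envs=[], **kw), plan, y_adj, gi, premiss)
    pd.testing.assert_frame_equal(r1.table, r2.table)


def test_oracle_predictions_have_unit_pa(cv_setup):
    gi, premiss, y_adj, plan, _ = cv_setup
    for _, valid in plan.partitions:
        obs = y_adj["E1"].loc[valid]
        assert predictive_ability(obs.to_numpy(), obs.to_numpy()) == pytest.approx(1.0)


def test_no_leakage_in_cv1_training_records(cv_setup, monkeypatch):
    # audit the records actually assembled for training: no validation
    # accession may appear in any environment under CV1
    gi, premiss, y_adj, plan, _ = cv_setup
    import ricegs.cvengine as cve
    seen = []
    orig = cve._fit_and_predict

    def spy(scenario, g_sel, train_records, valid_ids, seed):
        seen.append((set(train_records["accession"]), set(valid_ids)))
        return orig(scenario, g_sel, train_records, valid_ids, seed)

    monkeypatch.setattr(cve, "_fit_and_predict", spy)
    sc = CvScenario(scheme="CV1", target_env="E1", helper_envs=["E2"],
                    model="mxe_gblup", marker_mode="ld_derived",
                    ld_r2_max=1.0, ld_min_maf=0.0, iters=200, burnin=50)
    run_cv(sc, plan, y_adj, gi, premiss)
    assert seen
    for train_accs, valid in seen:
        assert train_accs.isdisjoint(valid)


def test_cv2_appends_helper_records_of_validation_accessions(cv_setup, monkeypatch):
    gi, premiss, y_adj, plan, _ = cv_setup
    import ricegs.cvengine as cve
    seen = []
    orig = cve._fit_and_predict

    def spy(scenario, g_sel, train_records, valid_ids, seed):
        seen.append((train_records.copy(), set(valid_ids)))
        return orig(scenario, g_sel, train_records, valid_ids, seed)

    monkeypatch.setattr(cve, "_fit_and_predict", spy)
    sc = CvScenario(scheme="CV2", target_env="E1", helper_envs=["E2"],
                    model="mxe_gblup", marker_mode="ld_derived",
                    ld_r2_max=1.0, ld_min_maf=0.0, iters=200, burnin=50)
    run_cv(sc, plan, y_adj, gi, premiss)
    for records, valid in seen:
        in_target = set(records.loc[records["env"] == "E1", "accession"])
        in_helper = set(records.loc[records["env"] == "E2", "accession"])
        assert in_target.isdisjoint(valid)  # target env stays unobserved
        assert valid <= in_helper  # helper records present


def test_null_model_pa_near_zero(cv_setup):
    # predictions from the training mean have no association with obs
    gi, premiss, y_adj, plan, _ = cv_setup
    rng = np.random.default_rng(0)
    rs = []
    for _ in range(50):
        valid = rng.choice(gi.accession_ids, 30, replace=False)
        obs = y_adj["E1"].loc[valid].to_numpy()
        pred = rng.standard_normal(30)  # exchangeable stand-in for a constant
        rs.append(np.corrcoef(pred, obs)[0, 1])
    se = np.std(rs, ddof=1) / np.sqrt(len(rs))
    assert abs(np.mean(rs)) < 3 * se + 1e-3


def test_pa_bounded_by_sqrt_h2(cv_setup, small_panel):
    cfg, *_ = small_panel
    gi, premiss, y_adj, plan, truth = cv_setup
    sc = CvScenario(scheme="CV1", target_env="E1", model="gblup",
                    marker_mode="ld_derived", ld_r2_max=1.0, ld_min_maf=0.0)
    res = run_cv(sc, plan, y_adj, gi, premiss)
    # PA against adjusted phenotypes cannot beat the accuracy ceiling
    assert res.summary["mean_r"].iloc[0] <= np.sqrt(cfg.h2_target["E1"]) + 0.05


def test_scenario_validation():
    with pytest.raises(ConfigError):
        CvScenario(scheme="CV3").validate()
    with pytest.raises(ConfigError):
        CvScenario(scheme="CV2", target_env="E1", helper_envs=["E1"]).validate()


def test_anova_constant_response_zero_ss():
    pa = pd.DataFrame({"r": 0.5, "model": ["a", "b"] * 10, "env": ["x", "x", "y", "y"] * 5})
    res = anova_z(pa, factors=["model", "env"])
    factor_rows = res.table[res.table["Source"] != "Residual"]
    assert np.allclose(factor_rows["SS"], 0.0, atol=1e-20)


def test_anova_two_level_f_equals_squared_t():
    rng = np.random.default_rng(1)
    r = np.clip(np.r_[rng.normal(0.5, 0.1, 20), rng.normal(0.6, 0.1, 20)], -0.99, 0.99)
    pa = pd.DataFrame({"r": r, "scheme": ["CV1"] * 20 + ["CV2"] * 20})
    res = anova_z(pa, factors=["scheme"])
    F = res.table.loc[res.table["Source"] == "C(scheme)", "F"].iloc[0]
    z = np.arctanh(r)
    t = stats.ttest_ind(z[:20], z[20:]).statistic
    assert F == pytest.approx(t**2, abs=1e-10)


def test_anova_main_effect_ss_stable_under_orthogonal_interactions():
    # balanced two-factor layout: main-effect SS identical whether or not
    # first-order interactions are added
    rng = np.random.default_rng(2)
    rows = []
    for a in ("m1", "m2"):
        for b in ("e1", "e2", "e3"):
            for _ in range(10):
                rows.append((a, b, np.tanh(rng.normal(0.4, 0.15))))
    pa = pd.DataFrame(rows, columns=["model", "env", "r"])
    r1 = anova_z(pa, factors=["model", "env"], interactions="none")
    r2 = anova_z(pa, factors=["model", "env"], interactions="first_order")
    for term in ("C(model)", "C(env)"):
        ss1 = r1.table.loc[r1.table["Source"] == term, "SS"].iloc[0]
        ss2 = r2.table.loc[r2.table["Source"] == term, "SS"].iloc[0]
        assert ss1 == pytest.approx(ss2, rel=1e-10)
    # df bookkeeping: factors + error = total
    assert r2.table["DF"].sum() == len(pa) - 1


def test_anova_z_factor_checks():
    pa = pd.DataFrame({"r": [0.1, 0.2], "model": ["a", "a"]})
    with pytest.raises(DataError):
        anova_z(pa, factors=["model"])
    with pytest.raises(DataError):
        anova_z(pa, factors=["missing_col"])
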