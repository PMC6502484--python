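import numpy as np
import pandas as pd
import pytest

from ricegs import genio
from ricegs import simdata as sd
from ricegs.errors import ConfigError, DataError
from ricegs.gwaselect import GRM, grm
from ricegs.kernelmodels import (
    KernelSpec,
    fit_gblup,
    fit_gxe_rkhs,
    fit_kron_multitrait,
    fit_mxe_gblup,
    fit_rkhs,
    gaussian_kernel,
    predict,
)

from conftest import make_gm


def _random_instance(seed, n=30, p=100):
    rng = np.random.default_rng(seed)
    M = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
    Mc = M - M.mean(axis=0)
    beta = rng.normal(0, 0.3, p)
    y = Mc @ beta + rng.standard_normal(n)
    ids = [f"A{i}" for i in range(n)]
    return M, Mc, pd.Series(y, index=ids), ids


def test_gaussian_kernel_formula_and_limits():
    M = np.array([[0.0, 2.0, 1.0], [0.0, 2.0, 1.0], [2.0, 0.0, 0.0]])
    g = make_gm(M)
    spec = KernelSpec(kind="gaussian", bandwidth_rule="fixed", h=0.5)
    K = gaussian_kernel(g, spec).matrix
    d2_13 = ((M[0] - M[2]) ** 2).sum() / 3.0
    assert K[0, 1] == pytest.approx(1.0)  # identical rows
    assert K[0, 2] == pytest.approx(np.exp(-0.5 * d2_13), abs=1e-12)
    # h -> 0 limit: all entries -> 1
    K0 = gaussian_kernel(g, KernelSpec("gaussian", "fixed", 1e-12)).matrix
    np.testing.assert_allclose(K0, 1.0, atol=1e-9)
    with pytest.raises(ConfigError):
        KernelSpec("gaussian", "fixed", -1.0)


def test_gblup_matches_ridge_oracle():
    M, Mc, y, ids = _random_instance(0)
    K = GRM(ids, Mc @ Mc.T + 1e-8 * np.eye(30), "raw", 1.0)
    fit = fit_gblup(y, K)
    lam = fit.sigma2_e / fit.sigma2_u
    bh = np.linalg.solve(Mc.T @ Mc + lam * np.eye(100), Mc.T @ (y.to_numpy() - fit.mu))
    np.testing.assert_allclose(fit.u_hat.to_numpy(), Mc @ bh, atol=1e-6)


def test_gblup_loglik_monotone():
    M, Mc, y, ids = _random_instance(1)
    K = GRM(ids, Mc @ Mc.T + 1e-8 * np.eye(30), "raw", 1.0)
    fit = fit_gblup(y, K)
    assert np.all(np.diff(fit.loglik_trace) >= -1e-9)


def test_gblup_interpolates_when_residual_fixed_near_zero():
    M, Mc, y, ids = _random_instance(2)
    K = GRM(ids, Mc @ Mc.T + 1e-6 * np.eye(30), "raw", 1.0)
    fit = fit_gblup(y, K, fix_sigma2_e=1e-9)
    np.testing.assert_allclose(fit.mu + fit.u_hat.to_numpy(), y.to_numpy(), atol=1e-6)


def test_gblup_h2_recovery():
    ests = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        n, p = 300, 400
        M = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
        g = make_gm(M)
        K = grm(g, "vanraden")
        L = np.linalg.cholesky(K.matrix + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n)
        u = u / u.std()
        y = u + rng.standard_normal(n)  # h2 = 0.5
        fit = fit_gblup(pd.Series(y, index=g.accession_ids), K)
        ests.append(fit.sigma2_u / (fit.sigma2_u + fit.sigma2_e))
    assert abs(np.mean(ests) - 0.5) < 0.1


def test_rkhs_reduces_to_gblup_with_linear_kernel():
    M, Mc, y, ids = _random_instance(3)
    K = GRM(ids, Mc @ Mc.T / 100 + 1e-8 * np.eye(30), "raw", 1.0)
    f1 = fit_gblup(y, K)
    f2 = fit_rkhs(y, K)
    np.testing.assert_allclose(f1.u_hat, f2.u_hat, atol=1e-10)


def test_rkhs_not_worse_than_gblup_under_epistasis():
    # genetic value includes pairwise products of QTL dosages
    better, close = 0, 0
    n_seeds = 6
    for seed in range(n_seeds):
        rng = np.random.default_rng(200 + seed)
        n, p = 150, 200
        M = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(float)
        q = rng.choice(p, 10, replace=False)
        lin = M[:, q] @ rng.normal(0, 1, 10)
        pairs = [(q[i], q[j]) for i in range(10) for j in range(i + 1, 10)]
        epi = sum(M[:, a] * M[:, b] * rng.normal(0, 0.6) for a, b in pairs)
        gval = lin + epi
        gval = (gval - gval.mean()) / gval.std()
        y = gval + 0.7 * rng.standard_normal(n)
        g = make_gm(M)
        ids = g.accession_ids
        train, valid = ids[:110], ids[110:]
        ys = pd.Series(y, index=ids)
        Klin = grm(g, "vanraden")
        Kg = gaussian_kernel(g)
        fl = fit_gblup(ys.loc[train], Klin)
        fg = fit_rkhs(ys.loc[train], Kg)
        pa_l = np.corrcoef(fl.u_hat.loc[valid], y[110:])[0, 1]
        pa_g = np.corrcoef(fg.u_hat.loc[valid], y[110:])[0, 1]
        if pa_g >= pa_l:
            better += 1
        if pa_g >= pa_l - 0.05:
            close += 1
    assert better >= n_seeds / 2
    assert close == n_seeds


@pytest.fixture(scope="module")
def mxe_instance():
    rng = np.random.default_rng(11)
    n, p = 100, 200
    M = rng.binomial(2, rng.uniform(0.1, 0.5, p), size=(n, p)).astype(float)
    g = make_gm(M)
    K = grm(g, "vanraden")
    w, U = np.linalg.eigh(K.matrix)
    L = U * np.sqrt(np.maximum(w, 0))
    u0, u1, u2 = (L @ rng.standard_normal(n) for _ in range(3))
    y1 = u0 + u1 + rng.normal(0, 1.0, n)
    y2 = u0 + u2 + rng.normal(0, 1.0, n)
    ids = g.accession_ids
    data = pd.DataFrame({
        "accession": ids * 2,
        "env": ["E1"] * n + ["E2"] * n,
        "value": np.r_[y1, y2],
    })
    return g, K, data, (u0, u1, u2)


def test_mxe_single_env_reduces_to_gblup(mxe_instance):
    g, K, data, _ = mxe_instance
    d1 = data[data["env"] == "E1"]
    fit = fit_mxe_gblup(d1, K, iters=1500, burnin=300, seed=1)
    y = pd.Series(d1["value"].to_numpy(), index=d1["accession"].to_numpy())
    fg = fit_gblup(y, K)
    r = np.corrcoef(fit.genetic_values["E1"], fg.u_hat.loc[fit.genetic_values.index])[0, 1]
    assert r > 0.99


def test_mxe_deterministic_under_seed(mxe_instance):
    g, K, data, _ = mxe_instance
    f1 = fit_mxe_gblup(data, K, iters=300, burnin=50, seed=5)
    f2 = fit_mxe_gblup(data, K, iters=300, burnin=50, seed=5)
    pd.testing.assert_frame_equal(f1.genetic_values, f2.genetic_values)


def test_mxe_recovers_between_env_correlation(mxe_instance):
    # equal shared and specific variances imply genetic correlation 0.5
    g, K, data, _ = mxe_instance
    ests = []
    for seed in range(3):
        fit = fit_mxe_gblup(data, K, iters=2500, burnin=500, seed=seed)
        s0 = fit.sigma2_0
        sj = np.mean(list(fit.sigma2_env.values()))
        ests.append(s0 / (s0 + sj))
    assert abs(np.mean(ests) - 0.5) < 0.15


def test_gxe_rkhs_matches_mxe_with_linear_kernel(mxe_instance):
    g, K, data, _ = mxe_instance
    f1 = fit_mxe_gblup(data, K, iters=1500, burnin=300, seed=3)
    f2 = fit_gxe_rkhs(data, K, iters=1500, burnin=300, seed=3)
    # same kernel, same sampler: identical up to the model label
    pd.testing.assert_frame_equal(f1.genetic_values, f2.genetic_values)
    assert f2.model == "gxe_rkhs"


def test_kron_recovers_genetic_correlation(mxe_instance):
    g, K, data, (u0, u1, u2) = mxe_instance
    Y = data.pivot(index="accession", columns="env", values="value")
    ests = []
    for seed in range(3):
        fit = fit_kron_multitrait(Y, K, iters=2500, burnin=500, seed=seed)
        Sg = fit.sigma_g
        ests.append(Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]))
    assert abs(np.mean(ests) - 0.5) < 0.15


def test_kron_null_correlation():
    # independent genetic values per environment: posterior genetic
    # correlation averages to ~0 over data realizations
    ests = []
    for seed in range(5):
        rng = np.random.default_rng(31 + seed)
        n, p = 120, 150
        M = rng.binomial(2, rng.uniform(0.2, 0.5, p), size=(n, p)).astype(float)
        g = make_gm(M)
        K = grm(g, "vanraden")
        w, U = np.linalg.eigh(K.matrix)
        L = U * np.sqrt(np.maximum(w, 0))
        y1 = L @ rng.standard_normal(n) + rng.normal(0, 0.5, n)
        y2 = L @ rng.standard_normal(n) + rng.normal(0, 0.5, n)
        Y = pd.DataFrame({"E1": y1, "E2": y2}, index=g.accession_ids)
        fit = fit_kron_multitrait(Y, K, iters=1500, burnin=300, seed=seed)
        Sg = fit.sigma_g
        ests.append(Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]))
    assert abs(np.mean(ests)) < 0.15


def test_kron_rejects_single_environment(mxe_instance):
    g, K, data, _ = mxe_instance
    Y = data[data["env"] == "E1"].pivot(index="accession", columns="env", values="value")
    with pytest.raises(DataError):
        fit_kron_multitrait(Y, K, iters=100, burnin=10, seed=0)


def test_predict_consistency_and_errors():
    M, Mc, y, ids = _random_instance(4)
    K = GRM(ids, Mc @ Mc.T + 1e-8 * np.eye(30), "raw", 1.0)
    fit = fit_gblup(y, K, env="E1")
    res = predict(fit, [(ids[0], "E1"), (ids[5], "E1")])
    assert res.table["gebv"].iloc[0] == pytest.approx(fit.mu + fit.u_hat[ids[0]])
    assert predict(fit, []).table.empty
    with pytest.raises(DataError, match="ZZZ"):
        predict(fit, [("ZZZ", "E1")])


def test_duplicate_genotypes_get_near_equal_gebv():
    rng = np.random.default_rng(6)
    n, p = 40, 80
    M = rng.binomial(2, 0.4, size=(n, p)).astype(float)
    M[-1] = M[0]  # unobserved duplicate of an observed accession
    Mc = M - M.mean(axis=0)
    g = make_gm(M)
    ids = g.accession_ids
    K = GRM(ids, Mc @ Mc.T + 1e-8 * np.eye(n), "raw", 1.0)
    y = pd.Series(Mc[:-1, :30] @ rng.normal(0, 0.5, 30) + rng.normal(0, 0.5, n - 1),
                  index=ids[:-1])
    fit = fit_gblup(y, K)
    assert abs(fit.u_hat[ids[0]] - fit.u_hat[ids[-1]]) < 1e-6


def test_prediction_equivariant_under_relabeling():
    M, Mc, y, ids = _random_instance(8)
    K1 = GRM(ids, Mc @ Mc.T + 1e-8 * np.eye(30), "raw", 1.0)
    f1 = fit_gblup(y, K1)
    perm = np.random.default_rng(0).permutation(30)
    K2 = GRM([ids[i] for i in perm], K1.matrix[np.ix_(perm, perm)], "raw", 1.0)
    f2 = fit_gblup(y, K2)
    np.testing.assert_allclose(f1.u_hat.sort_index(), f2.u_hat.sort_index(), atol=1e-8)
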