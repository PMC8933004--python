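"""Permutation nulls, beta MLE, empirical p-values and hierarchical calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtmkit import (
    bh_select,
    call_eqtms,
    discover,
    empirical_p,
    fit_beta_mle,
    min_p_per_cpg,
    nominal_threshold,
    permute_expression,
)
from eqtmkit.permutation import (
    BetaFit,
    SignificanceThresholds,
    fit_beta_mle_many,
    permutation_order,
)


def test_identity_permutation_reserved_for_observed():
    assert np.array_equal(permutation_order(50, 0, 123), np.arange(50))


def test_permutations_deterministic_and_nontrivial():
    p1 = permutation_order(100, 3, 42)
    p2 = permutation_order(100, 3, 42)
    assert np.array_equal(p1, p2)
    assert not np.array_equal(p1, np.arange(100))
    assert not np.array_equal(p1, permutation_order(100, 4, 42))


def test_permute_expression_preserves_row_content():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(5, 40)), columns=[f"s{i}" for i in range(40)])
    out = permute_expression(expr, 1, 7)
    assert np.allclose(np.sort(out.to_numpy(), axis=1), np.sort(expr.to_numpy(), axis=1))
    assert list(out.columns) == list(expr.columns)


def test_min_p_per_cpg_examples_and_oracle():
    assoc = pd.DataFrame(
        {"cpg_id": ["a", "b", "b", "b"], "gene_id": ["g1", "g1", "g2", "g3"],
         "p": [0.3, 0.5, 0.01, 0.2]}
    )
    got = min_p_per_cpg(assoc)
    assert got["a"] == 0.3 and got["b"] == 0.01
    rng = np.random.default_rng(1)
    big = pd.DataFrame(
        {"cpg_id": rng.choice([f"cg{i}" for i in range(50)], 400),
         "gene_id": [f"g{i}" for i in range(400)], "p": rng.uniform(size=400)}
    )
    brute = {c: g["p"].min() for c, g in big.groupby("cpg_id")}
    assert min_p_per_cpg(big).to_dict() == pytest.approx(brute)


def test_min_p_missing_pairs_rejected():
    assoc = pd.DataFrame({"cpg_id": ["a"], "gene_id": ["g1"], "p": [0.3]})
    pairs = pd.DataFrame({"cpg_id": ["a", "a"], "gene_id": ["g1", "g2"], "signed_dist": [0, 0]})
    with pytest.raises(ValueError, match="missing"):
        min_p_per_cpg(assoc, pairs)


def test_beta_mle_recovers_min_of_k_uniforms():
    """The minimum of k iid uniforms is Beta(1, k) exactly."""
    rng = np.random.default_rng(2)
    draws = rng.uniform(size=(5000, 30)).min(axis=1)
    fit = fit_beta_mle(draws)
    assert fit.converged
    assert fit.a == pytest.approx(1.0, rel=0.10)
    assert fit.b == pytest.approx(30.0, rel=0.10)


def test_beta_mle_uniform_limit():
    rng = np.random.default_rng(3)
    fit = fit_beta_mle(rng.uniform(size=5000))
    assert fit.converged
    assert fit.a == pytest.approx(1.0, rel=0.10)
    assert fit.b == pytest.approx(1.0, rel=0.10)


def test_beta_mle_beats_moment_start_loglik():
    rng = np.random.default_rng(4)
    x = rng.beta(0.8, 12.0, size=2000)
    fit = fit_beta_mle(x)
    m, v = x.mean(), x.var()
    common = m * (1 - m) / v - 1
    a0, b0 = m * common, (1 - m) * common
    from scipy.special import betaln

    ll0 = np.sum((a0 - 1) * np.log(x) + (b0 - 1) * np.log1p(-x)) - len(x) * betaln(a0, b0)
    assert fit.loglik >= ll0 - 1e-6


def test_beta_mle_matches_scipy_fit():
    """Independent oracle: scipy's generic beta MLE with fixed support."""
    rng = np.random.default_rng(5)
    x = rng.uniform(size=(1000, 40)).min(axis=1)
    fit = fit_beta_mle(x)
    a_ref, b_ref, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    assert fit.a == pytest.approx(a_ref, rel=0.02)
    assert fit.b == pytest.approx(b_ref, rel=0.02)


def test_beta_mle_degenerate_input_flagged():
    fit = fit_beta_mle(np.full(50, 0.2))
    assert not fit.converged


def test_beta_mle_many_matches_scalar():
    rng = np.random.default_rng(6)
    X = rng.beta(1.2, 8.0, size=(20, 100))
    a, b, ll, conv = fit_beta_mle_many(X)
    for i in range(20):
        f = fit_beta_mle(X[i])
        assert a[i] == pytest.approx(f.a, rel=1e-6)
        assert b[i] == pytest.approx(f.b, rel=1e-6)


@pytest.mark.parametrize(
    "a,b,obs,expected",
    [(1, 1, 0.3, 0.3), (1, 2, 0.1, 0.19), (1, 1, 1.0, 1.0)],
)
def test_empirical_p_closed_forms(a, b, obs, expected):
    fit = BetaFit(a=a, b=b, loglik=0.0, converged=True)
    assert empirical_p(obs, fit) == pytest.approx(expected, abs=1e-12)


def test_empirical_p_rank_fallback():
    fit = BetaFit(np.nan, np.nan, np.nan, False)
    perm = np.array([0.01, 0.2, 0.5, 0.9])
    assert empirical_p(0.15, fit, perm) == pytest.approx(2 / 5)
    with pytest.raises(ValueError):
        empirical_p(0.15, fit)


def test_bh_select_hand_example():
    p = pd.Series({"a": 0.001, "b": 0.002, "c": 0.9, "d": 0.95})
    sig, gw = bh_select(p, alpha=0.05)
    assert set(sig) == {"a", "b"}
    assert gw == pytest.approx((0.002 + 0.9) / 2)
    sig2, gw2 = bh_select(p, alpha=0.05, rule="largest")
    assert gw2 == pytest.approx(0.002)


def test_bh_select_nothing_significant():
    sig, gw = bh_select(pd.Series({"a": 1.0, "b": 1.0}), alpha=0.05)
    assert sig == [] and np.isnan(gw)


def _brute_bh(pvals: dict, alpha: float) -> set:
    items = sorted(pvals.items(), key=lambda kv: (kv[1], kv[0]))
    n = len(items)
    k = 0
    for i, (_, p) in enumerate(items, start=1):
        if p <= alpha * i / n:
            k = i
    return {name for name, _ in items[:k]}


def test_bh_select_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(20):
        p = pd.Series(rng.uniform(size=60) ** 3, index=[f"c{i}" for i in range(60)])
        sig, _ = bh_select(p, alpha=0.05)
        assert set(sig) == _brute_bh(p.to_dict(), 0.05)


def test_bh_uniform_null_rarely_rejects():
    rng = np.random.default_rng(8)
    total = 0
    for _ in range(50):
        p = pd.Series(rng.uniform(size=1000))
        sig, _ = bh_select(p, alpha=0.05)
        total += len(sig)
    assert total <= 10  # BH under a full null rejects with probability <= alpha


@pytest.mark.parametrize("a,b,gw,expected", [(1, 1, 0.05, 0.05), (1, 2, 0.19, 0.1)])
def test_nominal_threshold_closed_forms(a, b, gw, expected):
    fit = BetaFit(a=a, b=b, loglik=0.0, converged=True)
    assert nominal_threshold(fit, gw) == pytest.approx(expected, abs=1e-12)


def test_nominal_threshold_monotone():
    fit = BetaFit(a=1.1, b=25.0, loglik=0.0, converged=True)
    ts = [nominal_threshold(fit, g) for g in (0.01, 0.05, 0.2, 0.5)]
    assert ts == sorted(ts)


def test_call_eqtms_threshold_and_hierarchy():
    assoc = pd.DataFrame(
        {
            "cpg_id": ["a", "a", "b"],
            "gene_id": ["g1", "g2", "g3"],
            "beta": [-1.0, 2.0, -3.0],
            "p": [0.0005, 0.01, 1e-9],
            "signed_dist": [0, 0, 0],
        }
    )
    th = SignificanceThresholds(alpha=0.05, p_emp_genomewide=0.01, nominal_p={"a": 0.001})
    out = call_eqtms(assoc, th)
    assert len(out) == 1  # only a/g1; b is not BH-significant despite p=1e-9
    assert out.iloc[0]["gene_id"] == "g1"
    assert out.iloc[0]["direction"] == "inverse"


def test_discovery_hierarchical_containment(small_sim, small_pairs):
    res = discover(small_pairs, small_sim.meth, small_sim.expr, small_sim.covars,
                   n_perm=40, seed=5)
    sig, _ = bh_select(res.nulls["p_emp"], alpha=0.05)
    assert set(res.eqtms["cpg_id"]) <= set(sig)
    assert (res.eqtms["p"] < res.eqtms["nominal_p"]).all()
    assert res.min_p_perm.shape == (len(res.nulls), 40)


def test_discovery_deterministic(small_sim, small_pairs):
    r1 = discover(small_pairs, small_sim.meth, small_sim.expr, small_sim.covars, n_perm=20, seed=9)
    r2 = discover(small_pairs, small_sim.meth, small_sim.expr, small_sim.covars, n_perm=20, seed=9)
    pd.testing.assert_frame_equal(r1.eqtms, r2.eqtms)
    assert np.array_equal(r1.min_p_perm, r2.min_p_perm)
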