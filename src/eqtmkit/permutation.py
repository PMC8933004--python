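"""CpG-level multiple-testing via permutation nulls and a beta approximation.

The test statistic for each CpG is the minimum association p-value over all
its cis-paired genes.  Its null distribution is estimated by rerunning the
scan on expression matrices whose sample columns are permuted (one shared
permutation per permuted dataset, preserving gene-gene correlation), taking
the per-CpG minimum p in each permutation, and fitting a two-parameter beta
distribution to the permuted minima by maximum likelihood — the natural
family for extreme order statistics of p-values (the minimum of k
independent uniforms is exactly Beta(1, k)).

The observed minimum p evaluated through the fitted beta CDF gives the
CpG's empirical p-value.  Benjamini-Hochberg at 5% on empirical p-values
selects eCpGs; the empirical p closest to the FDR boundary defines a
genome-wide threshold, mapped back through each eCpG's inverse beta CDF to
a per-CpG nominal p-value threshold; every pair of a selected CpG below its
nominal threshold is a significant eQTM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .association import PairScanEngine, effect_log2fc_per_10pct

_CLIP_LO = 1e-300
_CLIP_HI = 1.0 - 1e-12


@dataclass
class BetaFit:
    a: float
    b: float
    loglik: float
    converged: bool


def permutation_order(n_samples: int, perm_index: int, master_seed: int) -> np.ndarray:
    """Deterministic sample permutation for permuted dataset ``perm_index``.

    Index 0 is reserved for the observed data (identity).  Each permutation
    is derived from an independent stream seeded by (master_seed,
    perm_index); an accidental identity draw is rejected and redrawn, so the
    identity permutation never enters the null.
    """
    if perm_index == 0:
        return np.arange(n_samples)
    rng = np.random.default_rng(np.random.SeedSequence([int(master_seed), int(perm_index)]))
    perm = rng.permutation(n_samples)
    while np.array_equal(perm, np.arange(n_samples)):  # pragma: no cover - p ~ 1/n!
        perm = rng.permutation(n_samples)
    return perm


def permute_expression(expr: pd.DataFrame, perm_index: int, master_seed: int) -> pd.DataFrame:
    """Apply one shared column permutation to all genes, keeping labels."""
    perm = permutation_order(expr.shape[1], perm_index, master_seed)
    return pd.DataFrame(expr.to_numpy()[:, perm], index=expr.index, columns=expr.columns)


def min_p_per_cpg(assoc: pd.DataFrame, pairs: pd.DataFrame | None = None) -> pd.Series:
    """Per-CpG minimum p-value over its paired genes."""
    if pairs is not None:
        key = pd.MultiIndex.from_frame(pairs[["cpg_id", "gene_id"]])
        have = pd.MultiIndex.from_frame(assoc[["cpg_id", "gene_id"]])
        if not key.isin(have).all():
            raise ValueError("association table is missing some candidate pairs")
    return assoc.groupby("cpg_id")["p"].min()


def _beta_negll_grad(la: np.ndarray, lb: np.ndarray, L1: np.ndarray, L2: np.ndarray):
    a, b = np.exp(la), np.exp(lb)
    ll = (a - 1) * L1 + (b - 1) * L2 - special.betaln(a, b)
    dig_ab = special.digamma(a + b)
    ga = (L1 - special.digamma(a) + dig_ab) * a
    gb = (L2 - special.digamma(b) + dig_ab) * b
    return -ll, -ga, -gb


def fit_beta_mle_many(minp: np.ndarray, tol: float = 1e-8, max_iter: int = 200):
    """Vectorized two-parameter beta MLE, one fit per row of ``minp``.

    Newton iterations on (log a, log b) from a method-of-moments start;
    values are clamped away from {0, 1} before taking logs.  Returns arrays
    (a, b, loglik, converged).
    """
    X = np.clip(np.asarray(minp, float), _CLIP_LO, _CLIP_HI)
    if X.ndim != 2:
        raise ValueError("minp must be 2-D (CpGs x permutations)")
    n = X.shape[1]
    if n < 20:
        raise ValueError("need at least 20 permuted minima per CpG")
    m = X.mean(axis=1)
    v = X.var(axis=1)
    degenerate = (v <= 1e-16) | (m <= 0) | (m >= 1)
    v = np.where(degenerate, 1e-4, np.minimum(v, m * (1 - m) * 0.999))
    common = m * (1 - m) / v - 1.0
    a = np.maximum(m * common, 1e-3)
    b = np.maximum((1 - m) * common, 1e-3)
    L1 = np.log(X).mean(axis=1)
    L2 = np.log1p(-X).mean(axis=1)

    la, lb = np.log(a), np.log(b)
    converged = np.zeros(len(m), bool)
    for _ in range(max_iter):
        a, b = np.exp(la), np.exp(lb)
        dig_ab = special.digamma(a + b)
        ga = (L1 - special.digamma(a) + dig_ab) * a  # d ll / d la
        gb = (L2 - special.digamma(b) + dig_ab) * b
        newly = (np.abs(ga) < tol) & (np.abs(gb) < tol)
        converged |= newly
        active = ~converged
        if not active.any():
            break
        tri_ab = special.polygamma(1, a + b)
        # Hessian of ll wrt (la, lb)
        haa = (-special.polygamma(1, a) + tri_ab) * a * a + ga
        hbb = (-special.polygamma(1, b) + tri_ab) * b * b + gb
        hab = tri_ab * a * b
        det = haa * hbb - hab * hab
        ok = active & (np.abs(det) > 1e-30) & (haa < 0) & (hbb < 0)
        step_a = np.where(ok, -(hbb * ga - hab * gb) / det, ga * 0.1)
        step_b = np.where(ok, -(haa * gb - hab * ga) / det, gb * 0.1)
        norm = np.maximum(np.abs(step_a), np.abs(step_b))
        scale = np.where(norm > 2.0, 2.0 / np.maximum(norm, 1e-30), 1.0)
        la = np.where(active, la + scale * step_a, la)
        lb = np.where(active, lb + scale * step_b, lb)
    a, b = np.exp(la), np.exp(lb)
    loglik = n * ((a - 1) * L1 + (b - 1) * L2 - special.betaln(a, b))
    converged &= np.isfinite(a) & np.isfinite(b) & ~degenerate
    return a, b, loglik, converged


def fit_beta_mle(min_p: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> BetaFit:
    """Beta MLE for one vector of permuted minimum p-values."""
    x = np.asarray(min_p, float)
    if x.ndim != 1 or len(x) < 20:
        raise ValueError("need a 1-D vector of at least 20 values")
    if np.ptp(np.clip(x, _CLIP_LO, _CLIP_HI)) == 0:
        return BetaFit(np.nan, np.nan, np.nan, False)
    a, b, ll, conv = fit_beta_mle_many(x[None, :], tol=tol, max_iter=max_iter)
    return BetaFit(float(a[0]), float(b[0]), float(ll[0]), bool(conv[0]))


def empirical_p(min_p_obs: float, fit: BetaFit, min_p_perm: np.ndarray | None = None) -> float:
    """Probability, under the fitted null, of a minimum p at least as small
    as observed.  Falls back to the rank-based (r+1)/(n+1) estimate when the
    beta fit did not converge."""
    if fit.converged:
        return float(stats.beta.cdf(min_p_obs, fit.a, fit.b))
    if min_p_perm is None:
        raise ValueError("non-converged beta fit and no permutation vector for fallback")
    r = int(np.sum(np.asarray(min_p_perm) <= min_p_obs))
    return (r + 1) / (len(min_p_perm) + 1)


def bh_select(
    p_emp: pd.Series, alpha: float = 0.05, rule: str = "midpoint"
) -> tuple[list[str], float]:
    """Benjamini-Hochberg on CpG empirical p-values.

    Returns the significant CpG ids and the genome-wide empirical threshold:
    by default the midpoint between the largest significant and smallest
    non-significant empirical p (``rule="largest"`` uses the largest
    significant value itself).  NaN when nothing is significant.
    """
    if p_emp.empty:
        raise ValueError("empty empirical p-value map")
    ordered = p_emp.reset_index()
    ordered.columns = ["cpg_id", "p_emp"]
    ordered = ordered.sort_values(["p_emp", "cpg_id"], kind="stable")
    reject, _, _, _ = multipletests(ordered["p_emp"].to_numpy(), alpha=alpha, method="fdr_bh")[:4]
    sig = ordered.loc[reject, "cpg_id"].tolist()
    if not sig:
        return [], float("nan")
    largest_sig = float(ordered.loc[reject, "p_emp"].max())
    nonsig = ordered.loc[~reject, "p_emp"]
    if rule == "largest" or nonsig.empty:
        gw = largest_sig
    else:
        gw = (largest_sig + float(nonsig.min())) / 2.0
    return sig, gw


def nominal_threshold(fit: BetaFit, p_emp_genomewide: float) -> float:
    """Per-CpG pair-level p cutoff: inverse beta CDF at the genome-wide
    empirical threshold."""
    if not fit.converged:
        raise ValueError("cannot invert a non-converged beta fit")
    if not (0 < p_emp_genomewide < 1):
        raise ValueError("p_emp_genomewide must lie in (0, 1)")
    return float(stats.beta.ppf(p_emp_genomewide, fit.a, fit.b))


@dataclass
class SignificanceThresholds:
    alpha: float
    p_emp_genomewide: float
    nominal_p: dict[str, float]


def call_eqtms(assoc: pd.DataFrame, thresholds: SignificanceThresholds) -> pd.DataFrame:
    """Flag every pair of a selected CpG whose p falls below that CpG's
    nominal threshold; direction is the sign of the coefficient."""
    nominal = pd.Series(thresholds.nominal_p, dtype=float)
    sub = assoc[assoc["cpg_id"].isin(nominal.index)].copy()
    sub["nominal_p"] = nominal.reindex(sub["cpg_id"]).to_numpy()
    out = sub[sub["p"] < sub["nominal_p"]].copy()
    out["direction"] = np.where(out["beta"] < 0, "inverse", "positive")
    out["log2fc_per_10pct"] = effect_log2fc_per_10pct(out["beta"])
    out["significant"] = True
    return out.reset_index(drop=True)


@dataclass
class DiscoveryResult:
    """Everything the permutation procedure produced."""

    associations: pd.DataFrame
    nulls: pd.DataFrame  # per CpG: min_p_obs, a, b, converged, p_emp
    thresholds: SignificanceThresholds
    eqtms: pd.DataFrame
    min_p_perm: np.ndarray  # CpGs x n_perm, row order = nulls.index


def discover(
    pairs: pd.DataFrame,
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    covars: pd.DataFrame,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    model: str = "cell_adjusted",
    rule: str = "midpoint",
) -> DiscoveryResult:
    """Run the full CpG-level discovery procedure.

    Scans the observed data, generates ``n_perm`` permuted expression
    datasets (sample columns shuffled identically for all genes), collects
    per-CpG minimum p-values, fits per-CpG beta nulls, computes empirical
    p-values, applies BH at ``alpha``, derives per-CpG nominal thresholds
    and calls significant eQTMs.
    """
    if pairs.empty:
        raise ValueError("no candidate pairs to test")
    engine = PairScanEngine(pairs, meth, expr, covars, model)
    assoc = engine.full_results()

    cpg_codes, cpg_ids = pd.factorize(assoc["cpg_id"], sort=True)
    n_cpg = len(cpg_ids)
    min_obs = np.full(n_cpg, np.inf)
    np.minimum.at(min_obs, cpg_codes, assoc["p"].to_numpy())

    E = expr.to_numpy(float)
    minp = np.empty((n_cpg, n_perm))
    for j in range(1, n_perm + 1):
        perm = permutation_order(E.shape[1], j, seed)
        p = engine.pvalues(E[:, perm])
        col = np.full(n_cpg, np.inf)
        np.minimum.at(col, cpg_codes, p)
        minp[:, j - 1] = col

    a, b, ll, conv = fit_beta_mle_many(minp)
    p_emp = np.where(
        conv,
        stats.beta.cdf(min_obs, a, b),
        (np.sum(minp <= min_obs[:, None], axis=1) + 1) / (n_perm + 1),
    )
    nulls = pd.DataFrame(
        {
            "min_p_obs": min_obs,
            "a": a,
            "b": b,
            "loglik": ll,
            "converged": conv,
            "p_emp": p_emp,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    sig, gw = bh_select(nulls["p_emp"], alpha=alpha, rule=rule)
    nominal: dict[str, float] = {}
    if sig and np.isfinite(gw) and 0 < gw < 1:
        for c in sig:
            row = nulls.loc[c]
            if row["converged"]:
                nominal[c] = float(stats.beta.ppf(gw, row["a"], row["b"]))
            else:
                # rank-based inverse: the gw-quantile of the permuted minima
                nominal[c] = float(np.quantile(minp[nulls.index.get_loc(c)], gw))
    thresholds = SignificanceThresholds(alpha=alpha, p_emp_genomewide=gw, nominal_p=nominal)
    eqtms = call_eqtms(assoc, thresholds)
    return DiscoveryResult(assoc, nulls, thresholds, eqtms, minp)
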