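"""Operating-characteristic studies of the discovery procedure.

These helpers measure, on synthetic data with known truth, the quantities
that validate the pipeline: the realized false discovery proportion among
declared eCpGs at the procedure's 5% operating point, the sensitivity for
planted cis effects, and the fidelity of the beta approximation to the
direct rank-based permutation p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cis import pair_cis
from .permutation import discover
from .simulate import EffectSpec, SimConfig, simulate_dataset

# Study conditions for the FDR benchmark: 2,000 CpGs, 200 genes, 300
# samples, 10% of CpGs carrying one true cis effect with |beta| in [1, 3],
# residual expression SD 0.5, 100 permutations, BH at 5%.
FDR_STUDY = SimConfig(n_cpgs=2000, n_genes=200, n_samples=300, with_metadata=False)


def fdr_replicate(
    seed: int,
    config: SimConfig = FDR_STUDY,
    n_perm: int = 100,
    alpha: float = 0.05,
) -> dict:
    """One simulate-discover cycle; returns realized FDP and sensitivity.

    FDP is the fraction of declared eCpGs with no planted effect;
    sensitivity the fraction of truly affected CpGs that were declared.
    """
    sim = simulate_dataset(config, seed=seed)
    pairs = pair_cis(sim.cpgs, sim.genes, config.window_bp)
    res = discover(pairs, sim.meth, sim.expr, sim.covars, n_perm=n_perm, alpha=alpha, seed=seed)
    declared = set(res.eqtms["cpg_id"])
    true_cpgs = set(sim.truth.loc[sim.truth["true_beta"] != 0, "cpg_id"])
    n_false = len(declared - true_cpgs)
    return {
        "seed": seed,
        "n_declared": len(declared),
        "n_true": len(true_cpgs),
        "fdp": n_false / len(declared) if declared else 0.0,
        "sensitivity": len(declared & true_cpgs) / len(true_cpgs) if true_cpgs else float("nan"),
        "n_eqtms": len(res.eqtms),
    }


def fdr_study(seeds, config: SimConfig = FDR_STUDY, n_perm: int = 100, alpha: float = 0.05) -> pd.DataFrame:
    """Run `fdr_replicate` over a seed list; one row per replicate."""
    return pd.DataFrame([fdr_replicate(s, config, n_perm, alpha) for s in seeds])


def beta_approximation_fidelity(
    seed: int = 0,
    n_cpgs: int = 600,
    n_genes: int = 80,
    n_samples: int = 150,
    n_perm: int = 1000,
) -> dict:
    """Compare beta-based and rank-based empirical p-values at high
    permutation depth on a global-null dataset.

    Returns the Spearman correlation over mid-range CpGs (empirical p in
    (0.001, 0.999)) and the two p-value vectors.
    """
    cfg = SimConfig(
        n_cpgs=n_cpgs, n_genes=n_genes, n_samples=n_samples,
        effect=EffectSpec(n_true_pairs=0), with_metadata=False,
    )
    sim = simulate_dataset(cfg, seed=seed)
    pairs = pair_cis(sim.cpgs, sim.genes, cfg.window_bp)
    res = discover(pairs, sim.meth, sim.expr, sim.covars, n_perm=n_perm, seed=seed)
    nulls = res.nulls[res.nulls["converged"]]
    minp = res.min_p_perm[res.nulls["converged"].to_numpy()]
    rank_p = (np.sum(minp <= nulls["min_p_obs"].to_numpy()[:, None], axis=1) + 1) / (n_perm + 1)
    beta_p = nulls["p_emp"].to_numpy()
    mid = (beta_p > 0.001) & (beta_p < 0.999)
    rho = stats.spearmanr(beta_p[mid], rank_p[mid]).statistic
    return {"spearman_rho": float(rho), "n_mid": int(mid.sum()), "beta_p": beta_p, "rank_p": rank_p}
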