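"""Synthetic-data generator: determinism, bounds, planted-effect fidelity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtmkit import (
    ChainSpec,
    EffectSpec,
    SimConfig,
    fit_pair,
    generate_annotation,
    generate_covariates,
    generate_genotypes,
    generate_omics,
    pair_cis,
    run_model,
    simulate_dataset,
)
from eqtmkit.simulate import CELL_COLUMNS


def test_empty_inputs_rejected():
    with pytest.raises(ValueError):
        generate_annotation(0, 10)
    with pytest.raises(ValueError):
        generate_annotation(10, 0)


def test_short_chromosome_rejected():
    with pytest.raises(ValueError, match="2x window"):
        generate_annotation(10, 5, {"1": 100_000}, window_bp=500_000)


def test_non_autosome_rejected():
    with pytest.raises(ValueError, match="autosome"):
        generate_annotation(10, 5, {"X": 10_000_000})


def test_annotation_determinism_and_bounds():
    a1 = generate_annotation(200, 20, seed=1)
    a2 = generate_annotation(200, 20, seed=1)
    pd.testing.assert_frame_equal(a1[0], a2[0])
    pd.testing.assert_frame_equal(a1[1], a2[1])
    cpgs, genes = a1
    assert (cpgs["pos"] >= 1).all()
    assert set(genes["strand"]) == {"+", "-"}
    assert (genes["start"] <= genes["end"]).all()
    assert cpgs.index.is_unique and genes.index.is_unique


def test_every_gene_has_cis_cpgs_on_dense_chromosome():
    """1000 CpGs and 50 genes on one 10 Mb chromosome: brute-force scan finds
    at least one CpG within 500 kb of every gene's TSS."""
    cpgs, genes = generate_annotation(1000, 50, {"1": 10_000_000}, seed=7)
    from eqtmkit.cis import tss_positions

    t = tss_positions(genes)
    pos = cpgs["pos"].to_numpy()
    for gid in genes.index:
        assert np.any(np.abs(pos - t[gid]) <= 500_000), f"gene {gid} has no cis CpG"


def test_covariates_shape():
    cov = generate_covariates(80, seed=0)
    cells = cov[CELL_COLUMNS].to_numpy()
    assert (cells >= 0).all()
    assert np.allclose(cells.sum(axis=1), 1.0)
    assert cov.index.is_unique


def _tiny_annotation(seed=0):
    return generate_annotation(60, 8, {"1": 5_000_000}, seed=seed)


def test_omics_determinism_and_bounds(small_sim):
    cfg = SimConfig(n_cpgs=300, n_genes=40, n_samples=150, chains=ChainSpec(n_chains=8, n_null_snps=6))
    again = simulate_dataset(cfg, seed=11)
    pd.testing.assert_frame_equal(small_sim.meth, again.meth)
    pd.testing.assert_frame_equal(small_sim.expr, again.expr)
    pd.testing.assert_frame_equal(small_sim.truth, again.truth)
    m = small_sim.meth.to_numpy()
    assert ((m >= 0) & (m <= 1)).all() and not np.isnan(m).any()


def test_no_true_pairs_gives_empty_truth():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(50, seed=1)
    _, _, truth = generate_omics(cpgs, genes, cov, EffectSpec(n_true_pairs=0), seed=2)
    assert (truth["true_beta"] != 0).sum() == 0


def test_beta_range_including_zero_rejected():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(50, seed=1)
    with pytest.raises(ValueError, match="beta_range"):
        generate_omics(cpgs, genes, cov, EffectSpec(beta_range=(0.0, 1.0)), seed=2)


def test_too_many_true_pairs_rejected():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(50, seed=1)
    with pytest.raises(ValueError, match="true pairs"):
        generate_omics(cpgs, genes, cov, EffectSpec(n_true_pairs=10_000), seed=2)


def test_noiseless_expression_exactly_linear_in_methylation():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(50, seed=1)
    spec = EffectSpec(
        n_true_pairs=1, beta_range=(1.0, 1.0), sign_mix=1.0, noise_sd=0.0,
        confound_meth_sd=0.0, confound_expr_sd=0.0, cell_effect_sd=0.0,
    )
    meth, expr, truth = generate_omics(cpgs, genes, cov, spec, seed=3)
    row = truth.iloc[0]
    resid = expr.loc[row.gene_id] - row.true_beta * meth.loc[row.cpg_id]
    # sex/age effects remain; regress them off and require exact linearity
    fp = fit_pair(meth.loc[row.cpg_id], expr.loc[row.gene_id], cov)
    assert fp["beta"] == pytest.approx(1.0, abs=1e-10)
    assert np.ptp(resid - resid.mean()) < 5.0  # bounded by covariate effects only


def test_planted_beta_recovered_within_3se():
    cpgs, genes = generate_annotation(200, 20, {"1": 10_000_000}, seed=4)
    cov = generate_covariates(300, seed=5)
    spec = EffectSpec(n_true_pairs=5, beta_range=(2.0, 2.0), noise_sd=0.5)
    meth, expr, truth = generate_omics(cpgs, genes, cov, spec, seed=6)
    for row in truth.itertuples():
        fp = fit_pair(meth.loc[row.cpg_id], expr.loc[row.gene_id], cov)
        assert abs(fp["beta"] - row.true_beta) < 3 * fp["se"]


def test_null_pvalues_uniform():
    """With no planted effects, adjusted per-pair p-values are uniform."""
    cpgs, genes = generate_annotation(2500, 100, {"1": 30_000_000}, seed=8)
    cov = generate_covariates(100, seed=9)
    meth, expr, _ = generate_omics(cpgs, genes, cov, EffectSpec(n_true_pairs=0), seed=10)
    pairs = pair_cis(cpgs, genes)
    assert len(pairs) >= 5000
    assoc = run_model(pairs, meth, expr, cov)
    ks = stats.kstest(assoc["p"], "uniform")
    assert ks.pvalue > 0.01


def test_genotype_maf_range_validated(small_sim):
    with pytest.raises(ValueError, match="maf_range"):
        generate_genotypes(
            small_sim.cpgs, small_sim.meth, small_sim.expr, small_sim.truth,
            ChainSpec(maf_range=(0.0, 0.6)), seed=0,
        )


def test_more_chains_than_truth_rejected():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(50, seed=1)
    meth, expr, truth = generate_omics(cpgs, genes, cov, EffectSpec(n_true_pairs=2), seed=2)
    with pytest.raises(ValueError, match="chains"):
        generate_genotypes(cpgs, meth, expr, truth, ChainSpec(n_chains=5), seed=3)


def test_zero_snp_effect_leaves_omics_unchanged():
    cpgs, genes = _tiny_annotation()
    cov = generate_covariates(60, seed=1)
    meth, expr, truth = generate_omics(cpgs, genes, cov, EffectSpec(n_true_pairs=3), seed=2)
    dos, snps, meth2, expr2, _ = generate_genotypes(
        cpgs, meth, expr, truth, ChainSpec(n_chains=2, snp_effect_on_meth=0.0, n_null_snps=0), seed=3
    )
    assert np.allclose(meth.to_numpy(), meth2.to_numpy())
    assert np.allclose(expr.to_numpy(), expr2.to_numpy())
    assert set(np.unique(dos.to_numpy())) <= {0.0, 1.0, 2.0}


def test_chain_sign_transitivity_noiseless():
    """sign(SNP->CpG) x sign(CpG->gene truth) == sign(SNP->gene) without noise."""
    cpgs, genes = generate_annotation(100, 30, {"1": 8_000_000}, seed=12)
    cov = generate_covariates(200, seed=13)
    spec = EffectSpec(
        n_true_pairs=8, beta_range=(1.5, 1.5), sign_mix=0.5, noise_sd=0.0,
        confound_meth_sd=0.0, confound_expr_sd=0.0, cell_effect_sd=0.0,
        meth_logit_sd=0.3,
    )
    meth, expr, truth = generate_omics(cpgs, genes, cov, spec, seed=14)
    dos, snps, meth, expr, truth = generate_genotypes(
        cpgs, meth, expr, truth, ChainSpec(n_chains=8, snp_effect_on_meth=1.0, n_null_snps=0), seed=15
    )
    # the marginal SNP->gene slope reflects the chain only where the gene has
    # a single planted driver; genes hit by two chains mix both signals
    single_driver = truth.groupby("gene_id")["cpg_id"].transform("size") == 1
    chains = truth[(truth["mechanism"] == "snp_driven") & single_driver]
    assert len(chains) >= 3
    for row in chains.itertuples():
        d = dos.loc[row.snp_id].to_numpy()
        s_mc = np.polyfit(d, meth.loc[row.cpg_id].to_numpy(), 1)[0]
        s_ge = np.polyfit(d, expr.loc[row.gene_id].to_numpy(), 1)[0]
        assert np.sign(s_mc) * np.sign(row.true_beta) == np.sign(s_ge)


def test_metadata_columns_present(small_sim):
    for col in ("icc", "heritability_total", "island_rel", "state_TssA", "age_change"):
        assert col in small_sim.cpgs.columns
    assert small_sim.cpgs["icc"].between(0, 1).all()
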