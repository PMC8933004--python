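"""Synthetic child-blood methylation/expression datasets with known ground truth.

The generator emulates the data structure an autosomal cis-eQTM scan
consumes: beta-value methylation (bounded in [0,1], bimodal per-CpG means,
logit-normal variation), approximately Gaussian log2 expression, a covariate
table (sex, age, cohort, six blood cell-type proportions), planted linear
CpG->gene effects of both signs inside the cis window, configurable
cohort/cell-composition confounding of both omics layers, and optional
SNP->CpG->gene causal chains with additive per-allele dosage effects on the
latent (logit) methylation scale.

Every planted effect is recorded in a truth table so downstream stages
(association, permutation FDR, trio assembly) can be scored against a known
answer.  All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cis import AUTOSOMES, pair_cis

CELL_TYPES = ["cd4t", "cd8t", "nk", "bcell", "mono", "gran"]
CELL_COLUMNS = [f"cell_{c}" for c in CELL_TYPES]
# Dirichlet concentrations approximating a typical child leukocyte mix
# (granulocyte-dominant); total concentration ~30 gives realistic spread.
_CELL_ALPHA = np.array([6.0, 4.0, 1.5, 3.5, 2.0, 13.0])

ISLAND_CATEGORIES = ["island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea"]
CHROMATIN_STATES = ["TssA", "TssAFlnk", "Tx", "Enh", "EnhG", "ReprPC", "Quies"]

DEFAULT_CHROM_LENGTHS = {"1": 60_000_000, "2": 40_000_000}


@dataclass(frozen=True)
class EffectSpec:
    """How many true cis effects to plant and how strong they are.

    ``beta_range`` is the magnitude range of the planted coefficient (change
    in log2 expression per unit methylation); signs are drawn with
    probability ``sign_mix`` of being positive.  ``noise_sd`` is the residual
    SD of log2 expression.  Confounding strengths are SDs of cohort/cell
    effects on the latent methylation scale and on log2 expression.
    """

    n_true_pairs: int | None = None  # default: 10% of CpGs
    beta_range: tuple[float, float] = (1.0, 3.0)
    sign_mix: float = 0.5
    noise_sd: float = 0.5
    meth_logit_sd: float = 1.0
    confound_meth_sd: float = 0.3
    confound_expr_sd: float = 0.3
    cell_effect_sd: float = 1.0
    expr_baseline_mean: float = 7.0
    expr_baseline_sd: float = 2.0
    shared_factor_sd: float = 0.0  # optional shared latent factor across genes
    unique_genes: bool = False  # plant at most one effect per gene


@dataclass(frozen=True)
class ChainSpec:
    """SNP->CpG->gene causal chains attached to already-planted pairs."""

    n_chains: int = 20
    snp_effect_on_meth: float = 1.0  # per-allele shift on the logit scale
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_null_snps: int = 20  # extra SNPs with no effect on any omics layer


def generate_annotation(
    n_cpgs: int,
    n_genes: int,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
    window_bp: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample CpG and gene annotations on autosomes.

    Positions are uniform per chromosome with counts proportional to
    chromosome length; gene bodies are short (log-normal ~10 kb) relative to
    the cis window, and both strands are represented.  Gene TSSs are kept at
    least ``window_bp`` from the chromosome ends so each gene's full cis
    window is coverable by CpGs.
    """
    if n_cpgs <= 0 or n_genes <= 0:
        raise ValueError("n_cpgs and n_genes must be positive")
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    if not chrom_lengths:
        raise ValueError("need at least one chromosome")
    for chrom, length in chrom_lengths.items():
        if str(chrom) not in AUTOSOMES:
            raise ValueError(f"chromosome {chrom!r} is not an autosome label '1'..'22'")
        if length < 2 * window_bp:
            raise ValueError(
                f"chromosome {chrom} length {length} < 2x window ({2 * window_bp}); "
                "cannot place a full cis window"
            )
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths, key=int)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    cpg_chrom = rng.choice(len(chroms), size=n_cpgs, p=probs)
    cpg_pos = (rng.random(n_cpgs) * lengths[cpg_chrom]).astype(np.int64) + 1
    cpgs = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in cpg_chrom],
            "pos": cpg_pos,
        },
        index=pd.Index([f"cg{i:07d}" for i in range(n_cpgs)], name="cpg_id"),
    )
    cpgs = cpgs.sort_values(["chrom", "pos"], kind="stable")

    gene_chrom = rng.choice(len(chroms), size=n_genes, p=probs)
    span = lengths[gene_chrom] - 2 * window_bp
    tss_pos = (window_bp + rng.random(n_genes) * span).astype(np.int64) + 1
    glen = np.minimum(
        rng.lognormal(mean=np.log(10_000), sigma=0.8, size=n_genes).astype(np.int64) + 200,
        window_bp // 2,
    )
    strand = rng.choice(["+", "-"], size=n_genes)
    start = np.where(strand == "+", tss_pos, np.maximum(tss_pos - glen, 1))
    end = np.where(strand == "+", tss_pos + glen, tss_pos)
    genes = pd.DataFrame(
        {
            "chrom": [chroms[i] for i in gene_chrom],
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
            "strand": strand,
            "symbols": [f"GENE{i}" for i in range(n_genes)],
        },
        index=pd.Index([f"TC{i:06d}" for i in range(n_genes)], name="gene_id"),
    )
    genes = genes.sort_values(["chrom", "start"], kind="stable")
    return cpgs, genes


def generate_covariates(n_samples: int, n_cohorts: int = 6, seed: int = 0) -> pd.DataFrame:
    """Sample a covariate table: sex, age (years), cohort, 6 cell proportions."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    sex = rng.integers(0, 2, size=n_samples)
    age = rng.uniform(6.0, 11.0, size=n_samples)
    cohort = rng.integers(0, n_cohorts, size=n_samples)
    cells = rng.dirichlet(_CELL_ALPHA, size=n_samples)
    covars = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "cohort": [f"coh{c + 1}" for c in cohort],
        },
        index=pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample_id"),
    )
    covars[CELL_COLUMNS] = cells
    return covars


def _cohort_codes(covars: pd.DataFrame) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(covars["cohort"], sort=True)
    return codes, len(uniques)


def generate_omics(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    covars: pd.DataFrame,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    window_bp: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate methylation and expression matrices with planted cis effects.

    Methylation is logit-normal per CpG: a latent Gaussian around a
    CpG-specific mean drawn from a bimodal mixture (mimicking the low/high
    beta-value modes of blood arrays), shifted by cohort, cell-composition,
    sex and age effects, then squashed through the logistic function.
    Expression is a per-gene Gaussian baseline plus cohort/cell/sex/age
    effects, plus ``true_beta * methylation`` for each planted pair, plus
    Gaussian noise.

    Returns ``(meth, expr, truth)``; truth lists every planted pair with its
    coefficient (mechanism ``direct``).  With ``n_true_pairs=0`` the truth
    table carries no nonzero rows.
    """
    spec = effect_spec or EffectSpec()
    if spec.beta_range[0] <= 0 or spec.beta_range[1] < spec.beta_range[0]:
        raise ValueError("beta_range must be a positive magnitude range excluding 0")
    rng = np.random.default_rng(seed)
    n_c, n_g, n_s = len(cpgs), len(genes), len(covars)
    cohort_codes, n_cohorts = _cohort_codes(covars)
    cells = covars[CELL_COLUMNS].to_numpy()
    cells_c = cells - cells.mean(axis=0)
    sex = covars["sex"].to_numpy(float)
    age_c = covars["age"].to_numpy(float) - covars["age"].mean()

    # --- methylation ---
    comp = rng.choice(3, size=n_c, p=[0.45, 0.45, 0.10])
    mu = np.where(
        comp == 0,
        rng.beta(2, 10, size=n_c),
        np.where(comp == 1, rng.beta(10, 2, size=n_c), rng.beta(5, 5, size=n_c)),
    )
    latent = logit(np.clip(mu, 1e-4, 1 - 1e-4))[:, None] * np.ones((1, n_s))
    coh_eff_m = rng.normal(0, spec.confound_meth_sd, size=(n_c, n_cohorts))
    latent += coh_eff_m[:, cohort_codes]
    cell_eff_m = rng.normal(0, spec.cell_effect_sd, size=(n_c, len(CELL_TYPES)))
    latent += cell_eff_m @ cells_c.T
    latent += rng.normal(0, 0.1, size=n_c)[:, None] * sex[None, :]
    latent += rng.normal(0, 0.02, size=n_c)[:, None] * age_c[None, :]
    latent += rng.normal(0, spec.meth_logit_sd, size=(n_c, n_s))
    meth = pd.DataFrame(expit(latent), index=cpgs.index, columns=covars.index)

    # --- planted truth ---
    pairs = pair_cis(cpgs, genes, window_bp=window_bp)
    n_true = spec.n_true_pairs if spec.n_true_pairs is not None else n_c // 10
    cpgs_with_pairs = pairs["cpg_id"].unique()
    if n_true > len(cpgs_with_pairs):
        raise ValueError(
            f"requested {n_true} true pairs but only {len(cpgs_with_pairs)} CpGs "
            "have cis partners"
        )
    truth_rows = []
    if n_true > 0:
        mags = rng.uniform(spec.beta_range[0], spec.beta_range[1], size=n_true)
        signs = np.where(rng.random(n_true) < spec.sign_mix, 1.0, -1.0)
        if spec.unique_genes:
            # one effect per CpG and per gene: shuffle the pair universe and
            # keep pairs whose CpG and gene are both still unused
            order = rng.permutation(len(pairs))
            seen_c: set[str] = set()
            seen_g: set[str] = set()
            k = 0
            carr = pairs["cpg_id"].to_numpy()
            garr = pairs["gene_id"].to_numpy()
            for idx in order:
                c, g = carr[idx], garr[idx]
                if c in seen_c or g in seen_g:
                    continue
                seen_c.add(c)
                seen_g.add(g)
                truth_rows.append((c, g, mags[k] * signs[k], "direct"))
                k += 1
                if k == n_true:
                    break
            if k < n_true:
                raise ValueError(
                    f"unique_genes: only {k} disjoint CpG-gene pairs available "
                    f"for {n_true} requested effects"
                )
        else:
            chosen = rng.choice(np.sort(cpgs_with_pairs), size=n_true, replace=False)
            by_cpg = pairs.groupby("cpg_id")["gene_id"]
            for k, cpg in enumerate(chosen):
                gene = rng.choice(np.sort(by_cpg.get_group(cpg).to_numpy()))
                truth_rows.append((cpg, gene, mags[k] * signs[k], "direct"))
    truth = pd.DataFrame(truth_rows, columns=["cpg_id", "gene_id", "true_beta", "mechanism"])

    # --- expression ---
    expr_arr = rng.normal(spec.expr_baseline_mean, spec.expr_baseline_sd, size=n_g)[:, None] * np.ones((1, n_s))
    coh_eff_e = rng.normal(0, spec.confound_expr_sd, size=(n_g, n_cohorts))
    expr_arr += coh_eff_e[:, cohort_codes]
    cell_eff_e = rng.normal(0, spec.cell_effect_sd, size=(n_g, len(CELL_TYPES)))
    expr_arr += cell_eff_e @ cells_c.T
    expr_arr += rng.normal(0, 0.1, size=n_g)[:, None] * sex[None, :]
    expr_arr += rng.normal(0, 0.02, size=n_g)[:, None] * age_c[None, :]
    if spec.shared_factor_sd > 0:
        factor = rng.normal(0, 1, size=n_s)
        expr_arr += rng.normal(0, spec.shared_factor_sd, size=n_g)[:, None] * factor[None, :]
    expr = pd.DataFrame(expr_arr, index=genes.index, columns=covars.index)
    gene_loc = {g: i for i, g in enumerate(genes.index)}
    cpg_loc = {c: i for i, c in enumerate(cpgs.index)}
    for row in truth.itertuples(index=False):
        expr.iloc[gene_loc[row.gene_id]] += row.true_beta * meth.iloc[cpg_loc[row.cpg_id]]
    expr += rng.normal(0, spec.noise_sd, size=(n_g, n_s)) if spec.noise_sd > 0 else 0.0
    return meth, expr, truth


def generate_genotypes(
    cpgs: pd.DataFrame,
    meth: pd.DataFrame,
    expr: pd.DataFrame,
    truth: pd.DataFrame,
    chain_spec: ChainSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Attach SNP->CpG->gene causal chains to already-planted cis pairs.

    Each chain adds ``snp_effect_on_meth * dosage`` to the chosen CpG's
    latent (logit) methylation, and propagates the resulting methylation
    change into the target gene's expression through the planted coefficient,
    so the chain is exactly linear through the CpG.

    Returns ``(dosages, snp_annotation, meth, expr, truth)`` with updated
    omics matrices and the truth table augmented with ``snp_id`` and
    mechanism ``snp_driven`` for chained pairs.
    """
    spec = chain_spec or ChainSpec()
    lo, hi = spec.maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if spec.n_chains > len(truth):
        raise ValueError("cannot attach more chains than planted CpG-gene pairs")
    rng = np.random.default_rng(seed)
    n_s = meth.shape[1]

    n_snps = spec.n_chains + spec.n_null_snps
    mafs = rng.uniform(lo, hi, size=n_snps)
    dos = rng.binomial(2, mafs[:, None], size=(n_snps, n_s)).astype(float)
    snp_ids = [f"rs{i:06d}" for i in range(n_snps)]

    meth = meth.copy()
    expr = expr.copy()
    truth = truth.copy()
    truth["snp_id"] = pd.NA
    chrom = []
    pos = []
    chain_rows = (
        rng.choice(len(truth), size=spec.n_chains, replace=False) if spec.n_chains else np.array([], int)
    )
    for k in range(n_snps):
        if k < spec.n_chains:
            ti = int(chain_rows[k])
            cpg = truth.iloc[ti]["cpg_id"]
            c = cpgs.loc[cpg]
            chrom.append(str(c["chrom"]))
            pos.append(int(c["pos"]) + int(rng.integers(-10_000, 10_001)))
            # copy: .to_numpy() can be a view that the .loc assignment mutates
            old = meth.loc[cpg].to_numpy().copy()
            latent = logit(np.clip(old, 1e-6, 1 - 1e-6))
            new = expit(latent + spec.snp_effect_on_meth * dos[k])
            meth.loc[cpg] = new
            gene = truth.iloc[ti]["gene_id"]
            expr.loc[gene] = expr.loc[gene].to_numpy() + truth.iloc[ti]["true_beta"] * (new - old)
            truth.iloc[ti, truth.columns.get_loc("snp_id")] = snp_ids[k]
            truth.iloc[ti, truth.columns.get_loc("mechanism")] = "snp_driven"
        else:
            chrom.append(str(rng.choice(sorted(cpgs["chrom"].astype(str).unique()))))
            pos.append(int(rng.integers(1, cpgs["pos"].max())))
    dosages = pd.DataFrame(dos, index=pd.Index(snp_ids, name="snp_id"), columns=meth.columns)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": np.array(pos, dtype=np.int64), "maf": mafs},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return dosages, snps, meth, expr, truth


def generate_cpg_metadata(
    cpgs: pd.DataFrame,
    true_cpgs: set[str] | None = None,
    seed: int = 0,
    icc_shift: float = 0.15,
    state_enrichment: float = 2.0,
) -> pd.DataFrame:
    """Fabricate optional CpG metadata (ICC, heritability, island position,
    chromatin-state flags, age-change flags), optionally dependent on truth
    status so enrichment analyses have signal to find.

    ``icc_shift`` raises the mean ICC of true eCpGs; ``state_enrichment``
    multiplies their odds of carrying the active-promoter/enhancer flags.
    """
    rng = np.random.default_rng(seed)
    n = len(cpgs)
    is_true = cpgs.index.isin(sorted(true_cpgs)) if true_cpgs else np.zeros(n, bool)
    out = cpgs.copy()
    icc = rng.beta(2.0, 3.0, size=n)
    out["icc"] = np.clip(icc + np.where(is_true, icc_shift, 0.0), 0, 1)
    h2 = rng.beta(2.0, 5.0, size=n)
    out["heritability_total"] = np.clip(h2 + np.where(is_true, 0.1, 0.0), 0, 1)
    out["heritability_snp"] = out["heritability_total"] * rng.uniform(0.3, 0.9, size=n)
    out["island_rel"] = rng.choice(ISLAND_CATEGORIES, size=n, p=[0.3, 0.1, 0.1, 0.05, 0.05, 0.4])
    base_p = {"TssA": 0.15, "TssAFlnk": 0.1, "Tx": 0.2, "Enh": 0.15, "EnhG": 0.05, "ReprPC": 0.1, "Quies": 0.4}
    for state in CHROMATIN_STATES:
        p = np.full(n, base_p[state])
        if state in ("TssA", "Enh"):
            odds = p / (1 - p) * np.where(is_true, state_enrichment, 1.0)
            p = odds / (1 + odds)
        out[f"state_{state}"] = rng.random(n) < p
    out["age_change"] = rng.choice(["increase", "decrease", "stable"], size=n, p=[0.15, 0.15, 0.7])
    return out


@dataclass
class SimDataset:
    """Everything one simulated study produces, sample-aligned."""

    cpgs: pd.DataFrame
    genes: pd.DataFrame
    covars: pd.DataFrame
    meth: pd.DataFrame
    expr: pd.DataFrame
    truth: pd.DataFrame
    dosages: pd.DataFrame | None = None
    snps: pd.DataFrame | None = None


@dataclass(frozen=True)
class SimConfig:
    n_cpgs: int = 2000
    n_genes: int = 200
    n_samples: int = 300
    n_cohorts: int = 6
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    window_bp: int = 500_000
    effect: EffectSpec = field(default_factory=EffectSpec)
    chains: ChainSpec | None = None
    with_metadata: bool = True


def simulate_dataset(config: SimConfig | None = None, seed: int = 0) -> SimDataset:
    """Run the full generation pipeline under a single master seed.

    Per-stage seeds are derived from the master seed by fixed offsets so
    stages remain individually reproducible.
    """
    cfg = config or SimConfig()
    cpgs, genes = generate_annotation(
        cfg.n_cpgs, cfg.n_genes, cfg.chrom_lengths, seed=seed, window_bp=cfg.window_bp
    )
    covars = generate_covariates(cfg.n_samples, cfg.n_cohorts, seed=seed + 1)
    meth, expr, truth = generate_omics(
        cpgs, genes, covars, cfg.effect, seed=seed + 2, window_bp=cfg.window_bp
    )
    dosages = snps = None
    if cfg.chains is not None:
        dosages, snps, meth, expr, truth = generate_genotypes(
            cpgs, meth, expr, truth, cfg.chains, seed=seed + 3
        )
    if cfg.with_metadata:
        cpgs = generate_cpg_metadata(cpgs, set(truth["cpg_id"]), seed=seed + 4)
    return SimDataset(cpgs, genes, covars, meth, expr, truth, dosages, snps)


def annotate_cpg_symbols(
    cpgs: pd.DataFrame, genes: pd.DataFrame, max_dist: int = 1500
) -> dict[str, set[str]]:
    """Map each CpG to symbols of genes whose body (padded by ``max_dist`` bp)
    contains it — the closest-gene style annotation used on arrays."""
    out: dict[str, set[str]] = {c: set() for c in cpgs.index}
    for chrom, gsub in genes.groupby(genes["chrom"].astype(str)):
        csub = cpgs[cpgs["chrom"].astype(str) == chrom]
        pos = csub["pos"].to_numpy()
        for gene_id, g in gsub.iterrows():
            hit = (pos >= g["start"] - max_dist) & (pos <= g["end"] + max_dist)
            syms = set(str(g["symbols"]).split(";")) if g["symbols"] else set()
            for c in csub.index[hit]:
                out[c] |= syms
    return out
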