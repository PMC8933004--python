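"""End-to-end orchestration: simulate -> pair -> associate -> discover ->
enrich -> trios -> compare, with a manifest for reproducibility auditing.

A single master seed fans out to per-stage seeds by fixed offsets
(documented in the synthetic module), so a rerun with the same config
reproduces every output byte-for-byte; the manifest records SHA-256
digests of all stage outputs to make that checkable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .association import run_model
from .catalogue import classify_ecpgs, summarize_catalogue
from .cis import pair_cis
from .compare import classify_shared, dedupe_min_p, explode_symbols
from .enrichment import chisq_enrichment, methylation_level_category, reliability_filter
from .permutation import discover
from .simulate import ChainSpec, EffectSpec, SimConfig, simulate_dataset
from .trios import build_trios, run_qtl, trio_summary

ALL_STAGES = ["simulate", "pair", "associate", "discover", "enrich", "trios", "compare"]


@dataclass
class RunConfig:
    seed: int = 0
    n_cpgs: int = 1000
    n_genes: int = 100
    n_samples: int = 200
    window_bp: int = 500_000
    n_perm: int = 100
    alpha: float = 0.05
    model: str = "cell_adjusted"
    p_thresh_qtl: float = 1e-7
    p_thresh_shared: float = 1e-5
    n_chains: int = 10
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    adult_catalogue: str | None = None  # path; compare runs only when set

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, outdir) -> dict:
    """Execute the configured stages into ``outdir``; returns the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": [], "skipped": [], "outputs": {}}
    stages = list(config.stages)

    def record(name: str, *paths: Path):
        manifest["stages"].append(name)
        for p in paths:
            manifest["outputs"][p.name] = _digest(p)

    if "simulate" in stages:
        chains = ChainSpec(n_chains=config.n_chains) if config.n_chains > 0 else None
        sim = simulate_dataset(
            SimConfig(
                n_cpgs=config.n_cpgs,
                n_genes=config.n_genes,
                n_samples=config.n_samples,
                window_bp=config.window_bp,
                chains=chains,
            ),
            seed=config.seed,
        )
        io.write_annotation(sim.cpgs, out / "cpgs.tsv")
        io.write_annotation(sim.genes, out / "genes.tsv")
        io.write_matrix(sim.covars, out / "covars.tsv")
        io.write_matrix(sim.meth, out / "meth.tsv")
        io.write_matrix(sim.expr, out / "expr.tsv")
        io.write_table(sim.truth, out / "truth.tsv")
        paths = [out / n for n in ("cpgs.tsv", "genes.tsv", "covars.tsv", "meth.tsv", "expr.tsv", "truth.tsv")]
        if sim.dosages is not None:
            io.write_matrix(sim.dosages, out / "dosages.tsv")
            io.write_annotation(sim.snps, out / "snps.tsv")
            paths += [out / "dosages.tsv", out / "snps.tsv"]
        record("simulate", *paths)

    def need(name: str) -> Path:
        p = out / name
        if not p.exists():
            raise FileNotFoundError(f"missing upstream output {name}; run its stage first")
        return p

    if "pair" in stages:
        cpgs = io.read_annotation(need("cpgs.tsv"))
        genes = io.read_annotation(need("genes.tsv"))
        pairs = pair_cis(cpgs, genes, config.window_bp)
        io.write_table(pairs, out / "pairs.tsv")
        record("pair", out / "pairs.tsv")

    if "associate" in stages:
        pairs = io.read_table(need("pairs.tsv"))
        meth = io.read_matrix(need("meth.tsv"))
        expr = io.read_matrix(need("expr.tsv"))
        covars = io.read_matrix(need("covars.tsv"))
        assoc = run_model(pairs, meth, expr, covars, model=config.model)
        io.write_table(assoc, out / "associations.tsv")
        record("associate", out / "associations.tsv")

    if "discover" in stages:
        pairs = io.read_table(need("pairs.tsv"))
        meth = io.read_matrix(need("meth.tsv"))
        expr = io.read_matrix(need("expr.tsv"))
        covars = io.read_matrix(need("covars.tsv"))
        res = discover(
            pairs, meth, expr, covars,
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed, model=config.model,
        )
        io.write_table(res.eqtms, out / "eqtms.tsv")
        io.write_matrix(res.nulls, out / "cpg_nulls.tsv")
        io.write_json(
            {
                "alpha": res.thresholds.alpha,
                "p_emp_genomewide": res.thresholds.p_emp_genomewide,
                "nominal_p": res.thresholds.nominal_p,
            },
            out / "thresholds.json",
        )
        types = classify_ecpgs(res.eqtms)
        types.to_csv(out / "ecpg_types.tsv", sep="\t")
        io.write_json(summarize_catalogue(res.eqtms), out / "catalogue_summary.json")
        record(
            "discover",
            out / "eqtms.tsv", out / "cpg_nulls.tsv", out / "thresholds.json",
            out / "ecpg_types.tsv", out / "catalogue_summary.json",
        )

    if "enrich" in stages:
        cpgs = io.read_annotation(need("cpgs.tsv"))
        meth = io.read_matrix(need("meth.tsv"))
        eqtms = io.read_table(need("eqtms.tsv"))
        is_ecpg = cpgs.index.isin(eqtms["cpg_id"]) if not eqtms.empty else np.zeros(len(cpgs), bool)
        rows = []
        med = meth.median(axis=1).reindex(cpgs.index)
        bins = med.map(methylation_level_category)
        categories: dict[str, np.ndarray] = {
            f"meth_{lvl}": (bins == lvl).to_numpy() for lvl in ("low", "medium", "high")
        }
        if "island_rel" in cpgs:
            for cat in sorted(cpgs["island_rel"].dropna().unique()):
                categories[f"island_{cat}"] = (cpgs["island_rel"] == cat).to_numpy()
        for col in cpgs.columns:
            if col.startswith("state_"):
                categories[col] = cpgs[col].astype(bool).to_numpy()
        for name, flags in categories.items():
            try:
                r = chisq_enrichment(is_ecpg, flags)
            except ValueError:
                continue
            a, b = r["counts"][0]
            c, d = r["counts"][1]
            rows.append({"category": name, "odds_ratio": r["odds_ratio"], "p": r["p"],
                         "a": a, "b": b, "c": c, "d": d})
        enr = pd.DataFrame(rows)
        io.write_table(enr, out / "enrichment.tsv")
        extra = [out / "enrichment.tsv"]
        if "icc" in cpgs.columns:
            reliable = reliability_filter(cpgs)
            io.write_json(
                {"n_reliable": int(len(reliable)), "n_total": int(len(cpgs))},
                out / "reliability.json",
            )
            extra.append(out / "reliability.json")
        record("enrich", *extra)

    if "trios" in stages:
        if not (out / "dosages.tsv").exists():
            manifest["skipped"].append("trios (no genotypes)")
        else:
            dosages = io.read_matrix(need("dosages.tsv"))
            snps = io.read_annotation(need("snps.tsv"))
            cpgs = io.read_annotation(need("cpgs.tsv"))
            meth = io.read_matrix(need("meth.tsv"))
            expr = io.read_matrix(need("expr.tsv"))
            covars = io.read_matrix(need("covars.tsv"))
            eqtms = io.read_table(need("eqtms.tsv"))
            me_cand = _snp_cpg_candidates(snps, cpgs, window_bp=config.window_bp)
            meqtls = run_qtl(me_cand, dosages, meth, covars, "meQTL")
            eq_cand = (
                meqtls[meqtls["p"] < config.p_thresh_qtl][["snp_id", "target_id"]]
                .rename(columns={"target_id": "cpg_id"})
                .merge(eqtms[["cpg_id", "gene_id"]], on="cpg_id")[["snp_id", "gene_id"]]
                .drop_duplicates()
                .rename(columns={"gene_id": "target_id"})
            )
            eqtls = run_qtl(eq_cand, dosages, expr, covars, "eQTL")
            trios = build_trios(meqtls, eqtms, eqtls, p_thresh=config.p_thresh_qtl)
            io.write_table(meqtls, out / "meqtls.tsv")
            io.write_table(eqtls, out / "eqtls.tsv")
            io.write_table(trios, out / "trios.tsv")
            io.write_json(trio_summary(trios), out / "trio_summary.json")
            record("trios", out / "meqtls.tsv", out / "eqtls.tsv", out / "trios.tsv",
                   out / "trio_summary.json")

    if "compare" in stages:
        if not config.adult_catalogue:
            manifest["skipped"].append("compare (no adult catalogue configured)")
        else:
            eqtms = io.read_table(need("eqtms.tsv"))
            genes = io.read_annotation(need("genes.tsv"))
            child = eqtms[["cpg_id", "gene_id", "beta", "p"]].copy()
            child["symbol"] = genes["symbols"].reindex(child["gene_id"]).to_numpy()
            child = dedupe_min_p(explode_symbols(child))
            adult = dedupe_min_p(explode_symbols(io.read_table(config.adult_catalogue)))
            labelled = classify_shared(child, adult, p_thresh=config.p_thresh_shared)
            io.write_table(labelled, out / "age_classification.tsv")
            record("compare", out / "age_classification.tsv")

    io.write_json(manifest, out / "manifest.json")
    return manifest


def _snp_cpg_candidates(snps: pd.DataFrame, cpgs: pd.DataFrame, window_bp: int) -> pd.DataFrame:
    """All same-chromosome SNP-CpG pairs within the window."""
    rows = []
    for chrom, ssub in snps.groupby(snps["chrom"].astype(str)):
        csub = cpgs[cpgs["chrom"].astype(str) == chrom]
        if csub.empty:
            continue
        pos = csub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        ids = csub.index.to_numpy()[order]
        lo = np.searchsorted(pos, ssub["pos"].to_numpy() - window_bp, side="left")
        hi = np.searchsorted(pos, ssub["pos"].to_numpy() + window_bp, side="right")
        for i, snp in enumerate(ssub.index):
            for c in ids[lo[i]:hi[i]]:
                rows.append((snp, c))
    return pd.DataFrame(rows, columns=["snp_id", "target_id"])
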