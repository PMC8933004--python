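"""meQTL/eQTL scans and direction-consistent SNP-CpG-gene trio assembly.

A SNP is an meQTL for a CpG (or an eQTL for a gene) when the OLS
coefficient of the target on allelic dosage — adjusted for the same
covariates as the eQTM model plus optional genotype principal components —
passes a genome-wide threshold (p < 1e-7 by default).  A trio is
*consistent* when sign(meQTL) x sign(eQTM) == sign(eQTL), i.e. the SNP's
expression effect matches the one implied by routing through methylation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import PairScanEngine, design_matrix, fit_pair

QTL_P_THRESHOLD = 1e-7


def genotype_pcs(dosages: pd.DataFrame, n_pcs: int = 20) -> pd.DataFrame:
    """Principal components of the centered dosage matrix (samples x PCs),
    via truncated SVD; PC columns are named pc1..pcK."""
    D = dosages.to_numpy(float)
    D = D - D.mean(axis=1, keepdims=True)
    k = min(n_pcs, min(D.shape) - 1)
    U, s, Vt = np.linalg.svd(D, full_matrices=False)
    scores = (Vt[:k].T * s[:k])
    return pd.DataFrame(scores, index=dosages.columns, columns=[f"pc{i + 1}" for i in range(k)])


def _covars_with_pcs(covars: pd.DataFrame, pcs: pd.DataFrame | None) -> pd.DataFrame:
    if pcs is None:
        return covars
    return covars.join(pcs)


def test_qtl(
    dosage, target, covars: pd.DataFrame, kind: str, pcs: pd.DataFrame | None = None
) -> dict:
    """Single SNP-target association (kind: 'meQTL' or 'eQTL')."""
    if kind not in ("meQTL", "eQTL"):
        raise ValueError("kind must be 'meQTL' or 'eQTL'")
    d = np.asarray(dosage, float)
    if np.ptp(d[np.isfinite(d)]) == 0:
        raise ValueError("constant dosage vector")
    res = fit_pair(d, np.asarray(target, float), _covars_with_pcs(covars, pcs))
    res["kind"] = kind
    return res


def run_qtl(
    candidates: pd.DataFrame,
    dosages: pd.DataFrame,
    targets: pd.DataFrame,
    covars: pd.DataFrame,
    kind: str,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Scan candidate (snp_id, target_id) pairs with the shared OLS engine.

    ``targets`` is the methylation matrix for meQTLs or the expression
    matrix for eQTLs; results are identical to per-pair ``test_qtl`` fits.
    """
    if kind not in ("meQTL", "eQTL"):
        raise ValueError("kind must be 'meQTL' or 'eQTL'")
    if candidates.empty:
        return pd.DataFrame(columns=["snp_id", "target_id", "beta", "se", "tstat", "p", "kind"])
    pairs = candidates.rename(columns={"snp_id": "cpg_id", "target_id": "gene_id"})
    engine = PairScanEngine(pairs, dosages, targets, _covars_with_pcs(covars, pcs))
    out = engine.full_results().rename(columns={"cpg_id": "snp_id", "gene_id": "target_id"})
    out["kind"] = kind
    return out.drop(columns=["model"])


def build_trios(
    meqtls: pd.DataFrame,
    eqtms: pd.DataFrame,
    eqtls: pd.DataFrame,
    p_thresh: float = QTL_P_THRESHOLD,
) -> pd.DataFrame:
    """Join significant meQTLs and eQTLs through the eQTM catalogue.

    Every SNP-CpG-gene triple where the SNP is an meQTL for the CpG and an
    eQTL for that CpG's eGene is emitted with a ``consistent`` flag
    (sign(b_meqtl) * sign(b_eqtm) == sign(b_eqtl); an exactly-zero
    coefficient is treated as inconsistent).
    """
    me = meqtls[meqtls["p"] < p_thresh][["snp_id", "target_id", "beta"]].rename(
        columns={"target_id": "cpg_id", "beta": "b_meqtl"}
    )
    eq = eqtls[eqtls["p"] < p_thresh][["snp_id", "target_id", "beta"]].rename(
        columns={"target_id": "gene_id", "beta": "b_eqtl"}
    )
    em = eqtms[["cpg_id", "gene_id", "beta"]].rename(columns={"beta": "b_eqtm"})
    trios = me.merge(em, on="cpg_id").merge(eq, on=["snp_id", "gene_id"])
    if trios.empty:
        return pd.DataFrame(
            columns=["snp_id", "cpg_id", "gene_id", "b_meqtl", "b_eqtm", "b_eqtl", "consistent"]
        )
    s = np.sign(trios["b_meqtl"]) * np.sign(trios["b_eqtm"])
    trios["consistent"] = (s == np.sign(trios["b_eqtl"])) & (s != 0) & (trios["b_eqtl"] != 0)
    return trios.reset_index(drop=True)


def trio_summary(trios: pd.DataFrame) -> dict:
    """Counts of consistent/inconsistent trios and unique members."""
    if trios.empty:
        return {
            "n_trios_consistent": 0,
            "n_trios_inconsistent": 0,
            "n_unique_eqtms": 0,
            "n_unique_ecpgs": 0,
            "n_unique_egenes": 0,
            "median_trios_per_ecpg": 0.0,
            "median_trios_per_egene": 0.0,
        }
    return {
        "n_trios_consistent": int(trios["consistent"].sum()),
        "n_trios_inconsistent": int((~trios["consistent"]).sum()),
        "n_unique_eqtms": int(trios[["cpg_id", "gene_id"]].drop_duplicates().shape[0]),
        "n_unique_ecpgs": int(trios["cpg_id"].nunique()),
        "n_unique_egenes": int(trios["gene_id"].nunique()),
        "median_trios_per_ecpg": float(trios.groupby("cpg_id").size().median()),
        "median_trios_per_egene": float(trios.groupby("gene_id").size().median()),
    }
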