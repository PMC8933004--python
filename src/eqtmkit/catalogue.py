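"""Classification and summary statistics for a significant eQTM catalogue.

eCpGs are typed along two axes: multiplicity (mono = exactly one eGene,
multi = several) and direction (inverse if every effect is negative,
positive if every effect is positive, bivalent if mixed — so a mono eCpG
can never be bivalent).  Distances are signed base pairs from the eGene's
TSS in its transcriptional direction; effect sizes are reported as log2
fold change per 0.1-point methylation increase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import effect_log2fc_per_10pct
from .enrichment import chisq_enrichment


def classify_ecpgs(records: pd.DataFrame) -> pd.DataFrame:
    """Type each eCpG by eGene count and sign pattern of its effects."""
    if records.empty:
        return pd.DataFrame(columns=["multiplicity", "direction", "n_egenes"])
    def _one(g: pd.DataFrame) -> pd.Series:
        n = g["gene_id"].nunique()
        signs = set(np.sign(g["beta"]))
        if signs <= {-1.0}:
            direction = "inverse"
        elif signs <= {1.0}:
            direction = "positive"
        else:
            direction = "bivalent"
        return pd.Series(
            {"multiplicity": "mono" if n == 1 else "multi", "direction": direction, "n_egenes": n}
        )
    out = records.groupby("cpg_id").apply(_one, include_groups=False)
    out.index.name = "cpg_id"
    return out


def summarize_catalogue(records: pd.DataFrame) -> dict:
    """Headline catalogue statistics.

    Medians and IQRs use linear interpolation.  ``pct_within_250kb`` is the
    fraction of eQTMs with |TSS distance| < 250 kb; effect sizes are
    |log2FC per 0.1 methylation|.
    """
    if records.empty:
        return {"n_eqtms": 0, "n_ecpgs": 0, "n_egenes": 0}
    dist = records["signed_dist"].to_numpy(float)
    eff = np.abs(effect_log2fc_per_10pct(records["beta"].to_numpy(float)))
    inverse = records["beta"].to_numpy() < 0
    def med_iqr(x):
        if len(x) == 0:
            return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return {
        "n_eqtms": int(len(records)),
        "n_ecpgs": int(records["cpg_id"].nunique()),
        "n_egenes": int(records["gene_id"].nunique()),
        "pct_inverse": float(100.0 * inverse.mean()),
        "signed_dist": med_iqr(dist),
        "signed_dist_inverse": med_iqr(dist[inverse]),
        "signed_dist_positive": med_iqr(dist[~inverse]),
        "abs_dist_median": float(np.median(np.abs(dist))),
        "pct_within_250kb": float(100.0 * np.mean(np.abs(dist) < 250_000)),
        "median_abs_log2fc_per_10pct": float(np.median(eff)),
        "pct_effect_below_0.5": float(100.0 * np.mean(eff < 0.5)),
        "median_egenes_per_ecpg": float(records.groupby("cpg_id")["gene_id"].nunique().median()),
        "median_ecpgs_per_egene": float(records.groupby("gene_id")["cpg_id"].nunique().median()),
    }


def distance_effect_trend(records: pd.DataFrame, drop_zero: bool = False) -> dict:
    """OLS of |log2FC per 0.1| on log10(|TSS distance|).

    Records at distance 0 are assigned |distance| = 1 bp before the log
    (``drop_zero=True`` removes them instead).
    """
    if records.empty or (records["signed_dist"] == 0).all():
        raise ValueError("need records at nonzero distance")
    d = np.abs(records["signed_dist"].to_numpy(float))
    y = np.abs(effect_log2fc_per_10pct(records["beta"].to_numpy(float)))
    if drop_zero:
        keep = d > 0
        d, y = d[keep], y[keep]
    else:
        d = np.maximum(d, 1.0)
    if len(d) < 3:
        raise ValueError("need at least 3 records")
    res = stats.linregress(np.log10(d), y)
    return {"slope": float(res.slope), "p": float(res.pvalue), "r": float(res.rvalue)}


def closest_gene_concordance(
    records: pd.DataFrame,
    cpg_symbols: dict[str, set[str]],
    gene_symbols: dict[str, set[str]],
    all_pairs: pd.DataFrame,
    pair_positions: pd.DataFrame | None = None,
) -> dict:
    """How much of the catalogue the closest-gene CpG annotation captures.

    A pair is *comparable* when the CpG's annotated symbols intersect the
    gene's; an eCpG is *concordant* when at least one of its eGenes shares a
    symbol with it.  Same-symbol enrichment of eQTMs is a 2x2 chi-square
    over the full candidate pair universe.  If ``pair_positions`` (columns
    cpg_id, gene_id, relpos) is given, pairs are expanded to one entry per
    relative gene position and enrichment is computed per position over the
    expanded entries.
    """
    def shares(cpg, gene):
        return bool(cpg_symbols.get(cpg, set()) & gene_symbols.get(gene, set()))

    eqtm_keys = set(zip(records["cpg_id"], records["gene_id"]))
    comparable = all_pairs.apply(lambda r: shares(r["cpg_id"], r["gene_id"]), axis=1).to_numpy()
    is_eqtm = all_pairs.apply(lambda r: (r["cpg_id"], r["gene_id"]) in eqtm_keys, axis=1).to_numpy()

    ecpg_comp: set[str] = set()
    ecpg_conc: set[str] = set()
    for cpg, g in records.groupby("cpg_id"):
        if cpg_symbols.get(cpg):
            ecpg_comp.add(cpg)
            if any(shares(cpg, gene) for gene in g["gene_id"]):
                ecpg_conc.add(cpg)
    out = {
        "n_comparable_pairs": int(comparable.sum()),
        "n_ecpgs_comparable": len(ecpg_comp),
        "n_ecpgs_concordant": len(ecpg_conc),
    }
    try:
        enr = chisq_enrichment(pd.Series(is_eqtm), pd.Series(comparable))
        out["same_symbol_or"] = enr["odds_ratio"]
        out["same_symbol_p"] = enr["p"]
    except ValueError:
        out["same_symbol_or"] = float("nan")
        out["same_symbol_p"] = float("nan")
    if pair_positions is not None and not pair_positions.empty:
        exp = pair_positions.copy()
        exp["is_eqtm"] = [
            (c, g) in eqtm_keys for c, g in zip(exp["cpg_id"], exp["gene_id"])
        ]
        rows = []
        for pos in sorted(exp["relpos"].unique()):
            try:
                r = chisq_enrichment(exp["is_eqtm"], exp["relpos"] == pos)
                rows.append({"relpos": pos, "odds_ratio": r["odds_ratio"], "p": r["p"]})
            except ValueError:
                continue
        out["relative_position_enrichment"] = pd.DataFrame(rows)
        out["n_expanded_entries"] = int(len(exp))
    return out
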