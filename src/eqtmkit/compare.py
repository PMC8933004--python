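"""Cross-catalogue comparison of child vs adult blood eQTMs.

Catalogues from different platforms are matched on (CpG id, gene symbol).
Entries annotated to several symbols are exploded to one row per symbol;
when one key maps to several rows within a source, only the row with the
smallest p-value is kept.  A child association is *age-shared* when any
adult source carries the same (CpG, symbol) at p below the sharing
threshold (1e-5 by default), otherwise *cohort-specific*.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SHARED_P_THRESHOLD = 1e-5


def explode_symbols(entries: pd.DataFrame, symbol_col: str = "symbol", sep: str = ";") -> pd.DataFrame:
    """One row per (cpg, symbol); multi-symbol strings are split on ``sep``."""
    out = entries.copy()
    out[symbol_col] = out[symbol_col].astype(str).str.split(sep)
    out = out.explode(symbol_col, ignore_index=True)
    return out[out[symbol_col].astype(bool)]


def dedupe_min_p(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep, per (cpg_id, symbol[, source]), the row with the smallest p;
    ties broken by stable input order."""
    if entries.empty:
        return entries.copy()
    keys = [k for k in ("cpg_id", "symbol", "source") if k in entries.columns]
    idx = entries.groupby(keys, sort=False)["p"].idxmin()
    return entries.loc[np.sort(idx.to_numpy())].reset_index(drop=True)


def classify_shared(
    child: pd.DataFrame, adult: pd.DataFrame, p_thresh: float = SHARED_P_THRESHOLD
) -> pd.DataFrame:
    """Label each child entry age_shared or cohort_specific.

    Both inputs must already be deduplicated; matching is exact and
    case-sensitive on (cpg_id, symbol).
    """
    hits = adult[adult["p"] < p_thresh][["cpg_id", "symbol"]].drop_duplicates()
    key = pd.MultiIndex.from_frame(child[["cpg_id", "symbol"]])
    shared = key.isin(pd.MultiIndex.from_frame(hits))
    out = child.copy()
    out["age_class"] = np.where(shared, "age_shared", "cohort_specific")
    return out


def shared_effect_stats(matched: pd.DataFrame, child_col: str = "beta_child", adult_col: str = "beta_adult") -> dict:
    """Direction agreement and Pearson correlation of matched effect sizes."""
    b1 = matched[child_col].to_numpy(float)
    b2 = matched[adult_col].to_numpy(float)
    if len(b1) == 0:
        return {"pct_same_direction": float("nan"), "pearson_r": float("nan"), "n": 0}
    same = np.sign(b1) == np.sign(b2)
    r = float(np.corrcoef(b1, b2)[0, 1]) if len(b1) >= 3 else float("nan")
    return {"pct_same_direction": float(100.0 * same.mean()), "pearson_r": r, "n": int(len(b1))}
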