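"""Estimator-style front ends for the discovery scans.

`CisEQTMMapper` wraps pair enumeration, the covariate-adjusted association
scan and the permutation/beta/BH multiple-testing procedure behind a
scikit-learn estimator interface (get_params/set_params, fit, fitted
attributes with trailing underscores), so runs compose with sklearn
tooling.  `QTLScanner` does the same for meQTL/eQTL dosage scans.  Both are
thin shells over the module-level functions.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from . import catalogue, cis, permutation, trios


class CisEQTMMapper(BaseEstimator):
    """Discover cis eQTMs: pair CpGs to gene TSSs, fit adjusted linear
    models, and control FDR at the CpG level by permutation.

    Parameters
    ----------
    window_bp : half-width of the cis window around each TSS (bp).
    n_perm : number of permuted expression datasets for the null.
    alpha : CpG-level FDR target for Benjamini-Hochberg.
    model : 'cell_adjusted' (default) or 'cell_unadjusted'.
    random_state : master seed for the permutation stream.
    strict_window : use strict inequality at the window boundary.
    rule : genome-wide threshold rule, 'midpoint' or 'largest'.

    Attributes (after fit)
    ----------------------
    pairs_ : candidate pair universe with signed TSS distances.
    associations_ : per-pair regression results.
    nulls_ : per-CpG beta-null fits and empirical p-values.
    thresholds_ : genome-wide and per-CpG nominal thresholds.
    eqtms_ : significant eQTM records.
    ecpg_types_ : mono/multi x inverse/positive/bivalent typology.
    summary_ : headline catalogue statistics.
    """

    def __init__(
        self,
        window_bp: int = 500_000,
        n_perm: int = 100,
        alpha: float = 0.05,
        model: str = "cell_adjusted",
        random_state: int = 0,
        strict_window: bool = False,
        rule: str = "midpoint",
    ):
        self.window_bp = window_bp
        self.n_perm = n_perm
        self.alpha = alpha
        self.model = model
        self.random_state = random_state
        self.strict_window = strict_window
        self.rule = rule

    def fit(self, meth: pd.DataFrame, expr: pd.DataFrame, covars: pd.DataFrame,
            cpgs: pd.DataFrame, genes: pd.DataFrame):
        self.pairs_ = cis.pair_cis(cpgs, genes, self.window_bp, strict=self.strict_window)
        result = permutation.discover(
            self.pairs_, meth, expr, covars,
            n_perm=self.n_perm, alpha=self.alpha, seed=self.random_state,
            model=self.model, rule=self.rule,
        )
        self.associations_ = result.associations
        self.nulls_ = result.nulls
        self.thresholds_ = result.thresholds
        self.eqtms_ = result.eqtms
        self.min_p_perm_ = result.min_p_perm
        self.ecpg_types_ = catalogue.classify_ecpgs(self.eqtms_)
        self.summary_ = catalogue.summarize_catalogue(self.eqtms_)
        return self

    def transform(self, assoc: pd.DataFrame) -> pd.DataFrame:
        """Apply the fitted per-CpG nominal thresholds to an association
        table (e.g. the unadjusted model's results)."""
        return permutation.call_eqtms(assoc, self.thresholds_)


class QTLScanner(BaseEstimator):
    """Scan candidate SNP-target pairs for meQTLs or eQTLs.

    Fitted attribute ``results_`` holds one row per candidate with the
    per-allele coefficient, SE and two-sided p-value.
    """

    def __init__(self, kind: str = "meQTL", n_pcs: int = 0):
        self.kind = kind
        self.n_pcs = n_pcs

    def fit(self, candidates: pd.DataFrame, dosages: pd.DataFrame,
            targets: pd.DataFrame, covars: pd.DataFrame):
        pcs = trios.genotype_pcs(dosages, self.n_pcs) if self.n_pcs else None
        self.pcs_ = pcs
        self.results_ = trios.run_qtl(candidates, dosages, targets, covars, self.kind, pcs)
        return self
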