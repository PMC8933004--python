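"""Strand-aware TSS definition and enumeration of cis CpG-gene candidate pairs.

A gene's transcription start site (TSS) is its ``start`` coordinate on the
``+`` strand and its ``end`` coordinate on the ``-`` strand.  Each gene is
paired with every autosomal CpG within ``window_bp`` of its TSS (a 1 Mb
window centered on the TSS by default).  Coordinates are 1-based and
inclusive throughout.

Signed distances are oriented in the gene's transcriptional direction:
positive means the CpG lies downstream of the TSS, negative upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AUTOSOMES = frozenset(str(i) for i in range(1, 23))

DEFAULT_WINDOW_BP = 500_000


def tss(gene) -> int:
    """TSS of a single gene record (mapping or Series with start/end/strand)."""
    strand = gene["strand"]
    if strand == "+":
        return int(gene["start"])
    if strand == "-":
        return int(gene["end"])
    raise ValueError(f"unknown strand {strand!r}; expected '+' or '-'")


def tss_positions(genes: pd.DataFrame) -> pd.Series:
    """Vectorized TSS for an annotation table (index gene_id)."""
    bad = ~genes["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand values: {genes.loc[bad, 'strand'].unique()!r}")
    return genes["start"].where(genes["strand"] == "+", genes["end"]).astype(np.int64)


def signed_distance(cpg_pos: int, gene) -> int:
    """CpG position relative to the gene's TSS, oriented with transcription.

    Positive = downstream of the TSS in the gene's direction.  Raises if the
    CpG and gene sit on different chromosomes (the distance is undefined).
    """
    if "chrom" in gene and "cpg_chrom" in gene:  # pragma: no cover - defensive
        raise TypeError("pass cpg_pos as an integer and gene as a record")
    t = tss(gene)
    d = int(cpg_pos) - t
    return d if gene["strand"] == "+" else -d


def signed_distance_checked(cpg_chrom: str, cpg_pos: int, gene) -> int:
    if str(cpg_chrom) != str(gene["chrom"]):
        raise ValueError("CpG and gene are on different chromosomes")
    return signed_distance(cpg_pos, gene)


def pair_cis(
    cpgs: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    strict: bool = False,
) -> pd.DataFrame:
    """Enumerate all autosomal cis CpG-gene pairs within the TSS window.

    Parameters
    ----------
    cpgs : DataFrame indexed by cpg_id with columns chrom, pos.
    genes : DataFrame indexed by gene_id with columns chrom, start, end, strand.
    window_bp : half-width of the cis window around the TSS.  Membership is
        ``|signed_dist| <= window_bp`` (inclusive); ``strict=True`` switches to
        a strict inequality.
    Returns
    -------
    DataFrame with columns cpg_id, gene_id, signed_dist, sorted by
    (cpg_id, gene_id).  Uses per-chromosome sorted positions and binary
    search, O((C+G) log C) per chromosome.
    """
    if cpgs.empty or genes.empty:
        raise ValueError("annotations must be non-empty")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    cpgs = cpgs[cpgs["chrom"].astype(str).isin(AUTOSOMES)]
    genes = genes[genes["chrom"].astype(str).isin(AUTOSOMES)]
    out_cpg: list[np.ndarray] = []
    out_gene: list[np.ndarray] = []
    out_dist: list[np.ndarray] = []
    for chrom, gsub in genes.groupby(genes["chrom"].astype(str), sort=True):
        csub = cpgs[cpgs["chrom"].astype(str) == chrom]
        if csub.empty:
            continue
        order = np.argsort(csub["pos"].to_numpy(), kind="stable")
        pos = csub["pos"].to_numpy()[order]
        ids = csub.index.to_numpy()[order]
        t = tss_positions(gsub).to_numpy()
        lo = np.searchsorted(pos, t - window_bp, side="left" if not strict else "right")
        hi = np.searchsorted(pos, t + window_bp, side="right" if not strict else "left")
        sign = np.where(gsub["strand"].to_numpy() == "+", 1, -1)
        for gi, gene_id in enumerate(gsub.index):
            a, b = lo[gi], hi[gi]
            if b <= a:
                continue
            out_cpg.append(ids[a:b])
            out_gene.append(np.repeat(gene_id, b - a))
            out_dist.append((pos[a:b] - t[gi]) * sign[gi])
    if not out_cpg:
        return pd.DataFrame(columns=["cpg_id", "gene_id", "signed_dist"])
    pairs = pd.DataFrame(
        {
            "cpg_id": np.concatenate(out_cpg),
            "gene_id": np.concatenate(out_gene),
            "signed_dist": np.concatenate(out_dist).astype(np.int64),
        }
    )
    pairs = pairs.sort_values(["cpg_id", "gene_id"], kind="stable", ignore_index=True)
    return pairs


def pair_counts(pairs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Per-CpG and per-gene pair counts (e.g. for median genes per CpG)."""
    return (
        pairs.groupby("cpg_id").size(),
        pairs.groupby("gene_id").size(),
    )
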