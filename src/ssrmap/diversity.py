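"""Per-locus SSR diversity statistics, allele-sharing distance and the
neighbor-joining tree.

Gene diversity (expected heterozygosity) is 1 - sum(p_i^2) and PIC is
the Botstein informativeness statistic
1 - sum(p_i^2) - 2 * sum_{i<j} p_i^2 p_j^2; both are computed over
amplified alleles only, i.e. null (non-amplified) calls are excluded
from the frequency denominator.  Loci are classed as highly informative
(PIC > 0.5), moderately informative (0.25 < PIC <= 0.5) or slightly
informative (PIC <= 0.25).

For single inbred individuals the classical between-"population"
genetic distances all reduce to allele sharing; the distance used here
is 1 minus the proportion of shared alleles over loci at which both
accessions amplified.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import skbio
from skbio.tree import nj as _skbio_nj

__all__ = ["allele_frequencies", "gene_diversity", "pic",
           "summarize_diversity", "nei_distance", "neighbor_joining",
           "classify_pic"]


def allele_frequencies(genotypes: pd.DataFrame, locus: str) -> pd.Series:
    """Allele frequencies at one locus over amplified calls only."""
    calls = genotypes[locus].dropna()
    if calls.empty:
        raise ValueError(f"locus {locus!r} has no amplified calls")
    freqs = calls.value_counts(normalize=True).sort_index()
    freqs.index = freqs.index.astype(int)
    return freqs


def gene_diversity(freqs) -> float:
    p = np.asarray(freqs, dtype=float)
    return float(1.0 - np.sum(p**2))


def pic(freqs) -> float:
    p = np.asarray(freqs, dtype=float)
    sq = p**2
    # 2*sum_{i<j} p_i^2 p_j^2 = (sum sq)^2 - sum sq^2
    return float(1.0 - sq.sum() - (sq.sum() ** 2 - np.sum(sq**2)))


def classify_pic(value: float) -> str:
    if value > 0.5:
        return "high"
    if value > 0.25:
        return "moderate"
    return "slight"


def summarize_diversity(genotypes: pd.DataFrame):
    """Per-locus diversity table plus a panel summary.

    The summary rounds as conventionally printed: mean alleles per locus
    to 1 decimal, mean gene diversity and PIC to 4 decimals.
    """
    rows = []
    for locus in genotypes.columns:
        freqs = allele_frequencies(genotypes, locus)
        gd = gene_diversity(freqs)
        p = pic(freqs)
        rows.append({
            "locus": locus,
            "n_alleles": len(freqs),
            "major_allele_freq": float(freqs.max()),
            "gene_diversity": gd,
            "pic": p,
            "informativeness": classify_pic(p),
        })
    table = pd.DataFrame(rows)
    counts = table["informativeness"].value_counts()
    summary = {
        "n_loci": len(table),
        "total_alleles": int(table["n_alleles"].sum()),
        "mean_alleles_per_locus": round(float(table["n_alleles"].mean()), 1),
        "mean_gene_diversity": round(float(table["gene_diversity"].mean()), 4),
        "mean_pic": round(float(table["pic"].mean()), 4),
        "n_high": int(counts.get("high", 0)),
        "n_moderate": int(counts.get("moderate", 0)),
        "n_slight": int(counts.get("slight", 0)),
    }
    return table, summary


def nei_distance(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise allele-sharing distance between accessions.

    d(i,j) = 1 - (shared alleles) / (loci where both amplified).
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 accessions")
    X = genotypes.to_numpy(dtype=float, na_value=np.nan)
    amp = ~np.isnan(X)
    co = amp.astype(float) @ amp.astype(float).T
    zero = np.argwhere(co == 0)
    if zero.size:
        i, j = zero[0]
        raise ValueError(
            f"accessions {genotypes.index[i]!r} and {genotypes.index[j]!r} "
            "share no co-amplified locus"
        )
    Xz = np.where(amp, X, np.nan)
    n = len(genotypes)
    shared = np.zeros((n, n))
    # accumulate per-locus equality; loci loop keeps memory at n x n
    for col in range(X.shape[1]):
        c = Xz[:, col]
        eq = (c[:, None] == c[None, :])
        shared += np.where(np.isnan(c[:, None]) | np.isnan(c[None, :]), 0.0, eq)
    d = 1.0 - shared / co
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=genotypes.index, columns=genotypes.index)


def neighbor_joining(dist: pd.DataFrame) -> skbio.TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Exact on additive distance matrices.
    """
    if len(dist) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = skbio.DistanceMatrix(dist.to_numpy(dtype=float), ids=[str(i) for i in dist.index])
    return _skbio_nj(dm, neg_as_zero=True)
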