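"""Multi-allelic linkage disequilibrium: D′, permutation significance,
per-subpopulation scans, and decay regression.

For two multi-allelic loci with allele frequencies p_i, q_j and
two-locus haplotype frequencies x_ij (observable directly in inbreds),
D_ij = x_ij - p_i q_j and D'_ij = D_ij / Dmax(i,j) with the standard
normalisation

    Dmax = min(p_i q_j, (1-p_i)(1-q_j))        if D_ij < 0
    Dmax = min(p_i (1-q_j), (1-p_i) q_j)       if D_ij > 0.

The multi-allelic D′ is the frequency-weighted mean
sum_ij p_i q_j |D'_ij|; on a biallelic pair it equals the classical
|D′|.  Significance comes from permuting one locus's calls across
accessions.  Decay with map distance is summarised by least squares on
D′ = b ln(x) + c over syntenic significant pairs, and the decay
distance is where the fitted curve falls to a critical background D′
(default: the 95th percentile of non-syntenic D′).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["pairwise_dprime", "permutation_pvalue", "ld_scan", "fit_decay",
           "decay_distance", "DecayFit", "DPRIME_BINS"]

DPRIME_BINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def _codes_pair(genotypes: pd.DataFrame, locus_a: str, locus_b: str):
    a = genotypes[locus_a]
    b = genotypes[locus_b]
    keep = a.notna() & b.notna()
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 accessions co-amplified at {locus_a!r}/{locus_b!r}")
    ia = pd.Categorical(a[keep]).codes.astype(np.int64)
    ib = pd.Categorical(b[keep]).codes.astype(np.int64)
    na, nb = ia.max() + 1, ib.max() + 1
    if na < 2:
        raise ValueError(f"locus {locus_a!r} is monomorphic on the co-amplified set")
    if nb < 2:
        raise ValueError(f"locus {locus_b!r} is monomorphic on the co-amplified set")
    return ia, ib, na, nb


def _dprime_from_counts(counts: np.ndarray) -> float:
    """Multi-allelic D′ from an na x nb joint count table (or a stack)."""
    x = counts / counts.sum(axis=(-2, -1), keepdims=True)
    p = x.sum(axis=-1, keepdims=True)           # ... x na x 1
    q = x.sum(axis=-2, keepdims=True)           # ... x 1 x nb
    d = x - p * q
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_neg = np.minimum(p * q, (1 - p) * (1 - q))
        dmax_pos = np.minimum(p * (1 - q), (1 - p) * q)
        dmax = np.where(d < 0, dmax_neg, dmax_pos)
        ratio = np.where(dmax > 0, np.abs(d) / np.where(dmax > 0, dmax, 1.0), 0.0)
    out = (p * q * np.clip(ratio, 0.0, 1.0)).sum(axis=(-2, -1))
    return out


def pairwise_dprime(genotypes: pd.DataFrame, locus_a: str, locus_b: str) -> float:
    ia, ib, na, nb = _codes_pair(genotypes, locus_a, locus_b)
    counts = np.bincount(ia * nb + ib, minlength=na * nb).reshape(na, nb).astype(float)
    return float(_dprime_from_counts(counts))


def permutation_pvalue(genotypes: pd.DataFrame, locus_a: str, locus_b: str,
                       n_perm: int = 1000, seed: int = 0):
    """Permutation p-value for D′; returns (observed D′, p).

    One locus's calls are permuted across accessions;
    p = (#{D′_perm >= D′_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ia, ib, na, nb = _codes_pair(genotypes, locus_a, locus_b)
    obs = _observed_and_perm(ia, ib, na, nb, n_perm, seed)
    return obs


def _observed_and_perm(ia, ib, na, nb, n_perm, seed):
    n = len(ia)
    counts = np.bincount(ia * nb + ib, minlength=na * nb).reshape(na, nb).astype(float)
    d_obs = float(_dprime_from_counts(counts))
    rng = np.random.default_rng(seed)
    # batch permutations to bound memory at ~batch x n
    exceed = 0
    batch = max(1, min(n_perm, 4_000_000 // max(n, 1)))
    done = 0
    cell = na * nb
    while done < n_perm:
        m = min(batch, n_perm - done)
        keys = rng.random((m, n))
        perm = np.argsort(keys, axis=1)
        ib_perm = ib[perm]
        code = ia[None, :] * nb + ib_perm + (np.arange(m) * cell)[:, None]
        flat = np.bincount(code.ravel(), minlength=m * cell).astype(float)
        stack = flat.reshape(m, na, nb)
        d_perm = _dprime_from_counts(stack)
        exceed += int((d_perm >= d_obs - 1e-12).sum())
        done += m
    p = (exceed + 1) / (n_perm + 1)
    return d_obs, float(p)


@dataclass
class DecayFit:
    b: float
    c: float
    n_pairs: int
    subpop: str
    critical_dprime: float | None = None
    decay_distance_cM: float | None = None


def ld_scan(genotypes: pd.DataFrame, marker_map: pd.DataFrame,
            subpops: pd.Series | None = None, n_perm: int = 1000,
            seed: int = 0, alpha: float = 0.05, min_subpop: int = 10,
            loci: list[str] | None = None):
    """All-pairs D′ with permutation p-values, per subpopulation.

    ``subpops`` assigns each accession a hard subpopulation label
    (argmax of its Q row); None scans the whole panel as one group.
    Returns (pair table, summary table).  The summary gives, per
    subpopulation: significant-pair count, its ratio (%) to the total
    significant pairs across subpopulations, the D′ histogram of the
    significant pairs in 0.2-wide bins, and their mean D′.
    Subpopulations with fewer than ``min_subpop`` accessions are skipped.
    """
    loci = list(loci if loci is not None else genotypes.columns)
    mp = marker_map.set_index("locus")
    if subpops is None:
        groups = {"ALL": genotypes.index}
    else:
        groups = {str(g): members.index for g, members in subpops.groupby(subpops)}
    rows = []
    rng = np.random.default_rng(seed)
    for label in sorted(groups):
        members = groups[label]
        if len(members) < min_subpop:
            warnings.warn(f"subpopulation {label} has {len(members)} accessions; skipped",
                          stacklevel=2)
            continue
        sub = genotypes.loc[members, loci]
        for la, lb in itertools.combinations(loci, 2):
            try:
                ia, ib, na, nb = _codes_pair(sub, la, lb)
            except ValueError:
                continue
            d_obs, p = _observed_and_perm(ia, ib, na, nb, n_perm,
                                          int(rng.integers(2**31 - 1)))
            same_chrom = mp.loc[la, "chromosome"] == mp.loc[lb, "chromosome"]
            rows.append({
                "subpop": label, "locus_a": la, "locus_b": lb,
                "dprime": d_obs, "p_value": p, "syntenic": bool(same_chrom),
                "distance_cM": abs(mp.loc[la, "cM"] - mp.loc[lb, "cM"])
                if same_chrom else np.nan,
            })
    pairs = pd.DataFrame(rows)
    summary = summarize_ld(pairs, alpha=alpha) if len(pairs) else pd.DataFrame()
    return pairs, summary


def summarize_ld(pairs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-subpopulation significant-pair counts, cross-subpopulation
    ratio (%), binned D′ frequencies and mean D′."""
    sig = pairs[pairs["p_value"] < alpha]
    total = len(sig)
    rows = []
    for label, grp in sig.groupby("subpop"):
        binned, _ = np.histogram(grp["dprime"], bins=DPRIME_BINS)
        # right-closed top bin: D' == 1 belongs to 0.8-1.0
        row = {"subpop": label, "n_significant": len(grp),
               "ratio_pct": round(100.0 * len(grp) / total, 1) if total else 0.0}
        for (lo, hi), cnt in zip(itertools.pairwise(DPRIME_BINS), binned):
            row[f"d_{lo:.1f}_{hi:.1f}"] = int(cnt)
        row["mean_dprime"] = round(float(grp["dprime"].mean()), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def fit_decay(pairs: pd.DataFrame, subpop: str | None = None,
              alpha: float = 0.05) -> DecayFit:
    """Least-squares fit of D′ = b ln(distance_cM) + c over syntenic
    significant pairs."""
    sel = pairs[pairs["syntenic"] & (pairs["p_value"] < alpha)
                & (pairs["distance_cM"] > 0)]
    if subpop is not None:
        sel = sel[sel["subpop"] == subpop]
    x = np.log(sel["distance_cM"].to_numpy(dtype=float))
    y = sel["dprime"].to_numpy(dtype=float)
    if len(sel) < 3 or np.unique(x).size < 2:
        raise ValueError("need >= 3 syntenic significant pairs with >= 2 distinct distances")
    b, c = np.polyfit(x, y, 1)
    return DecayFit(float(b), float(c), len(sel), subpop or "ALL")


def decay_distance(fit: DecayFit, critical_dprime: float) -> float:
    """Map distance (cM) at which the fitted curve crosses the critical D′."""
    if fit.b >= 0:
        raise ValueError("fitted slope is non-negative: no decay to invert")
    x_star = float(np.exp((critical_dprime - fit.c) / fit.b))
    if x_star < 1.0:
        warnings.warn("decay distance below 1 cM map resolution", stacklevel=2)
    fit.critical_dprime = critical_dprime
    fit.decay_distance_cM = x_star
    return x_star


def background_critical_dprime(pairs: pd.DataFrame, subpop: str | None = None,
                               quantile: float = 0.95) -> float:
    """Critical D′ = upper quantile of non-syntenic (background) D′."""
    sel = pairs[~pairs["syntenic"]]
    if subpop is not None:
        sel = sel[sel["subpop"] == subpop]
    if sel.empty:
        raise ValueError("no non-syntenic pairs to set a background threshold")
    return float(np.quantile(sel["dprime"], quantile))
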