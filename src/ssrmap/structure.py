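"""Admixture-proportion estimation, Evanno ΔK model selection and
kinship.

The admixture model treats each inbred accession as a haploid
multi-allelic profile: the probability of accession i's genotype is
prod_l sum_k q_ik f_kl(x_il), with q_i the accession's membership
(mixture) proportions over K clusters and f_kl the cluster-specific
allele frequencies at locus l.  The maximum-likelihood fit is obtained
with an EM algorithm (random restart controlled by a seed); the
log-likelihood is non-decreasing over iterations.  This is a
deterministic-given-seed surrogate for Bayesian MCMC clustering: same
Q-matrix contract, no correlated-frequency prior.

Model selection uses the Evanno second-difference statistic
ΔK = mean|L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over independent
restarts, with chosen K = argmax ΔK (ties go to the smaller K).

Kinship is background-corrected allele sharing: with s_ij the
proportion of co-amplified loci at which two accessions carry the same
allele and s̄ the mean off-diagonal sharing,
k_ij = (s_ij - s̄) / (1 - s̄), clamped at 0 for the model copy so the
matrix can serve as the covariance of a polygenic random effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StructureFit", "admixture_em", "select_k_delta_k",
           "kinship_matrix", "KINSHIP_BINS"]

#: histogram bin edges conventionally used for panel relatedness reporting
KINSHIP_BINS = (-np.inf, 0.05, 0.10, np.inf)


@dataclass
class StructureFit:
    q: pd.DataFrame
    freqs: list[np.ndarray]  # per locus: K x n_alleles
    loglik: float
    loglik_path: list[float]
    k: int
    seed: int
    n_iter: int
    converged: bool


def _encode(genotypes: pd.DataFrame):
    """Integer-code alleles per locus; -1 marks a null call."""
    codes = np.empty(genotypes.shape, dtype=np.int64)
    n_alleles = []
    for j, locus in enumerate(genotypes.columns):
        col = genotypes[locus]
        cat = pd.Categorical(col.astype("Int64"))
        if len(cat.categories) == 0:
            raise ValueError(f"locus {locus!r} has no amplified calls")
        codes[:, j] = cat.codes  # -1 for NA
        n_alleles.append(len(cat.categories))
    return codes, n_alleles


def admixture_em(genotypes: pd.DataFrame, k: int, seed: int = 0,
                 max_iter: int = 300, tol: float = 1e-4) -> StructureFit:
    """EM fit of the haploid admixture model with K clusters."""
    n, L = genotypes.shape
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError(f"K={k} exceeds the number of accessions ({n})")
    codes, n_alleles = _encode(genotypes)
    rng = np.random.default_rng(np.random.SeedSequence([seed, k]))

    q = rng.dirichlet(np.ones(k) * 5.0, size=n)  # mild random restart
    freqs = []
    for j in range(L):
        A = n_alleles[j]
        counts = np.bincount(codes[:, j][codes[:, j] >= 0], minlength=A).astype(float)
        base = counts / counts.sum()
        f = base[None, :] * (1.0 + 0.05 * rng.standard_normal((k, A)))
        f = np.clip(f, 1e-8, None)
        freqs.append(f / f.sum(axis=1, keepdims=True))

    amplified = codes >= 0
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities r[i,l,k] over clusters per call
        P = np.ones((n, L, k))
        for j in range(L):
            obs = amplified[:, j]
            P[obs, j, :] = freqs[j][:, codes[obs, j]].T
        numer = q[:, None, :] * P
        mix = numer.sum(axis=2)  # n x L
        loglik = float(np.log(np.clip(mix[amplified], 1e-300, None)).sum())
        path.append(loglik)
        r = numer / np.clip(mix, 1e-300, None)[:, :, None]
        r[~amplified] = 0.0
        # M step
        weights = amplified.sum(axis=1, keepdims=True).astype(float)
        q = r.sum(axis=1) / np.clip(weights, 1.0, None)
        q = np.clip(q, 1e-12, None)
        q /= q.sum(axis=1, keepdims=True)
        for j in range(L):
            A = n_alleles[j]
            f = np.zeros((k, A))
            obs = amplified[:, j]
            np.add.at(f.T, codes[obs, j], r[obs, j, :])
            f = np.clip(f, 1e-10, None)
            freqs[j] = f / f.sum(axis=1, keepdims=True)
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"admixture EM (K={k}) stopped at max_iter={max_iter} with "
            f"|Δloglik|={abs(path[-1] - path[-2]):.3g}", stacklevel=2)
    qdf = pd.DataFrame(q, index=genotypes.index,
                       columns=[f"Q{i + 1}" for i in range(k)])
    return StructureFit(qdf, freqs, path[-1], path, k, seed, it, converged)


def select_k_delta_k(fits: dict[int, list[StructureFit]], sd_floor: float = 1e-6):
    """Evanno ΔK over a consecutive K range with repeated restarts.

    Returns (table, chosen_k).  The table carries the run-mean
    log-likelihood L(K), its sd over runs and ΔK for the interior K
    values; chosen K = argmax ΔK, smaller K on ties.
    """
    ks = sorted(fits)
    if ks != list(range(ks[0], ks[-1] + 1)) or len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if any(len(fits[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    L = {k: np.array([f.loglik for f in fits[k]]) for k in ks}
    rows = []
    for k in ks:
        row = {"K": k, "mean_L": float(L[k].mean()), "sd_L": float(L[k].std(ddof=1))}
        if ks[0] < k < ks[-1]:
            second = abs(L[k + 1].mean() - 2 * L[k].mean() + L[k - 1].mean())
            row["delta_k"] = second / max(row["sd_L"], sd_floor)
        else:
            row["delta_k"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    if len(interior) > 1 and np.allclose(interior["delta_k"],
                                         interior["delta_k"].iloc[0]):
        warnings.warn("flat ΔK profile; chosen K is arbitrary within the range",
                      stacklevel=2)
    chosen = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return table, chosen


def allele_sharing(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Proportion of co-amplified loci with identical alleles, per pair."""
    if len(genotypes) < 2:
        raise ValueError("need at least 2 accessions")
    X = genotypes.to_numpy(dtype=float, na_value=np.nan)
    amp = ~np.isnan(X)
    co = amp.astype(float) @ amp.astype(float).T
    if (co == 0).any():
        i, j = np.argwhere(co == 0)[0]
        raise ValueError(
            f"accessions {genotypes.index[i]!r} and {genotypes.index[j]!r} "
            "share no co-amplified locus")
    n = len(genotypes)
    shared = np.zeros((n, n))
    for col in range(X.shape[1]):
        c = X[:, col]
        both = amp[:, col]
        eq = (c[:, None] == c[None, :]) & both[:, None] & both[None, :]
        shared += eq
    return pd.DataFrame(shared / co, index=genotypes.index, columns=genotypes.index)


def kinship_matrix(genotypes: pd.DataFrame):
    """Background-corrected allele-sharing kinship.

    Returns (model_kinship, raw_kinship, histogram).  The model copy is
    clamped at 0, has unit diagonal, and is repaired to positive
    semidefiniteness by flooring eigenvalues at 0.  The histogram counts
    off-diagonal pairs in the bins (<0.05, 0.05-0.10, >0.10).
    """
    s = allele_sharing(genotypes).to_numpy()
    n = s.shape[0]
    off = ~np.eye(n, dtype=bool)
    s_bar = s[off].mean()
    k = (s - s_bar) / (1.0 - s_bar)
    raw = pd.DataFrame(k, index=genotypes.index, columns=genotypes.index)
    km = np.clip(k, 0.0, None)
    np.fill_diagonal(km, 1.0)
    vals, vecs = np.linalg.eigh((km + km.T) / 2.0)
    if vals.min() < 0:
        km = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    model = pd.DataFrame(km, index=genotypes.index, columns=genotypes.index)
    pairs = raw.to_numpy()[np.triu_indices(n, 1)]
    counts, _ = np.histogram(pairs, bins=[-np.inf, 0.05, 0.10, np.inf])
    hist = pd.DataFrame({
        "bin": ["<0.05", "0.05-0.10", ">0.10"],
        "count": counts,
        "fraction": counts / counts.sum(),
    })
    return model, raw, hist
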