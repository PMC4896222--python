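"""Q+K mixed-linear-model genome scan for multi-allelic markers.

Model: for one trait (accession means within a year)

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with X holding an intercept, the admixture covariates Q (first K-1
columns, to avoid collinearity with the intercept) and, when a marker
is tested, its allele-class indicators.  Variance components are
estimated by REML through a one-dimensional optimisation over the
variance ratio on the eigenbasis of K (EMMA-style), once on the
covariate-only null model, and re-used for every marker (P3D).  Each
marker is then an F-test of its allele-class factor under generalised
least squares; PVE is the marker's reduction in residual sum of squares
over the total sum of squares, both on the whitened scale, in percent.

Rare allele classes (fewer carriers than a threshold, default 5) are
collapsed into a single "rare" class before testing; accessions with a
null (non-amplified) call at the tested marker are excluded from that
marker's test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["reml_variance_components", "MixedModelFit", "MixedAssociation",
           "MixedAssociationResults", "genome_scan", "filter_significant",
           "mlm_marker_test"]


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    log_reml: float
    ratio: float  # sigma_g2 / sigma_e2


def _check_full_rank(X: np.ndarray, names=None) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        if names is None:
            names = [f"col{i}" for i in range(X.shape[1])]
        # identify columns whose removal restores full column rank
        bad = [names[i] for i in range(X.shape[1])
               if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank]
        raise ValueError(f"design matrix rank-deficient; collinear column(s): {bad}")


def reml_variance_components(y: np.ndarray, X: np.ndarray, K: np.ndarray,
                             names=None) -> MixedModelFit:
    """REML estimates of (sigma_g^2, sigma_e^2) for a single K random effect.

    One-dimensional profile REML over log lambda (lambda = sigma_g^2 /
    sigma_e^2) on the eigenbasis of K; deterministic given inputs.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    _check_full_rank(X, names)
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X
    ldet_xx = np.linalg.slogdet(X.T @ X)[1]

    def neg_reml(log_lam: float):
        lam = np.exp(log_lam)
        w = lam * d + 1.0
        Xw = Xs / w[:, None]
        xtwx = Xs.T @ Xw
        beta = np.linalg.solve(xtwx, Xw.T @ ys)
        resid = ys - Xs @ beta
        rss_w = float(resid @ (resid / w))
        sigma_e2 = rss_w / (n - p)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma_e2) + (n - p)
                     + np.log(w).sum() + np.linalg.slogdet(xtwx)[1] - ldet_xx)
        return -ll, beta, sigma_e2

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_reml(g)[0] for g in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: neg_reml(g)[0], bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    best = res.x if res.fun <= vals[i] else grid[i]
    nll, beta, sigma_e2 = neg_reml(best)
    lam = float(np.exp(best))
    return MixedModelFit(lam * sigma_e2, sigma_e2, beta, -nll, lam)


def _rss(Xw: np.ndarray, yw: np.ndarray) -> tuple[float, int]:
    beta, rss, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rss.size == 0:
        resid = yw - Xw @ beta
        rss = np.array([resid @ resid])
    return float(rss[0]), int(rank)


def _collapse_classes(calls: pd.Series, rare_min: int) -> pd.Series | None:
    """Allele-class labels with rare classes (carriers < rare_min, and
    all singletons) merged into one "rare" class.  None if fewer than 2
    classes remain."""
    counts = calls.value_counts()
    rare = set(counts.index[counts < max(rare_min, 2)])
    labels = calls.map(lambda a: "rare" if a in rare else str(int(a)))
    if labels.nunique() < 2:
        return None
    return labels


@dataclass
class MarkerTest:
    p_value: float
    pve_pct: float
    n_used: int
    n_classes: int


def _whiten(K: np.ndarray, sigma_g2: float, sigma_e2: float) -> np.ndarray:
    """Inverse Cholesky factor of V = sigma_g^2 K + sigma_e^2 I."""
    V = sigma_g2 * K + sigma_e2 * np.eye(K.shape[0])
    L = np.linalg.cholesky(V)
    return L


def mlm_marker_test(y: pd.Series, q: pd.DataFrame | None, K: pd.DataFrame,
                    calls: pd.Series, vc: MixedModelFit | None = None,
                    rare_min: int = 5) -> MarkerTest | None:
    """GLS F-test of one marker's allele-class factor under Q+K.

    ``y``, ``q``, ``K`` and ``calls`` are aligned on accession ids.
    ``vc`` carries the P3D variance components (estimated on the null
    model if omitted).  Returns None when the marker is untestable
    (monomorphic after collapsing).
    """
    ids = y.index.intersection(calls.index)
    calls = calls.loc[ids].dropna()
    ids = calls.index
    labels = _collapse_classes(calls, rare_min)
    if labels is None:
        return None
    yv = y.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    X0 = np.ones((n, 1))
    if q is not None and q.shape[1] > 1:
        X0 = np.hstack([X0, q.loc[ids].to_numpy(dtype=float)[:, :-1]])
    Ksub = K.loc[ids, ids].to_numpy(dtype=float)
    if vc is None:
        vc = reml_variance_components(yv, X0, Ksub)
    L = _whiten(Ksub, vc.sigma_g2, vc.sigma_e2)
    yw = linalg.solve_triangular(L, yv, lower=True)
    X0w = linalg.solve_triangular(L, X0, lower=True)
    onew = linalg.solve_triangular(L, np.ones((n, 1)), lower=True)
    dummies = pd.get_dummies(labels).to_numpy(dtype=float)[:, 1:]
    X1w = np.hstack([X0w, linalg.solve_triangular(L, dummies, lower=True)])
    rss0, rank0 = _rss(X0w, yw)
    rss1, rank1 = _rss(X1w, yw)
    df1 = rank1 - rank0
    df2 = n - rank1
    if df1 < 1 or df2 < 1:
        return None
    F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = float(stats.f.sf(max(F, 0.0), df1, df2))
    tss, _ = _rss(onew, yw)
    pve = 100.0 * max(rss0 - rss1, 0.0) / tss if tss > 0 else 0.0
    return MarkerTest(p, float(min(pve, 100.0)), n, int(labels.nunique()))


class MixedAssociation:
    """Q+K mixed model for one trait-year phenotype vector.

    statsmodels-style: construct from data, ``fit()`` returns a results
    object carrying variance components and the per-marker scan.
    """

    def __init__(self, y: pd.Series, genotypes: pd.DataFrame,
                 q: pd.DataFrame | None, kinship: pd.DataFrame,
                 marker_map: pd.DataFrame | None = None,
                 trait: str = "trait", year: int | None = None):
        ids = y.index.intersection(genotypes.index).intersection(kinship.index)
        if q is not None:
            ids = ids.intersection(q.index)
        if len(ids) < len(y):
            warnings.warn(f"{len(y) - len(ids)} accessions dropped by inner join",
                          stacklevel=2)
        self.y = y.loc[ids]
        self.genotypes = genotypes.loc[ids]
        self.q = q.loc[ids] if q is not None else None
        self.kinship = kinship.loc[ids, ids]
        self.marker_map = marker_map
        self.trait = trait
        self.year = year

    @classmethod
    def from_tables(cls, phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                    q: pd.DataFrame | None, kinship: pd.DataFrame,
                    trait: str, year: int,
                    marker_map: pd.DataFrame | None = None) -> "MixedAssociation":
        from .quantgen import accession_trait_means
        y = accession_trait_means(phenotypes, trait, year)
        return cls(y, genotypes, q, kinship, marker_map, trait, year)

    def null_design(self) -> np.ndarray:
        X = np.ones((len(self.y), 1))
        if self.q is not None and self.q.shape[1] > 1:
            X = np.hstack([X, self.q.to_numpy(dtype=float)[:, :-1]])
        return X

    def fit(self, rare_min: int = 5) -> "MixedAssociationResults":
        vc = reml_variance_components(self.y.to_numpy(dtype=float),
                                      self.null_design(),
                                      self.kinship.to_numpy(dtype=float))
        rows = []
        skipped = []
        for locus in self.genotypes.columns:
            test = mlm_marker_test(self.y, self.q, self.kinship,
                                   self.genotypes[locus], vc, rare_min)
            if test is None:
                skipped.append(locus)
                continue
            row = {"trait": self.trait, "year": self.year, "locus": locus,
                   "p_value": test.p_value, "pve_pct": test.pve_pct,
                   "n_used": test.n_used, "n_classes": test.n_classes}
            if self.marker_map is not None:
                mp = self.marker_map.set_index("locus")
                row["chromosome"] = int(mp.loc[locus, "chromosome"])
                row["position_cM"] = float(mp.loc[locus, "cM"])
            rows.append(row)
        table = pd.DataFrame(rows)
        if len(table) and "chromosome" in table:
            table = table.sort_values(["trait", "chromosome", "position_cM"]
                                      ).reset_index(drop=True)
        return MixedAssociationResults(self, vc, table, skipped)


@dataclass
class MixedAssociationResults:
    model: MixedAssociation
    vc: MixedModelFit
    scan: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def summary(self) -> str:
        head = (f"Q+K mixed-model scan: trait {self.model.trait}, "
                f"year {self.model.year}\n"
                f"accessions: {len(self.model.y)}   "
                f"markers tested: {len(self.scan)}   skipped: {len(self.skipped)}\n"
                f"sigma_g2 = {self.vc.sigma_g2:.4g}   "
                f"sigma_e2 = {self.vc.sigma_e2:.4g}   "
                f"log-REML = {self.vc.log_reml:.2f}\n")
        if not len(self.scan):
            return head
        top = self.scan.nsmallest(min(10, len(self.scan)), "p_value")
        cols = [c for c in ("locus", "chromosome", "position_cM",
                            "p_value", "pve_pct") if c in top]
        return head + top[cols].to_string(index=False, float_format="%.4g")


def genome_scan(phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                marker_map: pd.DataFrame | None, q: pd.DataFrame | None,
                kinship: pd.DataFrame, rare_min: int = 5) -> pd.DataFrame:
    """Every trait x year x testable locus, P3D Q+K scan."""
    tables = []
    for (trait, year), _ in phenotypes.groupby(["trait", "year"]):
        model = MixedAssociation.from_tables(
            phenotypes, genotypes, q, kinship, trait, int(year), marker_map)
        tables.append(model.fit(rare_min=rare_min).scan)
    out = pd.concat(tables, ignore_index=True)
    sort_cols = [c for c in ("trait", "chromosome", "position_cM", "locus")
                 if c in out.columns]
    return out.sort_values(sort_cols).reset_index(drop=True)


def filter_significant(results: pd.DataFrame, p_max: float = 0.05,
                       pve_min: float = 5.0, both_years: bool = True) -> pd.DataFrame:
    """Retain trait-locus pairs with p < p_max (strict) in every scanned
    year (or any year when ``both_years`` is False) and PVE above
    ``pve_min`` in at least one year."""
    if results.empty:
        return results.copy()
    keep = []
    for (trait, locus), grp in results.groupby(["trait", "locus"]):
        sig = grp["p_value"] < p_max
        ok_p = sig.all() if both_years else sig.any()
        ok_pve = (grp["pve_pct"] > pve_min).any()
        if ok_p and ok_pve:
            keep.append(grp)
    if not keep:
        return results.iloc[0:0].copy()
    return pd.concat(keep).sort_index().reset_index(drop=True)
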