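"""Trait descriptives, ANOVA variance components, broad-sense
heritability and trait correlations.

Heritability of line means follows the classical replicated-trial
estimator: a one-way ANOVA of replicate-level data (genotypes as
groups, within each year) gives sigma_e^2 = MSE and
sigma_g^2 = (MSG - MSE) / n̄ with n̄ the harmonic-mean replicate count;
H² = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n).  Negative moment
estimates of sigma_g^2 are truncated at 0 and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["trait_descriptives", "anova_variance_components",
           "broad_sense_heritability", "trait_correlations",
           "VarianceComponents", "accession_trait_means"]


def accession_trait_means(phenotypes: pd.DataFrame, trait: str,
                          year: int | None = None) -> pd.Series:
    """Per-accession mean over replicates (and years unless one is given)."""
    sel = phenotypes[phenotypes["trait"] == trait]
    if year is not None:
        sel = sel[sel["year"] == year]
    if sel.empty:
        raise ValueError(f"no records for trait {trait!r}" +
                         (f", year {year}" if year is not None else ""))
    return sel.groupby("accession")["value"].mean()


def trait_descriptives(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, range, CV%, excess kurtosis and skewness of accession
    means, per trait and year.

    Sample SD (n-1); Fisher excess kurtosis and adjusted skewness
    (bias-corrected), which are undefined below 3 accessions and
    flagged NaN there or for constant traits.
    """
    rows = []
    for (trait, year), grp in phenotypes.groupby(["trait", "year"]):
        means = grp.groupby("accession")["value"].mean()
        m, sd = float(means.mean()), float(means.std(ddof=1))
        row = {
            "trait": trait, "year": int(year), "n": len(means),
            "mean": m, "sd": sd,
            "min": float(means.min()), "max": float(means.max()),
            "cv_pct": 100.0 * sd / m if m else np.nan,
        }
        if len(means) >= 3 and sd > 0:
            row["kurtosis"] = float(stats.kurtosis(means, fisher=True, bias=False))
            row["skewness"] = float(stats.skew(means, bias=False))
        else:
            row["kurtosis"] = np.nan
            row["skewness"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["trait", "year"]).reset_index(drop=True)


@dataclass
class VarianceComponents:
    trait: str
    year: int
    sigma_g2: float
    sigma_e2: float
    n_reps: float
    truncated: bool

    @property
    def h2(self) -> float:
        return broad_sense_heritability(self)


def anova_variance_components(phenotypes: pd.DataFrame, trait: str,
                              year: int) -> VarianceComponents:
    """One-way (genotype) ANOVA on replicate-level data within a year."""
    sel = phenotypes[(phenotypes["trait"] == trait) & (phenotypes["year"] == year)]
    if sel.empty:
        raise ValueError(f"no records for trait {trait!r}, year {year}")
    groups = sel.groupby("accession")["value"]
    sizes = groups.size()
    if len(sizes) < 2:
        raise ValueError("need >= 2 accessions")
    if (sizes < 2).all():
        raise ValueError("single replicate everywhere: error variance inestimable")
    grand = sel["value"].mean()
    gmeans = groups.mean()
    ss_between = float((sizes * (gmeans - grand) ** 2).sum())
    ss_within = float(((sel["value"] - sel["accession"].map(gmeans)) ** 2).sum())
    df_between = len(sizes) - 1
    df_within = len(sel) - len(sizes)
    msg = ss_between / df_between
    mse = ss_within / df_within if df_within else 0.0
    n_bar = len(sizes) / (1.0 / sizes).sum()  # harmonic mean replicates
    sigma_g2 = (msg - mse) / n_bar
    truncated = sigma_g2 < 0
    return VarianceComponents(trait, int(year), max(sigma_g2, 0.0), mse,
                              float(n_bar), truncated)


def broad_sense_heritability(vc: VarianceComponents) -> float:
    """H² = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n)."""
    if vc.sigma_g2 < 0 or vc.sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    denom = vc.sigma_g2 + vc.sigma_e2 / vc.n_reps
    if denom == 0:
        raise ValueError("both variance components are zero: H² undefined")
    return vc.sigma_g2 / denom


def heritability_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per trait-year variance components with H² in % (2 decimals)."""
    rows = []
    for (trait, year), _ in phenotypes.groupby(["trait", "year"]):
        vc = anova_variance_components(phenotypes, trait, int(year))
        rows.append({
            "trait": trait, "year": int(year),
            "sigma_g2": vc.sigma_g2, "sigma_e2": vc.sigma_e2,
            "n_reps": vc.n_reps, "truncated": vc.truncated,
            "H2_pct": round(100.0 * vc.h2, 2),
        })
    return pd.DataFrame(rows)


def trait_correlations(phenotypes: pd.DataFrame, year: int):
    """Pearson correlations among per-accession trait means, one year.

    Returns (r matrix, p matrix, star matrix) with stars at
    p<0.05 (*) and p<0.01 (**); constant traits yield NaN entries.
    """
    traits = sorted(phenotypes["trait"].unique())
    means = pd.DataFrame({
        t: accession_trait_means(phenotypes, t, year) for t in traits
    })
    if len(means) < 3:
        raise ValueError("need >= 3 accessions for correlations")
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    starred = pd.DataFrame("", index=traits, columns=traits)
    for i, ti in enumerate(traits):
        for j, tj in enumerate(traits):
            if j <= i:
                continue
            both = means[[ti, tj]].dropna()
            if both[ti].std() == 0 or both[tj].std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(both[ti], both[tj])
            r.loc[ti, tj] = r.loc[tj, ti] = rij
            p.loc[ti, tj] = p.loc[tj, ti] = pij
            star = "**" if pij < 0.01 else "*" if pij < 0.05 else ""
            starred.loc[ti, tj] = starred.loc[tj, ti] = star
    return r, p, starred
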