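"""Allele-effect estimation against the null-allele reference, and
elite-allele mining.

The phenotypic effect of allele i at an associated locus is

    a_i = (mean phenotype of accessions carrying allele i)
        - (mean phenotype of accessions with the null allele at the locus)

with phenotypes taken as per-accession means over years and replicates.
An allele with positive effect is an elite allele (for traits to be
increased; a direction flag handles traits to be decreased).  When a
locus has no null-allele accession the reference falls back to the
population mean and the row is flagged.  The "typical carrier" of an
elite allele is the highest-phenotype accession among the allele's
carriers that also ranks in the panel's top-n accessions for the trait;
if no carrier ranks that high, the best carrier overall is reported
with a fallback flag.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .quantgen import accession_trait_means

__all__ = ["allele_effect", "mine_elite_alleles", "typical_carriers"]


def _locus_reference(phen_means: pd.Series, calls: pd.Series):
    """Null-allele reference mean for a locus (population mean fallback)."""
    null_ids = calls.index[calls.isna()].intersection(phen_means.index)
    if len(null_ids):
        return float(phen_means.loc[null_ids].mean()), "null-allele mean"
    return float(phen_means.mean()), "population mean"


def allele_effect(phenotypes: pd.DataFrame, genotypes: pd.DataFrame,
                  trait: str, locus: str, allele: int) -> dict:
    """Effect a_i of one allele at one locus on one trait."""
    calls = genotypes[locus]
    phen = accession_trait_means(phenotypes, trait)
    carriers = calls.index[(calls == allele).fillna(False)]
    carriers = carriers.intersection(phen.index)
    if not len(carriers):
        raise ValueError(f"allele {allele} not observed at locus {locus!r} "
                         "among phenotyped accessions")
    ref, ref_kind = _locus_reference(phen, calls)
    effect = float(phen.loc[carriers].mean() - ref)
    return {
        "trait": trait, "locus": locus, "allele": int(allele),
        "effect": effect, "n_carriers": int(len(carriers)),
        "reference": ref_kind, "carriers": list(carriers),
    }


def mine_elite_alleles(assoc_filtered: pd.DataFrame, phenotypes: pd.DataFrame,
                       genotypes: pd.DataFrame, direction: str = "increase",
                       min_carriers: int = 2, top_n: int = 30) -> pd.DataFrame:
    """Effects for every observed allele at every retained trait-locus
    pair; elite = effect in the favourable direction.

    Alleles with fewer than ``min_carriers`` carriers are flagged
    singleton/noise and never marked elite.  Typical carriers follow the
    top-``top_n`` rule.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if assoc_filtered.empty:
        return pd.DataFrame(columns=["trait", "locus", "allele", "effect",
                                     "n_carriers", "reference", "elite",
                                     "typical_carrier", "carrier_fallback"])
    rows = []
    for (trait, locus), _ in assoc_filtered.groupby(["trait", "locus"]):
        calls = genotypes[locus]
        if calls.notna().sum() == 0:
            warnings.warn(f"locus {locus!r} has only null calls; skipped",
                          stacklevel=2)
            continue
        phen = accession_trait_means(phenotypes, trait)
        alleles = sorted(int(a) for a in calls.dropna().unique())
        for allele in alleles:
            rec = allele_effect(phenotypes, genotypes, trait, locus, allele)
            favourable = rec["effect"] > 0 if direction == "increase" else rec["effect"] < 0
            rec["elite"] = bool(favourable and rec["n_carriers"] >= min_carriers)
            carrier, fallback = typical_carriers(rec["carriers"], phen, top_n)
            rec["typical_carrier"] = carrier
            rec["carrier_fallback"] = fallback
            rec.pop("carriers")
            rows.append(rec)
    return pd.DataFrame(rows)


def typical_carriers(carriers, phen_means: pd.Series, top_n: int = 30):
    """Best carrier within the trait's top-``top_n`` accessions.

    Returns (accession id, fallback flag); the flag is True when no
    carrier ranks in the top-n and the best carrier overall is used.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    carriers = pd.Index(carriers).intersection(phen_means.index)
    if not len(carriers):
        return None, True
    top = phen_means.nlargest(top_n).index
    in_top = carriers.intersection(top)
    pool, fallback = (in_top, False) if len(in_top) else (carriers, True)
    return phen_means.loc[pool].idxmax(), fallback
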