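"""Cross design: rank parental combinations by pyramidable elite alleles.

A derived inbred line fixes one allele per locus, so when both parents
contribute elite alleles at the same locus only the largest-effect one
can be pyramided.  A cross's predicted effect is the sum of the selected
per-locus effects; crosses are ranked by (elite-allele count,
predicted effect), ties broken lexicographically by parent ids.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["CrossPlan", "pyramid_set", "predict_cross", "rank_crosses"]


@dataclass
class CrossPlan:
    trait: str
    parent_a: str
    parent_b: str
    pyramided: list[tuple[str, int, float]] = field(default_factory=list)

    @property
    def n_elite(self) -> int:
        return len(self.pyramided)

    @property
    def predicted_effect(self) -> float:
        return float(sum(e for _, _, e in self.pyramided))


def _elite_maps(elite: pd.DataFrame, genotypes: pd.DataFrame,
                parents) -> dict[str, dict[str, tuple[int, float]]]:
    """parent -> {locus -> (allele, effect)} over the elite alleles each
    parent carries.  An accession carries at most one allele per locus,
    so the inner map needs no de-duplication."""
    for parent in parents:
        if parent not in genotypes.index:
            raise ValueError(f"parent {parent!r} absent from genotypes")
    maps: dict[str, dict[str, tuple[int, float]]] = {p: {} for p in parents}
    sub = genotypes.loc[list(parents)]
    for _, row in elite.iterrows():
        locus, allele, effect = row["locus"], int(row["allele"]), float(row["effect"])
        hits = sub.index[(sub[locus] == allele).fillna(False)]
        for parent in hits:
            maps[parent][locus] = (allele, effect)
    return maps


def pyramid_set(parent_a: str, parent_b: str, elite_table: pd.DataFrame,
                trait: str, genotypes: pd.DataFrame):
    """Per locus, pool both parents' elite alleles and keep the
    largest-effect one.  Returns [(locus, allele, effect), ...] sorted
    by locus."""
    elite = elite_table[(elite_table["trait"] == trait) & elite_table["elite"]]
    maps = _elite_maps(elite, genotypes, {parent_a, parent_b})
    return _combine(maps[parent_a], maps[parent_b])


def _combine(ea: dict, eb: dict):
    chosen = {}
    for loc in set(ea) | set(eb):
        cands = [v for v in (ea.get(loc), eb.get(loc)) if v is not None]
        chosen[loc] = max(cands, key=lambda v: v[1])
    return [(loc, a, e) for loc, (a, e) in sorted(chosen.items())]


def predict_cross(parent_a: str, parent_b: str, elite_table: pd.DataFrame,
                  trait: str, genotypes: pd.DataFrame) -> CrossPlan:
    a, b = sorted([parent_a, parent_b])
    return CrossPlan(trait, a, b,
                     pyramid_set(a, b, elite_table, trait, genotypes))


def rank_crosses(accessions, elite_table: pd.DataFrame, trait: str,
                 genotypes: pd.DataFrame, top_m: int = 5) -> list[CrossPlan]:
    """Score every unordered pair of accessions; return the best
    ``top_m`` by (n_elite desc, predicted_effect desc, parent ids)."""
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    accessions = sorted(set(accessions))
    if len(accessions) < 2:
        raise ValueError("need at least 2 accessions")
    elite = elite_table[(elite_table["trait"] == trait) & elite_table["elite"]]
    maps = _elite_maps(elite, genotypes, accessions)
    plans = [CrossPlan(trait, a, b, _combine(maps[a], maps[b]))
             for a, b in itertools.combinations(accessions, 2)]
    plans.sort(key=lambda pl: (-pl.n_elite, -pl.predicted_effect,
                               pl.parent_a, pl.parent_b))
    return plans[:top_m]


def cross_table(plans: list[CrossPlan]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trait": pl.trait, "parent_a": pl.parent_a, "parent_b": pl.parent_b,
        "n_elite": pl.n_elite, "predicted_effect": pl.predicted_effect,
    } for pl in plans])
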