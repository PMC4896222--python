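"""Synthetic structured SSR panel generator.

Emulates a diversity panel of inbred rice accessions genotyped at
multi-allelic microsatellite loci: subpopulation allele frequencies
drift away from ancestral frequencies under a Balding-Nichols model,
accessions carry Dirichlet admixture proportions, and each accession
contributes a single scorable allele per locus (inbreds are effectively
haploid at SSR loci; a "null allele" is a failure to amplify).
Phenotypes are built from a handful of planted QTL with additive
per-allele effects, optional subpopulation-level confounding, year
shifts and replicate noise scaled to hit a target broad-sense
heritability — so every downstream stage of the pipeline has ground
truth to be checked against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio

__all__ = ["QTL", "SimConfig", "SyntheticDataset", "simulate_genotypes",
           "simulate_phenotypes", "simulate_dataset", "write_dataset",
           "default_config"]


@dataclass
class QTL:
    """One planted trait locus.

    ``effects`` maps allele label (fragment size, bp) to its additive
    contribution in trait units.  If ``effects`` is None the per-allele
    effects are drawn N(0, ``scale``^2) when phenotypes are simulated,
    and the realized map is echoed in the dataset's ``true_effects``.
    The null allele always contributes 0.
    """

    trait: str
    locus: str
    effects: dict[int, float] | None = None
    scale: float = 0.5


@dataclass
class SimConfig:
    n_accessions: int = 628
    n_loci: int = 262
    n_chromosomes: int = 12
    chrom_length_cM: dict[int, float] = field(
        default_factory=lambda: {c: 150.0 for c in range(1, 13)}
    )
    alleles_per_locus_range: tuple[int, int] = (3, 25)
    n_subpops: int = 7
    fst: float = 0.15
    admixture_alpha: float = 0.2
    qtl_spec: list[QTL] = field(default_factory=list)
    target_h2: dict[str, float] = field(default_factory=dict)
    trait_means: dict[str, float] = field(default_factory=dict)
    structure_effect_scale: dict[str, float] = field(default_factory=dict)
    year_effects: dict[int, float] = field(default_factory=lambda: {2013: 0.0, 2014: 0.02})
    n_reps: int = 2
    null_rate: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError(f"fst must lie strictly in (0,1); got {self.fst}")
        if self.alleles_per_locus_range[0] < 2:
            raise ValueError("alleles_per_locus_range minimum must be >= 2")
        if not 0 <= self.null_rate <= 0.2:
            raise ValueError("null_rate must lie in [0, 0.2]")
        for trait, h2 in self.target_h2.items():
            if not 0 < h2 <= 1:
                raise ValueError(f"target_h2 for {trait} must lie in (0,1]; got {h2}")
        if self.n_subpops < 1 or self.n_accessions < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticDataset:
    genotypes: pd.DataFrame
    marker_map: pd.DataFrame
    phenotypes: pd.DataFrame
    true_q: pd.DataFrame
    true_effects: list[QTL]
    realized_h2: dict[str, float]


def _locus_ids(n: int) -> list[str]:
    return [f"SSR{i + 1:04d}" for i in range(n)]


def _accession_ids(n: int) -> list[str]:
    return [f"ACC{i + 1:04d}" for i in range(n)]


def simulate_genotypes(config: SimConfig):
    """Draw genotypes, a marker map and the true admixture matrix.

    Per locus the ancestral frequency vector is symmetric-Dirichlet over
    the locus's allele count; each subpopulation's frequencies are drawn
    Dirichlet(p * (1-fst)/fst) around it (Balding-Nichols drift); each
    accession draws admixture proportions Dirichlet(alpha) and then one
    allele per locus from its personal mixture frequency.  Cells are
    nulled independently with probability ``null_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, L, K = config.n_accessions, config.n_loci, config.n_subpops

    q = rng.dirichlet(np.full(K, config.admixture_alpha), size=n)
    accessions = _accession_ids(n)
    loci = _locus_ids(L)

    amin, amax = config.alleles_per_locus_range
    n_alleles = rng.integers(amin, amax + 1, size=L)

    chroms = np.sort(rng.integers(1, config.n_chromosomes + 1, size=L))
    positions = np.empty(L)
    for c in range(1, config.n_chromosomes + 1):
        m = chroms == c
        positions[m] = np.sort(rng.uniform(0, config.chrom_length_cM.get(c, 150.0), m.sum()))
    marker_map = pd.DataFrame({"locus": loci, "chromosome": chroms, "cM": positions})

    geno = pd.DataFrame(index=pd.Index(accessions, name="accession"),
                        columns=loci, dtype="Int64")
    for j, locus in enumerate(loci):
        A = int(n_alleles[j])
        ancestral = rng.dirichlet(np.ones(A))
        # Balding-Nichols: subpop freqs concentrate around the ancestral
        # vector with mass (1-fst)/fst
        F = rng.dirichlet(np.maximum(ancestral, 1e-12) * (1 - config.fst) / config.fst, size=K)
        mix = q @ F  # n x A personal frequencies
        u = rng.random(n)
        idx = (mix.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(max=A - 1)
        base = 80 + int(rng.integers(0, 100)) * 2
        sizes = base + 2 * idx  # SSR ladder: >= 2 bp spacing
        cells = pd.array(sizes, dtype="Int64")
        if config.null_rate > 0:
            cells[rng.random(n) < config.null_rate] = pd.NA
        geno[locus] = cells

    true_q = pd.DataFrame(q, index=geno.index, columns=[f"Q{k + 1}" for k in range(K)])
    return geno, marker_map, true_q


def simulate_phenotypes(genotypes: pd.DataFrame, true_q: pd.DataFrame,
                        config: SimConfig):
    """Build replicate-level phenotypes from the planted QTL.

    Genetic value g = sum of planted allelic effects (null allele
    contributes 0), plus an optional subpopulation confounding term
    Q . shifts.  Noise variance is set so that
    Var(g) / (Var(g) + sigma_e^2 / n_reps) equals the target
    heritability of line means over replicates.

    Returns the long-format phenotype table, the realized QTL list and
    the realized per-trait heritability.
    """
    for qtl in config.qtl_spec:
        if qtl.locus not in genotypes.columns:
            raise ValueError(f"QTL locus {qtl.locus!r} not among simulated loci")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    n = len(genotypes)
    traits = sorted({q.trait for q in config.qtl_spec}
                    | set(config.structure_effect_scale))
    realized: list[QTL] = []
    rows = []
    realized_h2: dict[str, float] = {}
    for trait in traits:
        g = np.zeros(n)
        for qtl in (q for q in config.qtl_spec if q.trait == trait):
            calls = genotypes[qtl.locus]
            effects = qtl.effects
            if effects is None:
                observed = sorted(calls.dropna().unique())
                effects = {int(a): float(rng.normal(0.0, qtl.scale)) for a in observed}
            contrib = calls.map(lambda a: effects.get(int(a), 0.0) if pd.notna(a) else 0.0)
            g += contrib.to_numpy(dtype=float)
            realized.append(QTL(trait, qtl.locus, effects, qtl.scale))
        scale = config.structure_effect_scale.get(trait, 0.0)
        if scale:
            shifts = rng.normal(0.0, scale, size=true_q.shape[1])
            g = g + true_q.to_numpy() @ shifts
        var_g = float(np.var(g))
        h2 = config.target_h2.get(trait, 0.95)
        if var_g == 0 and h2 < 1:
            raise ValueError(
                f"trait {trait!r} has zero genetic variance; plant QTL with "
                "unequal per-allele effects to reach a heritability below 1"
            )
        sigma_e2 = 0.0 if h2 >= 1 else config.n_reps * var_g * (1 - h2) / h2
        realized_h2[trait] = var_g / (var_g + sigma_e2 / config.n_reps) if var_g else 1.0
        mean = config.trait_means.get(trait, 10.0)
        sd_e = np.sqrt(sigma_e2)
        for year, yshift in config.year_effects.items():
            for rep in range(1, config.n_reps + 1):
                vals = mean + g + yshift + rng.normal(0.0, sd_e, size=n)
                rows.append(pd.DataFrame({
                    "accession": genotypes.index, "trait": trait,
                    "year": year, "replicate": rep, "value": vals,
                }))
    phenotypes = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["accession", "trait", "year", "replicate", "value"])
    return phenotypes, realized, realized_h2


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    geno, marker_map, true_q = simulate_genotypes(config)
    phen, realized, realized_h2 = simulate_phenotypes(geno, true_q, config)
    return SyntheticDataset(geno, marker_map, phen, true_q, realized, realized_h2)


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict[str, Path]:
    """Write every artifact of a synthetic dataset as TSV/JSON; lossless."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if dataset.genotypes.empty:
        raise ValueError("refusing to write an empty dataset")
    paths = {
        "genotypes": out / "genotypes.tsv",
        "marker_map": out / "marker_map.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "true_q": out / "true_q.tsv",
        "truth": out / "truth.json",
    }
    sio.write_genotypes(dataset.genotypes, paths["genotypes"])
    sio.write_marker_map(dataset.marker_map, paths["marker_map"])
    sio.write_phenotypes(dataset.phenotypes, paths["phenotypes"])
    sio.write_q_matrix(dataset.true_q, paths["true_q"])
    truth = {
        "qtl": [
            {"trait": q.trait, "locus": q.locus,
             "effects": {str(a): e for a, e in (q.effects or {}).items()}}
            for q in dataset.true_effects
        ],
        "realized_h2": dataset.realized_h2,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-scale defaults: 628 accessions x 262 loci, 7 admixed
    subpopulations, 3-25 alleles per locus, five grain traits with a
    handful of QTL each, two years x two replicates.

    QTL effects are drawn at phenotype time (``QTL.effects=None``) with
    per-trait scales roughly half the trait's phenotypic SD.
    """
    loci = _locus_ids(overrides.get("n_loci", 262))
    trait_means = {"GL": 7.8, "GW": 3.05, "GT": 2.15, "GL/GW": 2.65, "TGW": 24.4}
    target_h2 = {"GL": 0.96, "GW": 0.92, "GT": 0.92, "GL/GW": 0.98, "TGW": 0.96}
    scales = {"GL": 0.35, "GW": 0.12, "GT": 0.06, "GL/GW": 0.25, "TGW": 1.0}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 411]))
    qtl_spec = []
    n_qtl = {"GL": 4, "GW": 2, "GT": 3, "GL/GW": 2, "TGW": 2}
    for trait, k in n_qtl.items():
        for locus in rng.choice(len(loci), size=min(k, len(loci)), replace=False):
            qtl_spec.append(QTL(trait, loci[locus], None, scales[trait]))
    cfg = SimConfig(qtl_spec=qtl_spec, target_h2=target_h2,
                    trait_means=trait_means, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg
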