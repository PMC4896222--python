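"""End-to-end pipeline: simulate -> diversity -> tree -> structure ->
kinship -> ld -> qstats -> assoc -> mine -> cross.

Each stage reads/writes the TSV artifacts defined in :mod:`ssrmap.io`.
A manifest records, per stage, the SHA-256 of its inputs and outputs and
the seed; on a re-run a stage is skipped when its outputs exist and its
recorded input hashes are unchanged, so corrupting one intermediate
re-runs only the stages downstream of it.  All randomness derives from
the single pipeline seed, so two runs with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, ld, mining, quantgen, simulate, structure
from . import association as assoc_mod
from . import crosses as cross_mod
from . import io as sio

log = logging.getLogger("ssrmap")


@dataclass
class PipelineConfig:
    out_dir: str = "ssrmap_out"
    seed: int = 0
    # simulate
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    genotypes: str | None = None
    marker_map: str | None = None
    phenotypes: str | None = None
    # structure
    k_range: tuple[int, int] = (2, 6)
    n_runs: int = 3
    em_max_iter: int = 200
    em_tol: float = 1e-3
    # ld
    n_perm: int = 200
    ld_max_loci: int = 30
    critical_dprime: float | None = None
    # association / mining / crosses
    rare_min_carriers: int = 5
    p_max: float = 0.05
    pve_min: float = 5.0
    both_years: bool = True
    top_n: int = 30
    top_m: int = 5
    stages: tuple[str, ...] = ("simulate", "diversity", "tree", "structure",
                              "kinship", "ld", "qstats", "assoc", "mine",
                              "cross")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        return cfg


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.data = {"config_hash": config_hash, "stages": {}}
        if path.exists():
            old = json.loads(path.read_text())
            if old.get("config_hash") == config_hash:
                self.data = old

    def fresh(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None:
            return False
        if not all(Path(o).exists() for o in rec["outputs"]):
            return False
        current = {str(p): _sha(Path(p)) for p in inputs if Path(p).exists()}
        return rec["inputs"] == current and sorted(rec["outputs"]) == sorted(map(str, outputs))

    def record(self, stage: str, inputs: list[Path], outputs: list[Path], seed: int):
        self.data["stages"][stage] = {
            "inputs": {str(p): _sha(Path(p)) for p in inputs},
            "outputs": [str(p) for p in outputs],
            "output_hashes": {str(p): _sha(Path(p)) for p in outputs},
            "seed": seed,
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json", _config_hash(config))
    seed = config.seed

    paths = {
        "genotypes": Path(config.genotypes) if config.genotypes else out / "genotypes.tsv",
        "marker_map": Path(config.marker_map) if config.marker_map else out / "marker_map.tsv",
        "phenotypes": Path(config.phenotypes) if config.phenotypes else out / "phenotypes.tsv",
    }

    def stage(name, inputs, outputs, fn):
        if name not in config.stages:
            return
        if manifest.fresh(name, inputs, outputs):
            log.info("stage %s: up to date, skipped", name)
            return
        log.info("stage %s: running", name)
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest.record(name, inputs, outputs, seed)

    # --- simulate -----------------------------------------------------
    if config.simulate:
        def do_sim():
            cfg = simulate.default_config(seed=seed, **config.sim_overrides)
            ds = simulate.simulate_dataset(cfg)
            simulate.write_dataset(ds, out)
        stage("simulate", [], [paths["genotypes"], paths["marker_map"],
                               paths["phenotypes"], out / "true_q.tsv",
                               out / "truth.json"], do_sim)

    geno_in = [paths["genotypes"]]

    # --- diversity ----------------------------------------------------
    div_out = [out / "diversity_per_locus.tsv", out / "diversity_summary.tsv"]

    def do_diversity():
        geno = sio.read_genotypes(paths["genotypes"])
        table, summary = diversity.summarize_diversity(geno)
        table.to_csv(div_out[0], sep="\t", index=False)
        pd.DataFrame([summary]).to_csv(div_out[1], sep="\t", index=False)
    stage("diversity", geno_in, div_out, do_diversity)

    # --- tree ---------------------------------------------------------
    tree_out = [out / "nj_tree.nwk"]

    def do_tree():
        geno = sio.read_genotypes(paths["genotypes"])
        dist = diversity.nei_distance(geno)
        tree = diversity.neighbor_joining(dist)
        sio.write_newick(tree, tree_out[0])
    stage("tree", geno_in, tree_out, do_tree)

    # --- structure ----------------------------------------------------
    struct_out = [out / "q_matrix.tsv", out / "delta_k.tsv"]

    def do_structure():
        geno = sio.read_genotypes(paths["genotypes"])
        k_lo, k_hi = config.k_range
        fits = {k: [structure.admixture_em(geno, k, seed=seed * 1000 + r,
                                           max_iter=config.em_max_iter,
                                           tol=config.em_tol)
                    for r in range(config.n_runs)]
                for k in range(k_lo, k_hi + 1)}
        table, chosen = structure.select_k_delta_k(fits)
        table.to_csv(struct_out[1], sep="\t", index=False)
        best = max(fits[chosen], key=lambda f: f.loglik)
        sio.write_q_matrix(best.q, struct_out[0])
    stage("structure", geno_in, struct_out, do_structure)

    # --- kinship ------------------------------------------------------
    kin_out = [out / "kinship.tsv", out / "kinship_hist.tsv"]

    def do_kinship():
        geno = sio.read_genotypes(paths["genotypes"])
        model, _raw, hist = structure.kinship_matrix(geno)
        sio.write_square_matrix(model, kin_out[0])
        hist.to_csv(kin_out[1], sep="\t", index=False)
    stage("kinship", geno_in, kin_out, do_kinship)

    # --- ld -----------------------------------------------------------
    ld_out = [out / "ld_pairs.tsv", out / "ld_summary.tsv", out / "ld_decay.tsv"]

    def do_ld():
        geno = sio.read_genotypes(paths["genotypes"])
        mp = sio.read_marker_map(paths["marker_map"], geno)
        q = sio.read_q_matrix(out / "q_matrix.tsv")
        subpops = q.idxmax(axis=1)
        loci = list(mp["locus"])
        if len(loci) > config.ld_max_loci:
            idx = np.linspace(0, len(loci) - 1, config.ld_max_loci).astype(int)
            loci = [loci[i] for i in idx]
        pairs, summary = ld.ld_scan(geno, mp, subpops, n_perm=config.n_perm,
                                    seed=seed, loci=loci)
        pairs.to_csv(ld_out[0], sep="\t", index=False)
        summary.to_csv(ld_out[1], sep="\t", index=False)
        decays = []
        for sp in sorted(pairs["subpop"].unique()):
            try:
                fit = ld.fit_decay(pairs, sp)
                crit = (config.critical_dprime
                        if config.critical_dprime is not None
                        else ld.background_critical_dprime(pairs, sp))
                if fit.b < 0:
                    ld.decay_distance(fit, crit)
                decays.append({"subpop": sp, "b": fit.b, "c": fit.c,
                               "n_pairs": fit.n_pairs,
                               "critical_dprime": fit.critical_dprime,
                               "decay_distance_cM": fit.decay_distance_cM})
            except ValueError as exc:
                log.warning("decay fit skipped for %s: %s", sp, exc)
        pd.DataFrame(decays).to_csv(ld_out[2], sep="\t", index=False)
    stage("ld", geno_in + [paths["marker_map"], out / "q_matrix.tsv"], ld_out, do_ld)

    # --- qstats -------------------------------------------------------
    q_out = [out / "descriptives.tsv", out / "heritability.tsv",
             out / "correlations.tsv"]

    def do_qstats():
        phen = sio.read_phenotypes(paths["phenotypes"])
        quantgen.trait_descriptives(phen).to_csv(q_out[0], sep="\t", index=False)
        quantgen.heritability_table(phen).to_csv(q_out[1], sep="\t", index=False)
        frames = []
        for year in sorted(phen["year"].unique()):
            r, p, stars = quantgen.trait_correlations(phen, int(year))
            r = r.round(3)
            r.insert(0, "year", int(year))
            frames.append(r)
        pd.concat(frames).to_csv(q_out[2], sep="\t")
    stage("qstats", [paths["phenotypes"]], q_out, do_qstats)

    # --- assoc --------------------------------------------------------
    assoc_out = [out / "associations.tsv", out / "associations_significant.tsv"]

    def do_assoc():
        geno = sio.read_genotypes(paths["genotypes"])
        mp = sio.read_marker_map(paths["marker_map"], geno)
        phen = sio.read_phenotypes(paths["phenotypes"])
        q = sio.read_q_matrix(out / "q_matrix.tsv")
        kin = sio.read_square_matrix(out / "kinship.tsv")
        scan = assoc_mod.genome_scan(phen, geno, mp, q, kin,
                                     rare_min=config.rare_min_carriers)
        scan.to_csv(assoc_out[0], sep="\t", index=False)
        sig = assoc_mod.filter_significant(scan, config.p_max, config.pve_min,
                                           config.both_years)
        sig.to_csv(assoc_out[1], sep="\t", index=False)
    stage("assoc", geno_in + [paths["marker_map"], paths["phenotypes"],
                              out / "q_matrix.tsv", out / "kinship.tsv"],
          assoc_out, do_assoc)

    # --- mine ---------------------------------------------------------
    mine_out = [out / "elite_alleles.tsv"]

    def do_mine():
        geno = sio.read_genotypes(paths["genotypes"])
        phen = sio.read_phenotypes(paths["phenotypes"])
        sig = pd.read_csv(assoc_out[1], sep="\t")
        elite = mining.mine_elite_alleles(sig, phen, geno,
                                          min_carriers=2, top_n=config.top_n)
        elite.to_csv(mine_out[0], sep="\t", index=False)
    stage("mine", geno_in + [paths["phenotypes"], assoc_out[1]], mine_out, do_mine)

    # --- cross --------------------------------------------------------
    cross_out = [out / "crosses.tsv"]

    def do_cross():
        geno = sio.read_genotypes(paths["genotypes"])
        elite = pd.read_csv(mine_out[0], sep="\t")
        frames = []
        if len(elite):
            for trait in sorted(elite.loc[elite["elite"], "trait"].unique()):
                plans = cross_mod.rank_crosses(geno.index, elite, trait, geno,
                                               top_m=config.top_m)
                frames.append(cross_mod.cross_table(plans))
        table = (pd.concat(frames, ignore_index=True) if frames
                 else pd.DataFrame(columns=["trait", "parent_a", "parent_b",
                                            "n_elite", "predicted_effect"]))
        table.to_csv(cross_out[0], sep="\t", index=False)
    stage("cross", geno_in + [mine_out[0]], cross_out, do_cross)

    return manifest.data
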