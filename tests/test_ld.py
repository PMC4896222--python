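import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssrmap import ld, simulate


def biallelic_genotypes(n_ab, n_aB, n_Ab, n_ab2):
    """Two-locus haploid panel from 2x2 haplotype counts."""
    haps = ([(100, 200)] * n_ab + [(100, 202)] * n_aB
            + [(102, 200)] * n_Ab + [(102, 202)] * n_ab2)
    return pd.DataFrame({"L1": pd.array([h[0] for h in haps], dtype="Int64"),
                         "L2": pd.array([h[1] for h in haps], dtype="Int64")},
                        index=[f"a{i}" for i in range(len(haps))])


class TestDprime:
    def test_two_by_two_hand_case(self):
        g = biallelic_genotypes(40, 10, 10, 40)  # D=0.15, Dmax=0.25
        assert ld.pairwise_dprime(g, "L1", "L2") == pytest.approx(0.6)

    def test_complete_coupling(self):
        g = biallelic_genotypes(50, 0, 0, 50)
        assert ld.pairwise_dprime(g, "L1", "L2") == pytest.approx(1.0)

    def test_exact_independence(self):
        g = biallelic_genotypes(25, 25, 25, 25)
        assert ld.pairwise_dprime(g, "L1", "L2") == pytest.approx(0.0)

    def test_monomorphic_rejected(self):
        g = biallelic_genotypes(50, 50, 0, 0)
        with pytest.raises(ValueError, match="monomorphic"):
            ld.pairwise_dprime(g, "L1", "L2")

    def test_swap_and_relabel_invariance(self, small_dataset):
        g = small_dataset.genotypes
        la, lb = g.columns[0], g.columns[1]
        d1 = ld.pairwise_dprime(g, la, lb)
        assert ld.pairwise_dprime(g, lb, la) == pytest.approx(d1)
        relabeled = g.copy()
        relabeled[la] = relabeled[la] * 3 + 7  # order-preserving relabel
        assert ld.pairwise_dprime(relabeled, la, lb) == pytest.approx(d1)

    def test_multiallelic_reduces_to_classical_biallelic(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            c = rng.integers(1, 40, size=4)
            g = biallelic_genotypes(*c)
            n = c.sum()
            x = c.reshape(2, 2) / n
            p, q = x.sum(1), x.sum(0)
            d = x[0, 0] - p[0] * q[0]
            dmax = (min(p[0] * q[0], p[1] * q[1]) if d < 0
                    else min(p[0] * q[1], p[1] * q[0]))
            if dmax == 0:
                continue
            assert ld.pairwise_dprime(g, "L1", "L2") == pytest.approx(
                abs(d) / dmax, abs=1e-12)

    def test_bounds_on_simulated_pairs(self, small_dataset):
        g = small_dataset.genotypes
        for la, lb in zip(g.columns[:6], g.columns[6:12]):
            assert 0.0 <= ld.pairwise_dprime(g, la, lb) <= 1.0


class TestPermutationP:
    def test_extreme_case_minimum_p(self):
        g = biallelic_genotypes(50, 0, 0, 50)
        d, p = ld.permutation_pvalue(g, "L1", "L2", n_perm=99, seed=1)
        assert d == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_self_ld_is_extreme(self, small_dataset):
        g = small_dataset.genotypes.copy()
        g["SELF"] = g[g.columns[0]]
        d, p = ld.permutation_pvalue(g, g.columns[0], "SELF", n_perm=99, seed=2)
        assert d == pytest.approx(1.0)
        assert p <= 0.05

    def test_null_pvalues_superuniform(self):
        # independent loci: p should be (super)uniform on (0,1]
        cfg = simulate.default_config(seed=33, n_accessions=120, n_loci=40,
                                      n_subpops=2, fst=1e-4, null_rate=0.0)
        geno, _, _ = simulate.simulate_genotypes(cfg)
        rng = np.random.default_rng(0)
        ps = []
        cols = list(geno.columns)
        for _ in range(100):
            la, lb = rng.choice(cols, size=2, replace=False)
            _, p = ld.permutation_pvalue(geno, la, lb, n_perm=199,
                                         seed=int(rng.integers(2**31)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3
        assert np.mean(np.array(ps) < 0.05) < 0.12


class TestScanSummary:
    @pytest.fixture(scope="class")
    def scan(self):
        cfg = simulate.default_config(seed=35, n_accessions=140, n_loci=14,
                                      n_subpops=2, fst=0.3,
                                      admixture_alpha=0.05, null_rate=0.0)
        ds = simulate.simulate_dataset(cfg)
        subpops = ds.true_q.idxmax(axis=1)
        return ld.ld_scan(ds.genotypes, ds.marker_map, subpops,
                          n_perm=100, seed=4)

    def test_bin_counts_partition_significant_pairs(self, scan):
        pairs, summary = scan
        bins = [c for c in summary.columns if c.startswith("d_")]
        for _, row in summary.iterrows():
            assert row[bins].sum() == row["n_significant"]

    def test_ratios_sum_to_100(self, scan):
        _, summary = scan
        assert summary["ratio_pct"].sum() == pytest.approx(100.0, abs=0.5)

    def test_ratio_is_share_of_total_significant(self, scan):
        pairs, summary = scan
        total = (pairs["p_value"] < 0.05).sum()
        for _, row in summary.iterrows():
            assert row["ratio_pct"] == pytest.approx(
                100.0 * row["n_significant"] / total, abs=0.05)

    def test_small_subpopulation_skipped(self, small_dataset):
        labels = pd.Series("big", index=small_dataset.genotypes.index)
        labels.iloc[:3] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            pairs, _ = ld.ld_scan(small_dataset.genotypes.iloc[:, :4],
                                  small_dataset.marker_map, labels,
                                  n_perm=20, seed=1)
        assert set(pairs["subpop"]) == {"big"}


class TestDecay:
    def test_exact_fit_on_noiseless_curve(self):
        x = np.array([2.0, 5.0, 20.0, 60.0])
        pairs = pd.DataFrame({
            "subpop": "S", "locus_a": "a", "locus_b": "b",
            "dprime": -0.1 * np.log(x) + 0.9, "p_value": 0.001,
            "syntenic": True, "distance_cM": x,
        })
        fit = ld.fit_decay(pairs)
        assert fit.b == pytest.approx(-0.1, abs=1e-12)
        assert fit.c == pytest.approx(0.9, abs=1e-12)

    def test_single_distance_rejected(self):
        pairs = pd.DataFrame({
            "subpop": "S", "locus_a": "a", "locus_b": "b",
            "dprime": [0.5, 0.6, 0.7], "p_value": 0.01,
            "syntenic": True, "distance_cM": [10.0, 10.0, 10.0],
        })
        with pytest.raises(ValueError, match="distinct"):
            ld.fit_decay(pairs)

    def test_decay_distance_closed_form(self):
        fit = ld.DecayFit(b=-0.1, c=0.9, n_pairs=10, subpop="S")
        assert ld.decay_distance(fit, 0.4) == pytest.approx(np.exp(5.0))
        assert ld.decay_distance(fit, 0.9) == pytest.approx(1.0)

    def test_below_resolution_warns(self):
        fit = ld.DecayFit(b=-0.1, c=0.9, n_pairs=10, subpop="S")
        with pytest.warns(UserWarning, match="resolution"):
            x = ld.decay_distance(fit, 0.95)
        assert x < 1.0

    def test_no_decay_rejected(self):
        fit = ld.DecayFit(b=0.05, c=0.5, n_pairs=10, subpop="S")
        with pytest.raises(ValueError, match="decay"):
            ld.decay_distance(fit, 0.4)
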