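import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssrmap import association, simulate, structure


def identity_k(ids):
    return pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)


@pytest.fixture(scope="module")
def qtl_panel():
    cfg = simulate.default_config(seed=41, n_accessions=200, n_loci=10,
                                  n_subpops=3, fst=0.2, null_rate=0.0)
    cfg.qtl_spec = [simulate.QTL("GL", "SSR0004", None, 0.6)]
    cfg.target_h2 = {"GL": 0.8}
    ds = simulate.simulate_dataset(cfg)
    kin, _, _ = structure.kinship_matrix(ds.genotypes)
    return ds, kin


class TestREML:
    def test_identity_kinship_reduces_to_ols_split(self):
        rng = np.random.default_rng(1)
        n = 120
        y = 3 + rng.normal(size=n)
        X = np.ones((n, 1))
        fit = association.reml_variance_components(y, X, np.eye(n))
        # unstructured y on K=I: total variance matches the OLS residual
        # variance; the split between the two components is unidentified
        # beyond their sum
        assert fit.sigma_g2 + fit.sigma_e2 == pytest.approx(np.var(y, ddof=1),
                                                            rel=0.05)

    def test_scale_equivariance(self, qtl_panel):
        ds, kin = qtl_panel
        from ssrmap.quantgen import accession_trait_means

        y = accession_trait_means(ds.phenotypes, "GL", 2013)
        X = np.ones((len(y), 1))
        f1 = association.reml_variance_components(y.to_numpy(), X,
                                                  kin.to_numpy())
        f2 = association.reml_variance_components(2 * y.to_numpy(), X,
                                                  kin.to_numpy())
        assert f2.sigma_g2 == pytest.approx(4 * f1.sigma_g2, rel=1e-3)
        assert f2.sigma_e2 == pytest.approx(4 * f1.sigma_e2, rel=1e-3)

    def test_ratio_recovery_on_known_kinship(self):
        rng = np.random.default_rng(2)
        n = 300
        A = rng.normal(size=(n, 8))
        K = A @ A.T / 8
        K /= np.diag(K).mean()
        L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
        ratios = []
        for _ in range(10):
            g = L @ rng.normal(size=n) * np.sqrt(2.0)
            y = 5 + g + rng.normal(size=n)
            fit = association.reml_variance_components(y, np.ones((n, 1)), K)
            ratios.append(fit.sigma_g2 / fit.sigma_e2)
        assert np.median(ratios) == pytest.approx(2.0, rel=0.3)

    def test_rank_deficient_design_named(self):
        n = 30
        X = np.ones((n, 3))
        X[:, 1] = np.arange(n)
        X[:, 2] = 2 * X[:, 1]
        with pytest.raises(ValueError, match="collinear"):
            association.reml_variance_components(np.zeros(n), X, np.eye(n),
                                                 names=["int", "a", "b"])


class TestMarkerTest:
    def test_reduces_to_oneway_anova_under_identity(self, qtl_panel):
        ds, _ = qtl_panel
        from ssrmap.quantgen import accession_trait_means

        y = accession_trait_means(ds.phenotypes, "GL", 2013)
        kin = identity_k(y.index)
        vc = association.MixedModelFit(0.0, 1.0, np.zeros(1), 0.0, 0.0)
        for locus in ds.genotypes.columns[:5]:
            calls = ds.genotypes[locus]
            res = association.mlm_marker_test(y, None, kin, calls, vc,
                                              rare_min=2)
            if res is None:
                continue
            labels = association._collapse_classes(calls.dropna(), 2)
            groups = [y.loc[labels.index[labels == g]].to_numpy()
                      for g in labels.unique()]
            ref = stats.f_oneway(*groups)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_monomorphic_marker_skipped(self, qtl_panel):
        ds, kin = qtl_panel
        from ssrmap.quantgen import accession_trait_means

        y = accession_trait_means(ds.phenotypes, "GL", 2013)
        calls = pd.Series(pd.array([100] * len(y), dtype="Int64"),
                          index=y.index)
        assert association.mlm_marker_test(y, None, kin, calls) is None

    def test_null_calls_excluded(self, qtl_panel):
        ds, kin = qtl_panel
        from ssrmap.quantgen import accession_trait_means

        y = accession_trait_means(ds.phenotypes, "GL", 2013)
        calls = ds.genotypes[ds.genotypes.columns[0]].copy()
        calls.iloc[:20] = pd.NA
        res = association.mlm_marker_test(y, ds.true_q, kin, calls)
        assert res.n_used == len(y) - 20


class TestGenomeScan:
    def test_planted_qtl_has_smallest_p(self, qtl_panel):
        ds, kin = qtl_panel
        scan = association.genome_scan(ds.phenotypes, ds.genotypes,
                                       ds.marker_map, ds.true_q, kin)
        gl = scan[(scan["trait"] == "GL") & (scan["year"] == 2013)]
        assert gl.loc[gl["p_value"].idxmin(), "locus"] == "SSR0004"

    def test_row_count_completeness(self, qtl_panel):
        ds, kin = qtl_panel
        scan = association.genome_scan(ds.phenotypes, ds.genotypes,
                                       ds.marker_map, ds.true_q, kin)
        n_cells = ds.phenotypes.groupby(["trait", "year"]).ngroups
        assert len(scan) <= n_cells * ds.genotypes.shape[1]
        # every tested locus appears exactly once per trait-year cell
        per_cell = scan.groupby(["trait", "year"]).size()
        assert len(per_cell) == n_cells
        assert (per_cell == per_cell.iloc[0]).all()
        assert not scan.duplicated(["trait", "year", "locus"]).any()

    def test_accession_order_invariance(self, qtl_panel):
        ds, kin = qtl_panel
        perm = ds.genotypes.sample(frac=1.0, random_state=1).index
        s1 = association.genome_scan(ds.phenotypes, ds.genotypes,
                                     ds.marker_map, ds.true_q, kin)
        s2 = association.genome_scan(ds.phenotypes, ds.genotypes.loc[perm],
                                     ds.marker_map, ds.true_q.loc[perm],
                                     kin.loc[perm, perm])
        merged = s1.merge(s2, on=["trait", "year", "locus"], suffixes=("1", "2"))
        assert np.allclose(merged["p_value1"], merged["p_value2"], atol=1e-8)

    def test_pve_bounds(self, qtl_panel):
        ds, kin = qtl_panel
        scan = association.genome_scan(ds.phenotypes, ds.genotypes,
                                       ds.marker_map, ds.true_q, kin)
        assert scan["pve_pct"].between(0, 100).all()

    def test_results_summary_prints(self, qtl_panel):
        ds, kin = qtl_panel
        model = association.MixedAssociation.from_tables(
            ds.phenotypes, ds.genotypes, ds.true_q, kin, "GL", 2013,
            ds.marker_map)
        res = model.fit()
        text = res.summary()
        assert "GL" in text and "sigma_g2" in text


class TestFilter:
    def _rows(self, recs):
        return pd.DataFrame(recs, columns=["trait", "locus", "year",
                                           "p_value", "pve_pct"])

    def test_pve_threshold_strict(self):
        res = self._rows([("GL", "A", 2013, 0.01, 4.9),
                          ("GL", "B", 2013, 0.01, 5.03)])
        out = association.filter_significant(res, both_years=False)
        assert list(out["locus"]) == ["B"]

    def test_p_boundary_excluded(self):
        res = self._rows([("GL", "A", 2013, 0.05, 10.0)])
        assert association.filter_significant(res, both_years=False).empty

    def test_both_year_rule(self):
        res = self._rows([("GL", "A", 2013, 0.01, 8.0),
                          ("GL", "A", 2014, 0.20, 8.0),
                          ("GL", "B", 2013, 0.01, 8.0),
                          ("GL", "B", 2014, 0.04, 4.0)])
        out = association.filter_significant(res)
        assert sorted(out["locus"].unique()) == ["B"]

    def test_empty_input(self):
        res = self._rows([])
        assert association.filter_significant(res).empty
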