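"""Mixed-effect association scan: oracles, calibration, aggregation views."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deepradiomics.assoc import (count_per_kernel, fit_lme_pair, run_scan,
                                 top_features, top_gfs)
from deepradiomics.dae import DRFMatrix
from deepradiomics.genomics import GenomicFeatureTable
from deepradiomics.simulate import simulate_drf_matrix


def _gf_table(values: pd.DataFrame, category="risk_gene"):
    return GenomicFeatureTable(values=values,
                               categories=pd.Series(category,
                                                    index=values.columns))


class TestFitLmePair:
    def test_single_image_per_patient_reduces_to_ols(self):
        """With no replication the REML slope equals the closed-form OLS slope."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(30, 60))
            g = rng.normal(size=n)
            y = 0.4 * g + rng.normal(size=n)
            pats = [f"p{i}" for i in range(n)]
            fit = fit_lme_pair(y, pd.Series(g, index=pats), pats)
            ols = stats.linregress(g, y)
            assert abs(fit.beta1 - ols.slope) < 1e-5
            assert abs(fit.p - ols.pvalue) < 0.01

    def test_duplicate_images_collapse_to_patient_regression(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=20)
        yb = g + rng.normal(size=20)
        y, pats = [], []
        for i in range(20):
            k = int(rng.integers(2, 5))
            y += [yb[i]] * k
            pats += [f"p{i}"] * k
        fit = fit_lme_pair(np.array(y),
                           pd.Series(yb * 0 + g, index=[f"p{i}" for i in range(20)]),
                           pats)
        assert abs(fit.beta1 - stats.linregress(g, yb).slope) < 1e-6

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_statsmodels_mixedlm(self, seed):
        """Independent oracle: statsmodels MixedLM REML on the same data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        P = 35
        g = rng.normal(size=P)
        rows = []
        for i in range(P):
            u = rng.normal(scale=0.7)
            for _ in range(int(rng.integers(2, 7))):
                rows.append((f"p{i:02d}", g[i],
                             0.3 * g[i] + u + rng.normal(scale=0.5)))
        df = pd.DataFrame(rows, columns=["pat", "g", "y"])
        fit = fit_lme_pair(df["y"].to_numpy(),
                           pd.Series(g, index=[f"p{i:02d}" for i in range(P)]),
                           df["pat"].to_numpy())
        ref = sm.MixedLM.from_formula("y ~ g", groups="pat",
                                      data=df).fit(reml=True)
        assert fit.beta1 == pytest.approx(ref.params["g"], abs=1e-3)
        assert fit.se1 == pytest.approx(ref.bse["g"], rel=0.01)
        assert fit.sigma_u == pytest.approx(
            np.sqrt(ref.cov_re.iloc[0, 0]), rel=0.05)

    def test_constant_gf_rejected(self):
        pats = ["a", "a", "b", "b", "c", "c"]
        with pytest.raises(ValueError, match="constant"):
            fit_lme_pair(np.arange(6.0),
                         pd.Series(1.0, index=["a", "b", "c"]), pats)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="3 patients"):
            fit_lme_pair([1.0, 2.0], pd.Series({"a": 1.0, "b": 2.0}),
                         ["a", "b"])

    def test_invariants_of_fit(self):
        rng = np.random.default_rng(3)
        pats = np.repeat([f"p{i}" for i in range(10)], 3)
        y = rng.normal(size=30)
        g = pd.Series(rng.normal(size=10), index=[f"p{i}" for i in range(10)])
        fit = fit_lme_pair(y, g, pats)
        assert fit.se1 > 0
        assert 0 < fit.p <= 1
        assert fit.sigma_u >= 0 and fit.sigma_e >= 0
        assert fit.n_images == 30 and fit.n_patients == 10


def _scan_inputs(seed=0, n_drfs=20, n_gfs=4, n_patients=30, informative=0):
    rng = np.random.default_rng(seed)

    class _Lat:
        def __init__(self, pid, z):
            self.patient_id, self.z = pid, z

    lats = [_Lat(f"p{i:02d}", rng.normal(size=3)) for i in range(n_patients)]
    df = simulate_drf_matrix(lats, n_drfs=n_drfs, n_informative=informative,
                             images_per_patient_range=(2, 5), seed=seed + 1)
    gf_vals = pd.DataFrame(rng.normal(size=(n_patients, n_gfs)),
                           index=[l.patient_id for l in lats],
                           columns=[f"gf{j}" for j in range(n_gfs)])
    return DRFMatrix.from_frame(df), _gf_table(gf_vals)


class TestRunScan:
    def test_bh_adjustment_matches_hand_computation(self):
        """Adjusted p equals the step-up BH transform of the scan's raw p."""
        drfs, gfs = _scan_inputs(seed=4)
        table = run_scan(drfs, gfs)
        for cat, sub in table.groupby("gf_category"):
            p = sub["p"].to_numpy()
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank_from_top, idx in enumerate(order[::-1]):
                rank = m - rank_from_top
                running = min(running, p[idx] * m / rank)
                adj[idx] = running
            np.testing.assert_allclose(sub["p_adj"].to_numpy(), adj,
                                       rtol=1e-10)

    def test_pvalues_uniform_under_global_null(self):
        drfs, gfs = _scan_inputs(seed=8, n_drfs=200, n_gfs=10, n_patients=40)
        table = run_scan(drfs, gfs)
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_row_order_invariance(self):
        drfs, gfs = _scan_inputs(seed=5)
        base = run_scan(drfs, gfs)
        perm = np.random.default_rng(0).permutation(drfs.values.shape[0])
        shuffled = DRFMatrix(values=drfs.values[perm],
                             feature_ids=drfs.feature_ids,
                             kernel_map=drfs.kernel_map,
                             image_index=drfs.image_index.iloc[perm]
                             .reset_index(drop=True))
        again = run_scan(shuffled, gfs)
        pd.testing.assert_frame_equal(base, again)

    def test_significance_shrinks_with_alpha(self):
        drfs, gfs = _scan_inputs(seed=6, informative=10)
        t5 = run_scan(drfs, gfs, alpha=0.05)
        t1 = run_scan(drfs, gfs, alpha=0.01)
        sig5 = set(map(tuple, t5.loc[t5.significant, ["drf_id", "gf_id"]].values))
        sig1 = set(map(tuple, t1.loc[t1.significant, ["drf_id", "gf_id"]].values))
        assert sig1 <= sig5

    def test_adjusted_p_never_below_raw(self):
        drfs, gfs = _scan_inputs(seed=7)
        table = run_scan(drfs, gfs)
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_no_overlapping_patients_rejected(self):
        drfs, gfs = _scan_inputs(seed=9)
        other = gfs.values.copy()
        other.index = [f"q{i}" for i in range(len(other))]
        with pytest.raises(ValueError, match="overlap"):
            run_scan(drfs, _gf_table(other))


def _toy_table(rows):
    return pd.DataFrame(rows, columns=["drf_id", "kernel", "gf_id",
                                       "gf_category", "beta1", "p", "p_adj",
                                       "significant"])


class TestAggregations:
    def test_empty_table_gives_16_zero_rows(self):
        out = count_per_kernel(_toy_table([]))
        assert out.shape == (16, 4)
        assert (out.to_numpy() == 0).all()

    def test_counts_land_in_their_kernel(self):
        rows = [(f"fea_{i}", 13, f"g{i}", "risk_gene", 1.0, 1e-4, 1e-3, True)
                for i in range(5)]
        out = count_per_kernel(_toy_table(rows))
        assert out.loc[13, "risk_gene"] == 5 and out.loc[13, "total"] == 5
        assert out.drop(index=13).to_numpy().sum() == 0

    def test_totals_are_category_sums(self):
        rows = [("fea_1", 2, "g1", "risk_gene", 1.0, 0.001, 0.01, True),
                ("fea_1", 2, "s1", "signature", 1.0, 0.001, 0.01, True),
                ("fea_2", 7, "pw1", "pathway", 1.0, 0.001, 0.01, True)]
        out = count_per_kernel(_toy_table(rows))
        assert (out["total"] == out[["risk_gene", "signature",
                                     "pathway"]].sum(axis=1)).all()

    def test_top_features_ranked_by_hit_count(self):
        rows = ([("fea_2", 1, f"g{i}", "risk_gene", 1.0, 1e-4, 1e-3, True)
                 for i in range(3)]
                + [("fea_9", 1, "g0", "risk_gene", 1.0, 1e-4, 1e-3, True)])
        out = top_features(_toy_table(rows), k=30)
        assert out["drf_id"].tolist() == ["fea_2", "fea_9"]
        assert (out["total"] == out[["risk_gene", "signature",
                                     "pathway"]].sum(axis=1)).all()

    def test_top_features_short_list_when_few_hits(self):
        rows = [("fea_1", 1, "g1", "risk_gene", 1.0, 1e-4, 1e-3, True)]
        assert len(top_features(_toy_table(rows), k=10)) == 1

    def test_top_gfs_kernel_ordering_and_partition(self):
        rows = ([("fea_%d" % i, 12, "g1", "risk_gene", 1.0, 1e-4, 1e-3, True)
                 for i in range(10)]
                + [("fea_99", 3, "g1", "risk_gene", 1.0, 1e-4, 1e-3, True)])
        out = top_gfs(_toy_table(rows), k_per_category=5)
        rg = out["risk_gene"]
        assert rg.loc[0, "gf_id"] == "g1"
        assert rg.loc[0, "top_kernels"][0] == 12
        assert rg.loc[0, "n_significant_drfs"] == 11
        assert out["pathway"].empty and out["signature"].empty
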