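import numpy as np
import pytest

from admetk import endogenous as en
from admetk.peakmatrix import PeakMatrix

from conftest import make_matrix


class TestPrefilter:
    def _matrix(self, extra_rows=(), extra_classes=()):
        # layout: 3 exposed, 3 control, 3 QC, 2 blank
        classes = ["exposed"] * 3 + ["control"] * 3 + ["QC"] * 3 + ["blank"] * 2
        rows = [
            [100, 110, 90, 95, 105, 100, 100, 101, 99, 2, 3],  # clean feature
        ] + list(extra_rows)
        return make_matrix(rows, classes)

    def test_blank_filter(self):
        # biological median 100 < 20 x blank median 10 -> removed
        pm = self._matrix(extra_rows=[
            [100, 100, 100, 100, 100, 100, 100, 100, 100, 10, 10],
        ])
        out, ledger = en.prefilter(pm)
        assert out.feature_ids == ["F1"]
        assert ledger.set_index("rule").loc["blank", "n_removed"] == 1

    def test_qc_rsd_zero_kept(self):
        pm = self._matrix()
        out, _ = en.prefilter(pm)
        assert "F1" in out.feature_ids

    def test_high_qc_rsd_removed(self):
        pm = self._matrix(extra_rows=[
            [100, 100, 100, 100, 100, 100, 10, 100, 400, None, None],
        ])
        out, ledger = en.prefilter(pm)
        assert out.feature_ids == ["F1"]
        assert ledger.set_index("rule").loc["qc_rsd", "n_removed"] == 1

    def test_xeno_ids_removed_unconditionally(self):
        pm = self._matrix()
        out, ledger = en.prefilter(pm, xeno_ids={"F1"})
        assert out.n_features == 0
        assert ledger.set_index("rule").loc["xenobiotic", "n_removed"] == 1

    def test_ledger_counts_sum_to_removed(self):
        pm = self._matrix(extra_rows=[
            [100, 100, 100, 100, 100, 100, 100, 100, 100, 10, 10],
            [100, 100, 100, 100, 100, 100, 10, 100, 400, None, None],
            [None, None, 100, None, None, 100, 100, 100, 100, None, None],
        ])
        out, ledger = en.prefilter(pm)
        removed_features = ledger[ledger["rule"] != "sample_missing"]["n_removed"].sum()
        assert removed_features == pm.n_features - out.n_features

    def test_no_qc_errors(self):
        pm = make_matrix([[1, 2]], ["exposed", "control"])
        with pytest.raises(ValueError, match="QC"):
            en.prefilter(pm)

    def test_no_blanks_skips_blank_filter(self):
        classes = ["exposed"] * 3 + ["control"] * 3 + ["QC"] * 3
        pm = make_matrix([[100] * 9], classes)
        out, ledger = en.prefilter(pm)
        assert "skipped" in ledger.set_index("rule").loc["blank", "ids"]
        assert out.n_features == 1


class TestPqn:
    def test_doubled_sample_gets_coefficient_two(self):
        ref = np.array([10.0, 20.0, 30.0])
        pm = make_matrix(
            np.column_stack([ref, 2 * ref]).tolist(), ["QC", "exposed"]
        )
        norm, coefs = en.pqn_normalise(pm, reference=ref)
        np.testing.assert_allclose(coefs, [1.0, 2.0])
        np.testing.assert_allclose(norm.intensity[:, 1], ref)

    def test_self_reference_identity(self):
        pm = make_matrix([[10.0], [20.0], [30.0]], ["exposed"])
        norm, coefs = en.pqn_normalise(pm, reference=pm.intensity[:, 0])
        np.testing.assert_allclose(coefs, [1.0])
        np.testing.assert_allclose(norm.intensity, pm.intensity)

    def test_endogenous_coefficients_applied_to_all_features(self):
        # coefficient from features F2, F3 only; F1 must be scaled identically
        pm = make_matrix(
            [[8, 16], [10, 30], [20, 60]], ["QC", "exposed"]
        )
        ref = np.array([8.0, 10.0, 20.0])
        norm, coefs = en.pqn_normalise(pm, reference=ref,
                                       coefficient_source=["F2", "F3"])
        np.testing.assert_allclose(coefs, [1.0, 3.0])
        assert norm.intensity[0, 1] == pytest.approx(16 / 3)

    def test_all_missing_sample_errors(self):
        pm = make_matrix([[10.0, None]], ["QC", "exposed"])
        with pytest.raises(ValueError):
            en.pqn_normalise(pm, reference=np.array([10.0]))


def brute_force_knn(x, feature_ids, k):
    """Naive reference kNN imputation (unit-variance rows, shared columns)."""
    nf = x.shape[0]
    mu = np.nanmean(x, axis=1, keepdims=True)
    sd = np.nanstd(x, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    out = x.copy()
    for i in range(nf):
        for col in np.flatnonzero(np.isnan(x[i])):
            dists = []
            for j in range(nf):
                if j == i:
                    continue
                shared = ~np.isnan(z[i]) & ~np.isnan(z[j])
                if not shared.any():
                    continue
                d = np.sqrt(np.mean((z[i, shared] - z[j, shared]) ** 2))
                dists.append((d, feature_ids[j], j))
            dists.sort()
            vals = []
            for _, _, j in dists:
                if not np.isnan(x[j, col]):
                    vals.append(x[j, col])
                if len(vals) == k:
                    break
            out[i, col] = np.mean(vals) if vals else np.nanmean(x[i])
    return out


class TestKnnImpute:
    def test_complete_matrix_identity(self):
        pm = make_matrix([[1, 2], [3, 4], [5, 6]], ["exposed", "control"])
        out = en.knn_impute(pm)
        np.testing.assert_array_equal(out.intensity, pm.intensity)

    def test_identical_neighbours_force_value(self):
        rows = [[5.0, 7.0]] * 6
        rows[0] = [5.0, None]
        pm = make_matrix(rows, ["exposed", "control"])
        out = en.knn_impute(pm, k=5)
        assert out.intensity[0, 1] == pytest.approx(7.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        x = np.exp(rng.normal(5, 1, (50, 10)))
        x[rng.random(x.shape) < 0.05] = np.nan
        # guarantee every feature retains observations
        x[:, 0] = np.exp(rng.normal(5, 1, 50))
        classes = ["exposed"] * 5 + ["control"] * 5
        pm = make_matrix(x.tolist(), classes)
        out = en.knn_impute(pm, k=5)
        expected = brute_force_knn(pm.intensity.copy(), pm.feature_ids, k=5)
        np.testing.assert_allclose(out.intensity, expected, rtol=1e-10)

    def test_fully_missing_feature_errors(self):
        pm = make_matrix([[None, None], [1, 2]], ["exposed", "control"])
        with pytest.raises(ValueError):
            en.knn_impute(pm)


class TestGlog:
    def test_small_lambda_limit_is_log(self):
        x = np.array([10.0, 100.0, 1000.0])
        np.testing.assert_allclose(en.glog(x, 1e-12), np.log(x), rtol=1e-8)

    def test_finite_at_zero(self):
        lam = 4.0
        assert en.glog(0.0, lam) == pytest.approx(np.log(np.sqrt(lam) / 2))

    def test_monotone(self):
        x = np.linspace(0, 1e6, 101)
        y = en.glog(x, 1e4)
        assert np.all(np.diff(y) > 0)

    def test_nonpositive_lambda_errors(self):
        with pytest.raises(ValueError):
            en.glog(np.ones(3), 0.0)

    def test_transform_requires_complete_matrix(self):
        pm = make_matrix([[1, None]], ["exposed", "control"])
        with pytest.raises(ValueError):
            en.glog_transform(pm, lam=1.0)


class TestExposureTests:
    def test_identical_distributions(self):
        rng = np.random.default_rng(2)
        v = rng.normal(100, 5, 6)
        pm = make_matrix([list(v) + list(v)], ["exposed"] * 6 + ["control"] * 6)
        res = en.exposure_tests(pm)
        assert res.loc[0, "fold_change"] == pytest.approx(1.0)
        assert res.loc[0, "p_value"] > 0.9

    def test_large_shift_detected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(200, 1, 5)  # 10 SD above control in units of SD=1
        b = rng.normal(190, 1, 5)
        pm = make_matrix([list(a) + list(b)], ["exposed"] * 5 + ["control"] * 5)
        res = en.exposure_tests(pm)
        assert res.loc[0, "q_value"] < 0.05

    def test_bh_hand_computation(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_variance_gives_nan_p(self):
        pm = make_matrix([[5, 5, 5, 5]], ["exposed"] * 2 + ["control"] * 2)
        res = en.exposure_tests(pm)
        assert np.isnan(res.loc[0, "p_value"])

    def test_recovers_planted_responders(self):
        """>=90% of 1.5-SD class shifts recovered at q < 0.05 with n=9+9."""
        from admetk.synthdata import SimConfig, simulate
        from admetk.peakmatrix import split_by_feature_ids

        cfg = SimConfig(seed=5, n_exposed=9, n_control=9,
                        timepoints={"day15": 1.0})
        matrix, truth, _ = simulate(cfg)
        _, endo = split_by_feature_ids(matrix, truth.xenobiotic_ids())
        filtered, _ = en.prefilter(endo)
        norm, _ = en.pqn_normalise(filtered)
        res = en.exposure_tests(norm).set_index("feature_id")
        planted = [f for f in filtered.feature_ids
                   if truth.roles[f] == "class_shifted"]
        recovered = (res.loc[planted, "q_value"] < 0.05).mean()
        assert recovered >= 0.9


class TestPca:
    def test_collinear_data_pc1_explains_all(self):
        t = np.arange(8, dtype=float)
        pm = make_matrix(
            [list(2 * t), list(-t + 30), list(5 * t)],
            ["exposed"] * 4 + ["control"] * 4,
        )
        _, _, ev = en.pca_scores(pm)
        assert ev.iloc[0] == pytest.approx(1.0)

    def test_rotation_invariance_of_explained_variance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(loc=50, size=(5, 10))
        pm = make_matrix(x.tolist(), ["exposed"] * 5 + ["control"] * 5)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        pm_rot = make_matrix((q @ x + 200).tolist(), ["exposed"] * 5 + ["control"] * 5)
        _, _, ev1 = en.pca_scores(pm)
        _, _, ev2 = en.pca_scores(pm_rot)
        np.testing.assert_allclose(ev1.values, ev2.values, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(9)
        x = rng.normal(loc=50, size=(6, 8))
        pm = make_matrix(x.tolist(), ["exposed"] * 4 + ["control"] * 4)
        scores, loadings, _ = en.pca_scores(pm)
        recon = scores.values @ loadings.values.T + x.T.mean(axis=0)
        np.testing.assert_allclose(recon, x.T, atol=1e-8)

    def test_too_few_samples_errors(self):
        pm = make_matrix([[1.0]], ["exposed"])
        with pytest.raises(ValueError):
            en.pca_scores(pm)
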