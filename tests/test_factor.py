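"""Latent factor model: concatenation, VB-ARD inference, normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import subspace_angles
from scipy.stats import norm

from villagefactor.factor import (
    LatentFactorAnalysis,
    adjust_for_age,
    concatenate_celltypes,
    quantile_normalize,
)
from villagefactor.pseudobulk import CellTypePseudobulk
from villagefactor.simulate import simulate_factor_matrix


def _pb_pair(cell_type, genes, donors, rng):
    raw = pd.DataFrame(
        rng.integers(1, 200, size=(len(genes), len(donors))),
        index=genes, columns=donors,
    )
    resid = pd.DataFrame(
        rng.normal(size=(len(genes), len(donors))), index=genes, columns=donors
    )
    return (
        CellTypePseudobulk(cell_type, resid, "residual_sum"),
        CellTypePseudobulk(cell_type, raw, "raw_sum", donor_umis=raw.sum(axis=0)),
    )


class TestConcatenate:
    def test_top_half_filter_and_suffix(self, rng):
        genes = [f"G{i}" for i in range(10)]
        donors = [f"d{i}" for i in range(5)]
        res1, raw1 = _pb_pair("glut", genes, donors, rng)
        res2, raw2 = _pb_pair("astro", genes, donors, rng)
        concat = concatenate_celltypes([res1, res2], [raw1, raw2],
                                       top_fraction=0.5)
        assert len(concat.features) == 10  # 5 per type
        assert all(f.endswith(("_glut", "_astro")) for f in concat.features)

    def test_top_fraction_one_keeps_everything(self, rng):
        genes = [f"G{i}" for i in range(8)]
        donors = [f"d{i}" for i in range(4)]
        res, raw = _pb_pair("t", genes, donors, rng)
        concat = concatenate_celltypes([res], [raw], top_fraction=1.0)
        assert len(concat.features) == 8

    def test_same_gene_two_types_two_features(self, rng):
        donors = [f"d{i}" for i in range(4)]
        res1, raw1 = _pb_pair("a", ["ACAP3"], donors, rng)
        res2, raw2 = _pb_pair("b", ["ACAP3"], donors, rng)
        concat = concatenate_celltypes([res1, res2], [raw1, raw2],
                                       top_fraction=1.0)
        assert set(concat.features) == {"ACAP3_a", "ACAP3_b"}

    def test_donor_missing_a_type_dropped_with_warning(self, rng):
        donors = [f"d{i}" for i in range(5)]
        res1, raw1 = _pb_pair("a", ["G1", "G2"], donors, rng)
        res2, raw2 = _pb_pair("b", ["G1", "G2"], donors[:-1], rng)
        with pytest.warns(UserWarning, match="d4"):
            concat = concatenate_celltypes([res1, res2], [raw1, raw2])
        assert concat.dropped_donors == ["d4"]
        assert "d4" not in concat.donors

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            concatenate_celltypes([], [])


class TestQuantileNormalize:
    def test_three_values(self):
        out = quantile_normalize([3, 1, 2])
        expected = norm.ppf([0.75, 0.25, 0.5])
        assert np.allclose(out, expected)
        assert out[0] == pytest.approx(0.6745, abs=1e-4)

    def test_median_of_odd_input_is_zero(self):
        out = quantile_normalize([10.0, -3.0, 5.0, 99.0, 7.0])
        assert out[np.argsort([10.0, -3.0, 5.0, 99.0, 7.0])[2]] == pytest.approx(0.0)

    def test_preserves_sort_order(self, rng):
        x = rng.normal(size=31)
        out = quantile_normalize(x)
        assert np.array_equal(np.argsort(x), np.argsort(out))


class TestAdjustForAge:
    def test_exact_linear_scores_give_zero_residuals(self):
        ages = np.array([30.0, 40.0, 55.0, 70.0])
        scores = 2.0 - 0.01 * ages
        assert np.allclose(adjust_for_age(scores, ages), 0.0, atol=1e-12)

    def test_residuals_orthogonal_to_age(self, rng):
        ages = rng.uniform(22, 97, size=50)
        scores = rng.normal(size=50)
        resid = adjust_for_age(scores, ages)
        assert abs(resid @ (ages - ages.mean())) < 1e-8

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="age not identifiable"):
            adjust_for_age([1.0, 2.0, 3.0], [50.0, 50.0, 50.0])

    def test_case_gap_preserved_when_age_matched(self):
        # age-matched cases/controls: the case deficit survives adjustment
        ages = np.tile(np.linspace(30, 80, 20), 2)
        case = np.repeat([1.0, 0.0], 20)
        scores = -0.02 * ages - 0.5 * case
        resid = adjust_for_age(scores, ages)
        gap = resid[case == 1].mean() - resid[case == 0].mean()
        assert gap == pytest.approx(-0.5, abs=1e-10)


class TestVbArd:
    def test_rank_one_noiseless_recovery(self, rng):
        u = rng.normal(size=(50, 1))
        v = rng.normal(size=(40, 1))
        res = LatentFactorAnalysis(u @ v.T).fit(k=1, method="vb_ard")
        r = np.corrcoef(res.scores.to_numpy()[:, 0], u[:, 0])[0, 1]
        assert abs(r) >= 0.999

    def test_elbo_monotone_nondecreasing(self):
        X, _, _ = simulate_factor_matrix(n_donors=60, n_genes_per_type=40,
                                         seed=2)
        res = LatentFactorAnalysis(X).fit(k=5, method="vb_ard")
        d = np.diff(res.elbo_trace)
        assert np.all(d >= -1e-6 * np.abs(res.elbo_trace[:-1]))

    def test_planted_three_factor_recovery_and_shrinkage(self, rng):
        # orthogonal planted scores, distinct strengths, SNR 2, k=10
        n, p, K = 180, 300, 3
        S = np.linalg.qr(rng.normal(size=(n, K)))[0] * np.sqrt(n)
        L = rng.normal(size=(p, K)) * np.array([1.0, 0.6, 0.35])
        sig = S @ L.T
        X = sig + rng.normal(0, np.sqrt(sig.var() / 2.0), size=sig.shape)
        res = LatentFactorAnalysis(X).fit(k=10, method="vb_ard")
        Sf = res.scores.to_numpy()
        for k in range(K):
            best = max(
                abs(np.corrcoef(Sf[:, j], S[:, k])[0, 1]) for j in range(10)
            )
            assert best >= 0.9
        shares = res.factor_variance_shares().to_numpy()
        assert (shares < 0.05).sum() >= 4  # surplus factors shrunk by ARD
        retained = shares >= 0.05
        C = np.corrcoef(Sf[:, retained].T)
        np.fill_diagonal(C, 0.0)
        assert np.abs(C).max() <= 0.3  # factor independence

    def test_vb_matches_pca_subspace_noiseless(self, rng):
        n, K = 80, 3
        S = np.linalg.qr(rng.normal(size=(n, K)))[0] * np.sqrt(n)
        L = rng.normal(size=(60, K)) * np.array([1.0, 0.7, 0.4])
        X = S @ L.T
        vb = LatentFactorAnalysis(X).fit(k=K, method="vb_ard", tol=1e-10,
                                         max_iter=2000)
        pca = LatentFactorAnalysis(X).fit(k=K, method="pca")
        ang = subspace_angles(vb.scores.to_numpy(), pca.scores.to_numpy())
        assert np.max(ang) < 1e-3

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(size=(10, 8))
        with pytest.raises(ValueError):
            LatentFactorAnalysis(X).fit(k=8)
        with pytest.raises(ValueError):
            LatentFactorAnalysis(X).fit(k=0)

    def test_sign_convention_max_loading_positive(self):
        X, _, _ = simulate_factor_matrix(n_donors=60, n_genes_per_type=40,
                                         seed=3)
        res = LatentFactorAnalysis(X).fit(k=4)
        L = res.loadings.to_numpy()
        for k in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, k])), k] >= 0


class TestSummaries:
    def test_rank_one_noiseless_variance_explained_is_one(self, rng):
        u = rng.normal(size=(30, 1))
        v = rng.normal(size=(25, 1))
        X = u @ v.T
        res = LatentFactorAnalysis(X, center=False).fit(k=1, method="pca")
        total, per = res.variance_explained()
        assert total == pytest.approx(1.0, abs=1e-10)
        assert per.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_single_celltype_loading_composition(self, rng):
        # factor loading only on astrocyte features -> 100% astrocyte
        features = [f"G{i}_astrocyte" for i in range(20)] + [
            f"G{i}_neuron" for i in range(20)
        ]
        scores = rng.normal(size=(40, 1))
        loadings = np.vstack([rng.normal(size=(20, 1)), np.zeros((20, 1))])
        X = pd.DataFrame(scores @ loadings.T, columns=features)
        res = LatentFactorAnalysis(X).fit(k=1, method="pca")
        comp = res.celltype_composition(top_n=20)
        assert comp.loc["LF1", "astrocyte"] == pytest.approx(1.0)

    def test_variance_explained_nondecreasing_in_k(self):
        X, _, _ = simulate_factor_matrix(
            n_donors=60, n_genes_per_type=40, n_factors=3, seed=4
        )
        ve = []
        model = LatentFactorAnalysis(X)
        for k in range(1, 8):
            total, _ = model.fit(k=k, method="pca").variance_explained()
            ve.append(total)
        assert np.all(np.diff(ve) >= -1e-10)

    def test_top_n_clamped_with_warning(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 10)),
                         columns=[f"G{i}_t" for i in range(10)])
        res = LatentFactorAnalysis(X).fit(k=2, method="pca")
        with pytest.warns(UserWarning, match="clamped"):
            comp = res.celltype_composition(top_n=1000)
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_summary_renders(self):
        X, _, _ = simulate_factor_matrix(n_donors=40, n_genes_per_type=30,
                                         seed=5)
        res = LatentFactorAnalysis(X).fit(k=3)
        text = res.summary(top_n=50)
        assert "variance explained" in text
        assert "vb_ard" in text

    def test_hdf5_round_trip(self, tmp_path, rng):
        import h5py

        X = rng.normal(size=(20, 15))
        res = LatentFactorAnalysis(X).fit(k=2, method="pca")
        path = tmp_path / "model.h5"
        res.to_hdf5(path)
        with h5py.File(path) as f:
            assert f.attrs["k"] == 2
            assert np.allclose(f["scores"][...], res.scores.to_numpy())
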