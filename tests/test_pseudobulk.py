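"""Residual normalization, pseudobulk aggregation and donor conformity QC."""

import numpy as np
import pandas as pd
import pytest

from villagefactor.pseudobulk import (
    CellTypePseudobulk,
    aggregate_pseudobulk,
    conformity_scores,
    flag_outlier_donors,
    modified_z,
    pearson_residuals,
    proportion_conformity_scores,
)


class TestPearsonResiduals:
    def test_uniform_gene_equal_depth_residuals_zero(self):
        counts = pd.DataFrame(np.full((5, 8), 3))
        r = pearson_residuals(counts, theta=10.0)
        assert np.allclose(r.to_numpy(), 0.0, atol=1e-12)

    def test_infinite_theta_is_poisson_residual(self, rng):
        counts = pd.DataFrame(rng.poisson(5.0, size=(20, 30)))
        r = pearson_residuals(counts, theta=np.inf, clip=1e9)
        X = counts.to_numpy(dtype=float)
        depth = X.sum(axis=0)
        mu = np.outer(X.sum(axis=1) / X.sum(), depth)
        expected = (X - mu) / np.sqrt(mu)
        assert np.allclose(r.to_numpy(), expected)

    def test_all_zero_gene_gives_zero_row(self):
        counts = pd.DataFrame(np.vstack([np.zeros(6), np.arange(6)]).astype(int))
        r = pearson_residuals(counts, theta=10.0)
        assert np.allclose(r.iloc[0].to_numpy(), 0.0)

    def test_residual_variance_near_unity_on_nb_counts(self, rng):
        # simulate from the generative model at known theta
        n_genes, n_cells, theta = 300, 400, 10.0
        p = rng.dirichlet(np.ones(n_genes) * 5)
        depth = rng.integers(800, 1200, size=n_cells)
        mu = np.outer(p, depth)
        counts = pd.DataFrame(rng.negative_binomial(theta, theta / (theta + mu)))
        r = pearson_residuals(counts, theta=theta)
        var = r.to_numpy().var(axis=1)
        frac = np.mean((var >= 0.5) & (var <= 2.0))
        assert frac >= 0.95

    def test_clip_bound_default_sqrt_n(self):
        counts = pd.DataFrame(np.eye(4, 16, dtype=int) * 1000 + 1)
        r = pearson_residuals(counts, theta=np.inf)
        assert r.to_numpy().max() <= np.sqrt(16) + 1e-12


class TestAggregate:
    def _maps(self, cells, donors, types):
        return (pd.Series(donors, index=cells), pd.Series(types, index=cells))

    def test_single_cell_pseudobulk_is_that_cell(self):
        counts = pd.DataFrame({"c1": [1, 2, 3]}, index=["g1", "g2", "g3"])
        dm, tm = self._maps(["c1"], ["d1"], ["astro"])
        pbs = aggregate_pseudobulk(counts, dm, tm, mode="raw_sum")
        assert len(pbs) == 1
        assert list(pbs[0].matrix["d1"]) == [1, 2, 3]

    def test_additivity_over_donor_split(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 10, size=(6, 10)),
            columns=[f"c{i}" for i in range(10)],
        )
        dm, tm = self._maps(
            counts.columns, ["d1"] * 5 + ["d2"] * 5, ["t"] * 10
        )
        pbs = aggregate_pseudobulk(counts, dm, tm, mode="raw_sum")
        total = pbs[0].matrix.sum(axis=1)
        assert np.array_equal(total.to_numpy(), counts.sum(axis=1).to_numpy())

    def test_conserves_totals_in_raw_mode(self, village_counts_df, village_sim):
        pbs = aggregate_pseudobulk(
            village_counts_df, village_sim.cell_to_donor,
            village_sim.cell_to_type, mode="raw_sum",
        )
        total = sum(pb.matrix.to_numpy().sum() for pb in pbs)
        assert total == village_counts_df.to_numpy().sum()

    def test_unmapped_barcode_raises_with_offenders(self):
        counts = pd.DataFrame({"c1": [1], "mystery": [2]})
        dm, tm = self._maps(["c1"], ["d1"], ["t"])
        with pytest.raises(ValueError, match="mystery"):
            aggregate_pseudobulk(counts, dm, tm, mode="raw_sum")

    def test_absent_donor_recorded(self):
        counts = pd.DataFrame(
            {"c1": [1], "c2": [2]}, index=["g"]
        )
        dm = pd.Series({"c1": "d1", "c2": "d2"})
        tm = pd.Series({"c1": "t1", "c2": "t2"})
        pbs = aggregate_pseudobulk(counts, dm, tm, mode="raw_sum")
        by_type = {pb.cell_type: pb for pb in pbs}
        assert by_type["t1"].absent_donors == ["d2"]
        assert by_type["t2"].absent_donors == ["d1"]


class TestConformity:
    def _pb(self, matrix):
        return CellTypePseudobulk("t", matrix, "raw_sum",
                                  donor_umis=matrix.sum(axis=0))

    def test_identical_donors_conformity_one(self):
        col = pd.Series(np.arange(1, 21))
        m = pd.DataFrame({f"d{i}": col for i in range(5)})
        report = conformity_scores([self._pb(m)])
        assert np.allclose(report.scores.to_numpy(), 1.0)

    def test_shuffled_donor_is_strictly_lowest(self, rng):
        base = rng.gamma(2, 50, size=200)
        m = pd.DataFrame(
            {f"d{i}": np.round(base * rng.lognormal(0, 0.05, 200))
             for i in range(6)}
        )
        m["weird"] = rng.permutation(m["d0"].to_numpy())
        report = conformity_scores([self._pb(m)])
        assert report.scores.idxmin() == "weird"

    def test_gene_filter_threshold_on_scaled_column(self):
        # one donor scaled to 1e5: genes at >=10 per 1e5 are kept exactly
        m = pd.DataFrame({
            "d1": [10, 9, 100, 0],
            "d2": [10, 9, 100, 0],
            "d3": [10, 9, 100, 0],
        }, index=["keep_edge", "drop", "keep_big", "drop_zero"])
        scale = 1e5 / m["d1"].sum()
        assert m["d1"].mul(scale).loc["keep_edge"] >= 10
        report = conformity_scores([self._pb(m)])
        # with only kept genes [keep_edge, keep_big] identical everywhere
        assert np.allclose(report.scores.to_numpy(), 1.0)

    def test_fewer_than_three_donors_rejected(self):
        m = pd.DataFrame({"d1": [1, 2], "d2": [2, 3]})
        with pytest.raises(ValueError, match="conformity undefined"):
            conformity_scores([self._pb(m)])

    def test_invariant_to_donor_column_order(self, rng):
        m = pd.DataFrame(rng.integers(0, 100, size=(50, 6)),
                         columns=[f"d{i}" for i in range(6)])
        a = conformity_scores([self._pb(m)])
        perm = ["d3", "d0", "d5", "d1", "d4", "d2"]
        b = conformity_scores([self._pb(m[perm])])
        assert np.allclose(
            a.scores.loc[perm].to_numpy(), b.scores.to_numpy()
        )


class TestModifiedZ:
    def test_median_maps_to_zero(self):
        mz = modified_z([1.0, 2.0, 3.0])
        assert mz[1] == pytest.approx(0.0)

    def test_one_mad_above_median_is_0_6745(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        med = scores.median()
        mad = (scores - med).abs().median()
        target = med + mad
        assert target in set(scores)  # value exactly one MAD above median
        mz = modified_z(scores)
        assert mz[scores == target].iloc[0] == pytest.approx(0.6745)

    def test_frozen_hand_evaluation(self):
        # direct formula evaluation: median 0.915, MAD 0.015
        mz = modified_z([0.90, 0.91, 0.92, 0.93, 0.94, 0.50])
        assert mz.iloc[-1] == pytest.approx(0.6745 * (0.50 - 0.915) / 0.015)
        assert mz.iloc[-1] == pytest.approx(-18.6611666667)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="degenerate spread"):
            modified_z([1.0, 1.0, 1.0, 1.0])


class TestFlagging:
    def _report(self, values, donors):
        from villagefactor.pseudobulk import _report_from_scores

        return _report_from_scores(pd.Series(values, index=donors))

    def test_homogeneous_donors_no_exclusions(self, rng):
        donors = [f"d{i}" for i in range(10)]
        expr = self._report(rng.normal(0.95, 0.005, 10), donors)
        prop = self._report(rng.normal(0.9, 0.01, 10), donors)
        umis = pd.DataFrame({"t": np.full(10, 5000.0)}, index=donors)
        flags = flag_outlier_donors(expr, prop, umis)
        assert flags.empty

    def test_expression_threshold_exclusive_at_5(self):
        donors = [f"d{i}" for i in range(8)]
        base = np.array([0.90, 0.905, 0.91, 0.915, 0.92, 0.925, 0.93, 0.60])
        expr = self._report(base, donors)
        assert abs(expr.modified_z.iloc[-1]) > 5
        flags = flag_outlier_donors(expr, None, None)
        assert list(flags["donor"]) == ["d7"]
        assert list(flags["criterion"]) == ["expression_conformity"]

    def test_proportion_threshold_is_15_not_5(self):
        donors = [f"d{i}" for i in range(6)]
        scores = pd.Series([0.9, 0.91, 0.92, 0.93, 0.94, 0.5], index=donors)
        report = self._report(scores, donors)
        m = report.modified_z.abs().iloc[-1]
        assert 5 < m < 19
        # as a proportion report: excluded only if above 15
        flags = flag_outlier_donors(None, report, None)
        expected = ["d5"] if m > 15 else []
        assert list(flags["donor"]) == expected
        # same values as an expression report: always excluded
        flags2 = flag_outlier_donors(report, None, None)
        assert list(flags2["donor"]) == ["d5"]

    def test_low_umi_rule(self):
        umis = pd.DataFrame(
            {"t1": [5000.0, 900.0], "t2": [5000.0, 5000.0]},
            index=["ok", "low"],
        )
        flags = flag_outlier_donors(None, None, umis)
        assert list(flags["donor"]) == ["low"]
        assert flags["criterion"].iloc[0] == "low_umis"


class TestPlantedOutlierRecovery:
    def test_planted_outliers_recovered_over_seeds(self):
        # 2 aberrant donors among 40; exact recovery, no false positives
        from villagefactor.simulate import (OutlierSpec, VillageConfig,
                                            simulate_village)

        hits = 0
        for seed in range(10):
            cfg = VillageConfig(outliers=OutlierSpec(n_outliers=2))
            sim = simulate_village(cfg, seed=100 + seed)
            counts = pd.DataFrame(
                sim.counts.toarray(), index=sim.gene_ids,
                columns=sim.nuclei["barcode"],
            )
            pbs = aggregate_pseudobulk(
                counts, sim.cell_to_donor, sim.cell_to_type, mode="raw_sum"
            )
            umis = pd.DataFrame(
                {pb.cell_type: pb.donor_umis for pb in pbs}
            ).fillna(0.0)
            expr = conformity_scores(pbs)
            props = sim.nuclei.groupby(["cell_type", "donor"]).size().unstack(
                fill_value=0
            )
            prop = proportion_conformity_scores(props / props.sum(axis=0))
            flags = flag_outlier_donors(expr, prop, umis)
            flagged = set(flags["donor"])
            assert flagged <= set(sim.outlier_truth), "false positive"
            hits += len(flagged & set(sim.outlier_truth))
        assert hits / 20 >= 0.95  # seed-averaged sensitivity
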