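"""Cluster×sample counting and the negative-binomial abundance tests."""

import numpy as np
import pandas as pd
import pytest

from cellpam import (
    AbundanceTable,
    SampleMetadata,
    cluster_sample_counts,
    nb_glm_lrt,
    nb_glm_ql,
    phase_contrasts,
    simulate_abundance,
    simulate_nb_table,
)
from cellpam.abundance import NBAbundanceGLM, _design_matrices, nb_test_designs


def meta_two_groups(n_per=4):
    days = list(range(15, 15 + n_per)) + list(range(21, 21 + n_per))
    phases = [4] * n_per + [5] * n_per
    return SampleMetadata(pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(2 * n_per)],
        "day": days,
        "phase": phases,
    }))


class TestSampleMetadata:
    def test_time2_derived_from_day(self):
        meta = meta_two_groups(3)
        np.testing.assert_array_equal(meta.frame["time2"], [0, 0, 0, 1, 1, 1])

    def test_inconsistent_time2_rejected(self):
        with pytest.raises(ValueError, match="time2"):
            SampleMetadata(pd.DataFrame({
                "sample_id": ["a", "b"], "day": [10, 25], "time2": [1, 1],
            }))

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleMetadata(pd.DataFrame({"sample_id": ["a", "a"], "day": [1, 2]}))


class TestClusterSampleCounts:
    def test_direct_tally(self):
        meta = SampleMetadata(pd.DataFrame({"sample_id": ["A", "B"], "day": [15, 25]}))
        t = cluster_sample_counts([0, 0, 1, 1], ["A", "A", "A", "B"], meta)
        np.testing.assert_array_equal(t.counts.to_numpy(), [[2, 0], [1, 1]])
        assert t.sample_ids == ["A", "B"]

    def test_empty_labels_rejected(self):
        meta = SampleMetadata(pd.DataFrame({"sample_id": ["A"], "day": [15]}))
        with pytest.raises(ValueError, match="no labelled cells"):
            cluster_sample_counts([], [], meta)

    def test_unknown_sample_rejected(self):
        meta = SampleMetadata(pd.DataFrame({"sample_id": ["A"], "day": [15]}))
        with pytest.raises(ValueError, match="unknown sample"):
            cluster_sample_counts([0], ["Z"], meta)

    def test_column_sums_equal_per_sample_tallies(self, rng):
        meta = meta_two_groups(4)
        samples = rng.choice(meta.sample_ids, size=200)
        labels = rng.integers(0, 6, size=200)
        t = cluster_sample_counts(labels, samples, meta)
        for s in meta.sample_ids:
            assert t.counts[s].sum() == (samples == s).sum()
        assert t.counts.to_numpy().sum() == 200

    def test_cluster_permutation_equivariance(self, rng):
        meta = meta_two_groups(2)
        samples = rng.choice(meta.sample_ids, size=60)
        labels = rng.integers(0, 4, size=60)
        t1 = cluster_sample_counts(labels, samples, meta)
        t2 = cluster_sample_counts(3 - labels, samples, meta)
        np.testing.assert_array_equal(
            t1.counts.to_numpy(), t2.counts.to_numpy()[::-1]
        )


class TestNBTests:
    def test_identity_nested_design_gives_p_one(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=3,
                               cells_per_sample=300, seed=0)
        Xf, _, _, cols = _design_matrices(t, "time2")
        res = nb_test_designs(t, Xf, Xf, cols, kind="lrt")
        assert (res.table["stat"] == 0.0).all()
        assert (res.table["pvalue"] == 1.0).all()

    def test_ql_identity_nested_design(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=3,
                               cells_per_sample=300, seed=0)
        Xf, _, _, cols = _design_matrices(t, "time2")
        res = nb_test_designs(t, Xf, Xf, cols, kind="ql")
        assert (res.table["pvalue"] == 1.0).all()

    def test_ql_residual_df_error(self):
        meta = SampleMetadata(pd.DataFrame({"sample_id": ["A", "B"],
                                            "day": [15, 25]}))
        t = AbundanceTable(
            pd.DataFrame([[50, 60]], index=["c0"], columns=["A", "B"]), meta
        )
        with pytest.raises(ValueError, match="residual df"):
            nb_glm_ql(t, "time2")

    def test_shifted_cluster_detected_and_top_ranked(self):
        eff = np.zeros(8)
        eff[2] = np.log(3)
        t = simulate_abundance(n_clusters=8, condition_effect=eff, seed=42)
        res = nb_glm_lrt(t, "time2")
        assert res.table["qvalue"].idxmin() == "c2"
        assert res.table.loc["c2", "qvalue"] < 0.05
        assert res.table.loc["c2", "estimate"] > 0  # more abundant after day 20

    def test_ql_not_more_liberal_than_lrt(self):
        eff = np.zeros(8)
        eff[[1, 5]] = [np.log(2), -np.log(2)]
        n_lrt = n_ql = 0
        for seed in range(5):
            t = simulate_abundance(n_clusters=8, condition_effect=eff, seed=seed)
            n_lrt += len(nb_glm_lrt(t, "time2").significant())
            n_ql += len(nb_glm_ql(t, "time2").significant())
        assert n_ql <= n_lrt

    def test_offset_scale_invariance_of_lrt(self):
        t = simulate_abundance(n_clusters=5, n_samples_per_condition=4,
                               cells_per_sample=500, seed=9)
        Xf, Xr, _, cols = _design_matrices(t, "time2")
        base = np.log(t.sample_totals())
        r1 = nb_test_designs(t, Xf, Xr, cols, offset=base)
        r2 = nb_test_designs(t, Xf, Xr, cols, offset=base + np.log(7.0))
        np.testing.assert_allclose(
            r1.table["stat"], r2.table["stat"], rtol=1e-5, atol=1e-7
        )

    def test_qvalues_are_monotone_bh_transform(self):
        t = simulate_abundance(n_clusters=10, seed=5)
        res = nb_glm_lrt(t, "time2")
        p = res.table["pvalue"].to_numpy()
        q = res.table["qvalue"].to_numpy()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()

    def test_all_zero_cluster_flagged_p_one(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=3,
                               cells_per_sample=200, seed=1)
        frame = t.counts.copy()
        frame.loc["dead"] = 0
        t2 = AbundanceTable(frame, t.metadata)
        res = nb_glm_lrt(t2, "time2")
        assert res.table.loc["dead", "flagged"]
        assert res.table.loc["dead", "pvalue"] == 1.0

    def test_time_design_uses_day_as_numeric(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=4, seed=3)
        res = nb_glm_lrt(t, "time")
        assert res.design_name == "time"
        assert res.table["pvalue"].between(0, 1).all()

    def test_estimator_api(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=3, seed=2)
        est = NBAbundanceGLM(design="time2", test="lrt").fit(t)
        assert est.results_.table.shape[0] == 4
        assert est.get_params()["design"] == "time2"


class TestPhaseDesigns:
    def test_three_levels_give_three_pairwise_results(self):
        t = simulate_abundance(n_clusters=4, n_samples_per_condition=6, seed=11)
        phases = t.metadata.frame["phase"].unique()
        assert len(phases) >= 2
        if len(phases) == 3:
            results = phase_contrasts(t)
            assert len(results) == 3
            names = {r.design_name for r in results}
            assert len(names) == 3

    def test_two_level_pairwise_equals_joint(self):
        # with exactly 2 phase levels the 1-df contrast IS the joint test
        meta = meta_two_groups(4)
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(100, size=(5, 8)),
            index=[f"c{i}" for i in range(5)],
            columns=meta.sample_ids,
        )
        t = AbundanceTable(counts, meta)
        joint = nb_glm_lrt(t, "phase")
        pair = nb_glm_lrt(t, "phase", contrast=(4, 5))
        np.testing.assert_allclose(
            joint.table["pvalue"], pair.table["pvalue"], rtol=1e-6
        )

    def test_shift_between_levels_four_five_found_by_that_contrast(self):
        rng = np.random.default_rng(21)
        n_per = 5
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(3 * n_per)],
            "day": [13] * n_per + [18] * n_per + [24] * n_per,
            "phase": [3] * n_per + [4] * n_per + [5] * n_per,
        }))
        rows = {}
        # cluster c0: the 4 -> 5 jump (3x) dwarfs the 3 -> 4 and 3 -> 5 gaps
        rows["c0"] = np.concatenate([
            rng.poisson(350, n_per), rng.poisson(200, n_per), rng.poisson(600, n_per)
        ])
        for c in range(1, 5):
            rows[f"c{c}"] = rng.poisson(300, 3 * n_per)
        t = AbundanceTable(pd.DataFrame(rows, index=meta.sample_ids).T, meta)
        results = phase_contrasts(t)
        by_name = {r.design_name: r for r in results}
        p45 = by_name["phase_pairwise(4,5)"].table.loc["c0", "pvalue"]
        assert p45 == min(
            r.table.loc["c0", "pvalue"] for r in results
        )
        assert p45 < 0.05


class TestParameterRecovery:
    def test_beta_recovery_bias_and_rmse_shrinks(self):
        beta_true = 0.8
        errs = {6: [], 24: []}
        for n_per in (6, 24):
            for seed in range(8):
                beta = np.zeros(6)
                beta[3] = beta_true
                t, off = simulate_nb_table(
                    beta, n_samples_per_condition=n_per, seed=100 + seed
                )
                Xf, Xr, _, cols = _design_matrices(t, "time2")
                res = nb_test_designs(t, Xf, Xr, cols, offset=off)
                errs[n_per].append(res.table["estimate"].iloc[3] - beta_true)
        bias = np.mean(errs[24])
        assert abs(bias) < 0.05
        rmse_small = np.sqrt(np.mean(np.square(errs[6])))
        rmse_large = np.sqrt(np.mean(np.square(errs[24])))
        assert rmse_large < rmse_small
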