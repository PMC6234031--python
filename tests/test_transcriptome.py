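"""Count normalization, baseline interpolation, gene filtering, clustering, groups."""

import itertools

import numpy as np
import pandas as pd
import pytest

from smaddyn import synth, transcriptome
from smaddyn.transcriptome import FilterParams


class TestNormalizeCounts:
    def test_identical_samples_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, dtype=float)
        norm, factors = transcriptome.normalize_counts(df)
        assert np.allclose(factors, 1.0)
        pd.testing.assert_frame_equal(norm, df)

    def test_doubled_sample_factor_two(self):
        a = np.array([10.0, 50.0, 100.0])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        norm, factors = transcriptome.normalize_counts(df)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        assert np.allclose(norm["a"], norm["b"])

    def test_single_gene_falls_back_to_totals(self):
        df = pd.DataFrame({"a": [100.0], "b": [400.0]})
        with pytest.warns(UserWarning, match="total counts"):
            norm, factors = transcriptome.normalize_counts(df)
        assert factors["b"] / factors["a"] == pytest.approx(4.0)

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError):
            transcriptome.normalize_counts(df)


class TestInterpolateBaseline:
    control = pd.DataFrame({"c0": [100.0], "c6": [200.0], "c12": [150.0]},
                           index=["g1"])

    def test_knot_identity(self):
        out = transcriptome.interpolate_baseline(self.control, [0, 6, 12], [0, 6, 12])
        assert np.allclose(out.to_numpy(), [[100, 200, 150]])

    def test_linear_midpoint(self):
        out = transcriptome.interpolate_baseline(self.control, [0, 6, 12], [3.0])
        assert out.iloc[0, 0] == 150.0

    def test_hand_interpolation_at_9hr(self):
        out = transcriptome.interpolate_baseline(self.control, [0, 6, 12], [9.0])
        assert out.iloc[0, 0] == 175.0

    def test_no_extrapolation(self):
        with pytest.raises(ValueError):
            transcriptome.interpolate_baseline(self.control, [0, 6, 12], [13.0])


class TestSubtractBaseline:
    def test_examples(self):
        t = pd.DataFrame({"x": [5.0], "y": [7.0]}, index=["g"])
        b = pd.DataFrame({"x": [5.0], "y": [7.0]}, index=["g"])
        assert (transcriptome.subtract_baseline(t, b) == 0).all().all()
        assert (transcriptome.subtract_baseline(t + 50, b) == 50).all().all()

    def test_alignment_enforced(self):
        t = pd.DataFrame({"x": [1.0]}, index=["g1"])
        b = pd.DataFrame({"x": [1.0]}, index=["g2"])
        with pytest.raises(ValueError):
            transcriptome.subtract_baseline(t, b)

    def test_down_genes_go_negative(self):
        p = synth.CountSimParams(
            n_genes={"transient_up": 0, "stable_up": 0, "down": 100, "null": 0},
            dispersion=0.005, seed=1,
        )
        cm = synth.generate_count_timecourse(p)
        res = transcriptome.run_timecourse_analysis(cm)
        adjusted = res["adjusted"]
        frac_negative = (adjusted.min(axis=1) < 0).mean()
        assert frac_negative >= 0.95


def brute_force_filter(treated, adjusted, t0, params):
    kept = []
    for g in treated.index:
        fc_hit = False
        for col in treated.columns:
            R = (adjusted.loc[g, col] + t0[g] + params.pseudocount) / (
                t0[g] + params.pseudocount)
            R = max(R, 1e-12)
            if max(R, 1 / R) > params.fc_threshold:
                fc_hit = True
        if fc_hit and treated.loc[g].max() > params.min_count:
            kept.append(g)
    return kept


class TestFilterGenes:
    params = FilterParams()

    def _one_gene(self, t0, profile):
        treated = pd.DataFrame([profile], index=["g"],
                               columns=[f"t{i}" for i in range(len(profile))],
                               dtype=float)
        baseline = pd.DataFrame([[t0] * len(profile)], index=["g"],
                                columns=treated.columns, dtype=float)
        adjusted = treated - baseline
        return treated, adjusted, pd.Series({"g": float(t0)})

    def test_kept_gene_passing_both_rules(self):
        treated, adjusted, t0 = self._one_gene(100, [100, 250, 180, 120, 110])
        assert list(transcriptome.filter_genes(treated, adjusted, t0, self.params)) == ["g"]

    def test_dropped_below_fold_change(self):
        treated, adjusted, t0 = self._one_gene(100, [100, 150, 140, 130, 120])
        assert len(transcriptome.filter_genes(treated, adjusted, t0, self.params)) == 0

    def test_dropped_below_count_floor(self):
        treated, adjusted, t0 = self._one_gene(10, [10, 30, 25, 20, 15])
        assert len(transcriptome.filter_genes(treated, adjusted, t0, self.params)) == 0

    def test_matches_brute_force_on_random_genes(self):
        rng = np.random.default_rng(21)
        n = 1000
        treated = pd.DataFrame(
            rng.uniform(0, 400, size=(n, 5)),
            index=[f"g{i}" for i in range(n)],
            columns=[f"t{j}" for j in range(5)],
        )
        baseline = pd.DataFrame(
            rng.uniform(1, 300, size=(n, 5)), index=treated.index,
            columns=treated.columns,
        )
        adjusted = treated - baseline
        t0 = pd.Series(rng.uniform(0, 300, n), index=treated.index)
        fast = list(transcriptome.filter_genes(treated, adjusted, t0, self.params))
        slow = brute_force_filter(treated, adjusted, t0, self.params)
        assert fast == slow


class TestZscore:
    def test_unit_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"])
        z = transcriptome.zscore_profiles(df)
        assert np.allclose(z.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_rows_standardized(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(10, 3, size=(20, 5)))
        z = transcriptome.zscore_profiles(df)
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_row_excluded_with_warning(self):
        df = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.warns(UserWarning):
            z = transcriptome.zscore_profiles(df)
        assert list(z.index) == ["ok"]


def brute_force_upgma(X):
    """O(n^3) average-linkage on centered-correlation distance.

    Returns the cophenetic distance matrix (condensed, scipy ordering).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    D = 1.0 - (Xc @ Xc.T) / np.outer(norm, norm)
    np.fill_diagonal(D, np.inf)
    clusters = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: kv[1])
        members_i, members_j = clusters.pop(i), clusters.pop(j)
        for a in members_i:
            for b in members_j:
                coph[a, b] = coph[b, a] = dij
        merged = members_i + members_j
        new_dists = {}
        for k, members_k in clusters.items():
            key_i = (min(i, k), max(i, k))
            key_j = (min(j, k), max(j, k))
            dik, djk = dist[key_i], dist[key_j]
            new_dists[k] = (len(members_i) * dik + len(members_j) * djk) / len(merged)
        dist = {(a, b): v for (a, b), v in dist.items()
                if i not in (a, b) and j not in (a, b)}
        for k, v in new_dists.items():
            dist[(min(k, next_id), max(k, next_id))] = v
        clusters[next_id] = merged
        next_id += 1
    from scipy.spatial.distance import squareform

    return squareform(coph, checks=False)


class TestHCluster:
    def test_identical_rows_merge_at_zero(self):
        z = pd.DataFrame([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["a", "b"])
        Z = transcriptome.hcluster(z)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        z = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        Z = transcriptome.hcluster(z)
        assert Z[0, 2] == pytest.approx(2.0)

    def test_matches_cubic_oracle_on_random_instances(self):
        from scipy.cluster.hierarchy import cophenet

        rng = np.random.default_rng(31)
        for _ in range(50):
            X = rng.normal(size=(6, 4))
            Z = transcriptome.hcluster(pd.DataFrame(X))
            assert np.allclose(cophenet(Z), brute_force_upgma(X), atol=1e-10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            transcriptome.hcluster(pd.DataFrame([[1.0, 2.0]]))


class TestAssignGroups:
    def test_planted_classes_recovered(self):
        cm = synth.generate_count_timecourse(synth.CountSimParams(seed=11))
        res = transcriptome.run_timecourse_analysis(cm)
        groups = res["groups"]
        cls = cm.gene_classes
        planted = [g for g in groups.index if cls[g] != "null"]
        acc = np.mean([groups.loc[g, "group"] == cls[g] for g in planted])
        assert acc >= 0.95

    def test_single_class_input_single_label(self):
        p = synth.CountSimParams(
            n_genes={"transient_up": 40, "stable_up": 0, "down": 0, "null": 0},
            dispersion=0.01, seed=2,
        )
        cm = synth.generate_count_timecourse(p)
        res = transcriptome.run_timecourse_analysis(cm, n_clusters=4)
        assert set(res["groups"]["group"]) == {"transient_up"}

    def test_noise_genes_unassigned_far_more_often_than_planted(self):
        """Filter-surviving null genes lack a coherent class shape."""
        p = synth.CountSimParams(n_genes={"null": 3000}, seed=0)
        cm = synth.generate_count_timecourse(p)
        res = transcriptome.run_timecourse_analysis(cm)
        null_unassigned = (res["groups"]["group"] == "unassigned").mean()
        cm2 = synth.generate_count_timecourse(synth.CountSimParams(seed=11))
        res2 = transcriptome.run_timecourse_analysis(cm2)
        cls2 = cm2.gene_classes
        planted = [g for g in res2["groups"].index if cls2[g] != "null"]
        planted_unassigned = (res2["groups"].loc[planted, "group"] == "unassigned").mean()
        assert null_unassigned >= 0.05
        assert null_unassigned > 10 * max(planted_unassigned, 1e-9) or planted_unassigned == 0

    def test_more_clusters_than_genes_rejected(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)))
        Z = transcriptome.hcluster(z)
        with pytest.raises(ValueError):
            transcriptome.assign_groups(Z, z, [1, 2.5, 4, 8, 12], n_clusters=10)


class TestPipelineRecovery:
    def test_filter_sensitivity_and_null_passthrough(self):
        cm = synth.generate_count_timecourse(synth.CountSimParams(seed=17))
        res = transcriptome.run_timecourse_analysis(cm)
        kept = set(res["filtered_genes"])
        cls = cm.gene_classes
        nonnull = set(cls[cls != "null"].index)
        null = set(cls[cls == "null"].index)
        assert len(kept & nonnull) / len(nonnull) >= 0.90
        assert len(kept & null) / len(null) < 0.05

    def test_transient_group_mean_profile_peaks_at_2p5(self):
        cm = synth.generate_count_timecourse(synth.CountSimParams(seed=17))
        res = transcriptome.run_timecourse_analysis(cm)
        groups = res["groups"]
        z = res["z_profiles"]
        tg = groups.index[groups["group"] == "transient_up"]
        prof = z.loc[tg].mean(axis=0).to_numpy()
        assert res["treated_times"][np.argmax(prof)] == 2.5


class TestGenesetEnrichment:
    def _groups(self, labels):
        return pd.DataFrame(
            {"cluster": 1, "group": labels},
            index=[f"g{i}" for i in range(len(labels))],
        )

    def test_exact_tail_probability(self):
        # universe 20, group 5, set 5, overlap 4
        from math import comb

        groups = self._groups(["stable_up"] * 5 + ["down"] * 15)
        gene_set = [f"g{i}" for i in range(4)] + ["g10"]
        out = transcriptome.geneset_enrichment(groups, {"s": gene_set})
        row = out[(out.group == "stable_up")].iloc[0]
        p_brute = sum(
            comb(5, k) * comb(15, 5 - k) for k in range(4, 6)
        ) / comb(20, 5)
        assert row.p_value == pytest.approx(p_brute, rel=1e-12)
        assert row.overlap == 4

    def test_disjoint_set_near_one(self):
        groups = self._groups(["stable_up"] * 5 + ["down"] * 15)
        gene_set = [f"g{i}" for i in range(10, 16)]
        out = transcriptome.geneset_enrichment(groups, {"s": gene_set})
        row = out[(out.group == "stable_up")].iloc[0]
        assert row.overlap == 0
        assert row.p_value > 0.5

    def test_empty_intersection_skipped_and_bh_applied(self):
        groups = self._groups(["stable_up"] * 10)
        out = transcriptome.geneset_enrichment(
            groups, {"absent": ["nope1", "nope2"], "all": [f"g{i}" for i in range(10)]}
        )
        assert set(out.gene_set) == {"all"}
        assert "q_value" in out


class TestRtpcr:
    def _table(self):
        return pd.DataFrame(
            {"t0": [10.0, 100.0], "t1": [40.0, 200.0]}, index=["GOI", "GAPDH"]
        )

    def test_t0_sample_is_one(self):
        out = transcriptome.rtpcr_relative(self._table(), t0_sample="t0")
        assert np.allclose(out["t0"], 1.0)
        assert out.loc["GOI", "t1"] == pytest.approx((40 / 200) / (10 / 100))

    def test_ratio_invariance_under_common_scaling(self):
        t = self._table()
        out1 = transcriptome.rtpcr_relative(t, t0_sample="t0")
        out2 = transcriptome.rtpcr_relative(t * 2, t0_sample="t0")
        pd.testing.assert_frame_equal(out1, out2)

    def test_ct_input_ddct(self):
        t = pd.DataFrame({"t0": [20.0, 15.0], "t1": [18.0, 15.0]},
                         index=["GOI", "GAPDH"])
        out = transcriptome.rtpcr_relative(t, t0_sample="t0", input_kind="ct")
        assert out.loc["GOI", "t1"] == pytest.approx(4.0)

    def test_missing_reference_rejected(self):
        t = self._table().drop(index="GAPDH")
        with pytest.raises(ValueError):
            transcriptome.rtpcr_relative(t, t0_sample="t0")
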