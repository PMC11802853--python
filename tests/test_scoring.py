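import numpy as np
import pandas as pd
import pytest

from immunoclone import scoring


def hand_module_score(matrix, gene_set):
    """Oracle for the 6-gene / n_bins=2 / n_ctrl=2 configuration: bins of 3
    genes by mean expression, one set gene per bin, so the 2 eligible
    controls per set gene are forced and the recipe is deterministic."""
    means = matrix.mean(axis=0).sort_values(kind="stable")
    bins = [list(means.index[:3]), list(means.index[3:])]
    controls = []
    for gene in gene_set:
        for b in bins:
            if gene in b:
                controls.extend(g for g in sorted(b) if g not in gene_set)
    return matrix[list(gene_set)].mean(axis=1) - matrix[controls].mean(axis=1)


@pytest.fixture()
def toy_matrix():
    # 4 cells x 6 genes with distinct dataset means
    return pd.DataFrame(
        {
            "g1": [0.0, 0.1, 0.0, 0.1],
            "g2": [0.5, 0.2, 0.1, 0.2],
            "g3": [1.0, 0.8, 0.9, 1.1],
            "g4": [2.0, 2.2, 1.8, 2.0],
            "g5": [3.0, 2.5, 3.5, 3.0],
            "g6": [5.0, 4.0, 6.0, 5.0],
        },
        index=[f"c{i}" for i in range(4)],
    )


class TestModuleScore:
    def test_identical_expression_scores_zero(self):
        matrix = pd.DataFrame(1.7, index=[f"c{i}" for i in range(5)],
                              columns=[f"g{i}" for i in range(30)])
        table = scoring.module_score(matrix, ["g0", "g7"], n_bins=3, n_ctrl=5,
                                     seed=0)
        assert np.allclose(table.scores, 0.0)

    def test_upshifted_subset_scores_higher(self, toy_matrix):
        matrix = toy_matrix.copy()
        matrix.loc[["c0", "c1"], ["g2", "g5"]] += 2.0
        table = scoring.module_score(matrix, ["g2", "g5"], n_bins=2, n_ctrl=2,
                                     seed=0)
        assert table.scores[["c0", "c1"]].mean() > table.scores[["c2", "c3"]].mean()

    def test_hand_computed_oracle(self, toy_matrix):
        table = scoring.module_score(toy_matrix, ["g2", "g5"], n_bins=2,
                                     n_ctrl=2, seed=123)
        expected = hand_module_score(toy_matrix, ["g2", "g5"])
        assert np.allclose(table.scores, expected, atol=1e-9)

    def test_empty_intersection_error(self, toy_matrix):
        with pytest.raises(ValueError, match="nope"):
            scoring.module_score(toy_matrix, ["nope"], n_bins=2, n_ctrl=2)

    def test_permuted_set_mean_near_zero(self):
        rng = np.random.default_rng(7)
        matrix = pd.DataFrame(
            rng.gamma(2.0, 1.0, size=(60, 120)),
            index=[f"c{i}" for i in range(60)],
            columns=[f"g{i}" for i in range(120)],
        )
        means = []
        for seed in range(20):
            gene_rng = np.random.default_rng(1000 + seed)
            gene_set = list(gene_rng.choice(matrix.columns, size=8, replace=False))
            table = scoring.module_score(matrix, gene_set, n_bins=6, n_ctrl=10,
                                         seed=seed)
            means.append(table.scores.mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-12


class TestFitScoreThreshold:
    def test_symmetric_separable_midpoint(self):
        assert scoring.fit_score_threshold([1.0] * 10, [-1.0] * 10) == 0.0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(1, 1, 200)
        neg = rng.normal(-1, 1, 200)
        t0 = scoring.fit_score_threshold(pos, neg)
        t_shift = scoring.fit_score_threshold(pos + 5.0, neg + 5.0)
        assert t_shift == pytest.approx(t0 + 5.0, abs=1e-6)

    def test_symmetric_gaussians_near_zero(self):
        rng = np.random.default_rng(42)
        pos = rng.normal(1, 1, 500)
        neg = rng.normal(-1, 1, 500)
        # 3 SE of the logistic 50% point at this n/separation (~0.05 SE)
        assert abs(scoring.fit_score_threshold(pos, neg)) < 0.15

    def test_identical_distributions_warn_median(self):
        scores = [0.0, 1.0, 2.0]
        with pytest.warns(RuntimeWarning, match="identical"):
            assert scoring.fit_score_threshold(scores, scores) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            scoring.fit_score_threshold([], [1.0])


class TestClassifyPapc:
    def _table(self, scores):
        return scoring.ScoreTable(pd.Series(scores), "papc", 24, 100, 0)

    def test_all_below_threshold(self):
        meta = pd.DataFrame({"cell_id": ["a", "b"], "subset": ["DC", "B"],
                             "patient": ["P1", "P1"]})
        flags, composition = scoring.classify_papc(
            self._table({"a": -1.0, "b": -2.0}), 0.0, meta)
        assert not flags.any()
        assert composition.empty

    def test_composition_sums_to_one(self):
        meta = pd.DataFrame({
            "cell_id": list("abcde"),
            "subset": ["DC", "DC", "B", "MoMac", "T"],
            "patient": ["P1"] * 5,
        })
        scores = {"a": 1.0, "b": 1.0, "c": 0.5, "d": 0.7, "e": -1.0}
        _, composition = scoring.classify_papc(self._table(scores), 0.0, meta)
        assert composition["fraction"].sum() == pytest.approx(1.0)
        assert "T" not in set(composition["subset"])

    def test_exclusive_signature_forces_composition(self):
        meta = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(6)],
            "subset": ["X"] * 3 + ["Y"] * 3,
            "patient": ["P1"] * 6,
        })
        scores = {f"c{i}": (1.0 if i < 3 else -1.0) for i in range(6)}
        _, composition = scoring.classify_papc(self._table(scores), 0.0, meta)
        assert composition["subset"].tolist() == ["X"]
        assert composition["fraction"].tolist() == [1.0]


class TestGateCells:
    def _rules(self):
        return [
            scoring.GateRule("plasma cell", 1, (
                scoring.GatePredicate("percBCR_high", ">", 0.4),
                scoring.GatePredicate("PC_score", ">", 0.04),
            )),
            scoring.GateRule("plasmablast", 2, (
                scoring.GatePredicate("percBCR_high", ">", 0.15),
            )),
        ]

    def test_plasma_cell_rule(self):
        features = pd.DataFrame({"percBCR_high": [0.5], "PC_score": [0.05]},
                                index=["cl1"])
        labels = scoring.gate_cells(features, self._rules())
        assert labels["cl1"] == "plasma cell"

    def test_fallback(self):
        features = pd.DataFrame({"percBCR_high": [0.01], "PC_score": [0.0]},
                                index=["cl1"])
        labels = scoring.gate_cells(features, self._rules(), fallback="B cell")
        assert labels["cl1"] == "B cell"

    def test_priority_wins_regardless_of_rule_order(self):
        features = pd.DataFrame({"percBCR_high": [0.5], "PC_score": [0.05]},
                                index=["cl1"])
        rules = self._rules()
        assert scoring.gate_cells(features, rules[::-1])["cl1"] == "plasma cell"

    def test_duplicate_priorities_rejected(self):
        rules = self._rules()
        clash = [rules[0], scoring.GateRule("other", 1, rules[1].predicates)]
        with pytest.raises(ValueError, match="unique"):
            scoring.gate_cells(pd.DataFrame({"percBCR_high": [0.5],
                                             "PC_score": [0.1]}), clash)

    def test_unknown_feature_rejected(self):
        rules = [scoring.GateRule("x", 1,
                                  (scoring.GatePredicate("missing", ">", 0.0),))]
        with pytest.raises(KeyError, match="missing"):
            scoring.gate_cells(pd.DataFrame({"percBCR_high": [0.5]}), rules)

    def test_idempotent_pure_function(self):
        features = pd.DataFrame({"percBCR_high": [0.5, 0.2, 0.01],
                                 "PC_score": [0.05, 0.0, 0.0]},
                                index=["a", "b", "c"])
        l1 = scoring.gate_cells(features, self._rules())
        l2 = scoring.gate_cells(features, self._rules())
        pd.testing.assert_series_equal(l1, l2)

    def test_aggregate_features_cluster_level(self):
        cell_features = pd.DataFrame({
            "bcr_numis": [100, 1, 1, 2],
            "CD27": [0.0, 0.2, 0.4, 0.0],
        }, index=list("abcd"))
        clusters = pd.Series(["cl1", "cl1", "cl2", "cl2"], index=list("abcd"))
        agg = scoring.aggregate_features(
            cell_features, clusters,
            {"percBCR_high": ("fraction_gt", "bcr_numis", 50),
             "mean_CD27": ("mean", "CD27")})
        assert agg.loc["cl1", "percBCR_high"] == 0.5
        assert agg.loc["cl2", "percBCR_high"] == 0.0
        assert agg.loc["cl2", "mean_CD27"] == pytest.approx(0.2)

    def test_default_rulebook_loads(self):
        from importlib import resources
        path = resources.files("immunoclone.data") / "gate_rules.yaml"
        rules = scoring.load_gate_rules(str(path))
        assert any(r.label == "plasma cell" for r in rules)
        features = pd.DataFrame({
            "percBCR_high": [0.5], "PC_score": [0.05], "pct_unmutated": [0.0],
            "pct_IGHDM": [0.0], "mean_CD27": [0.0]}, index=["cl"])
        assert scoring.gate_cells(features, rules)["cl"] == "plasma cell"


def naive_complete_linkage_heights(dist):
    """Independent O(n^3) agglomerative complete-linkage oracle."""
    clusters = [{i} for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return sorted(heights)


class TestGeneModules:
    def test_two_perfect_blocks_recovered(self, rng):
        base1 = rng.poisson(5, size=40)
        base2 = rng.poisson(5, size=40)
        counts = pd.DataFrame({
            "a1": base1, "a2": base1 * 2, "a3": base1 * 3,
            "b1": base2, "b2": base2 * 2, "b3": base2 * 4,
        }, index=[f"c{i}" for i in range(40)])
        modules, _, _ = scoring.gene_modules({"s1": counts}, n_modules=2,
                                             umi_target=10**6, seed=0)
        assert modules["a1"] == modules["a2"] == modules["a3"]
        assert modules["b1"] == modules["b2"] == modules["b3"]
        assert modules["a1"] != modules["b1"]

    def test_identical_samples_fisher_z_identity(self, rng):
        counts = pd.DataFrame(rng.poisson(4, size=(30, 8)),
                              index=[f"c{i}" for i in range(30)],
                              columns=[f"g{i}" for i in range(8)])
        _, _, corr_one = scoring.gene_modules({"s1": counts}, n_modules=2,
                                              umi_target=10**6, seed=0)
        _, _, corr_three = scoring.gene_modules(
            {"s1": counts, "s2": counts.copy(), "s3": counts.copy()},
            n_modules=2, umi_target=10**6, seed=0)
        assert np.allclose(corr_one.to_numpy(), corr_three.to_numpy(), atol=1e-9)

    def test_merge_heights_match_oracle(self, rng):
        counts = pd.DataFrame(rng.poisson(6, size=(50, 20)),
                              index=[f"c{i}" for i in range(50)],
                              columns=[f"g{i:02d}" for i in range(20)])
        _, link, corr = scoring.gene_modules({"s1": counts}, n_modules=3,
                                             umi_target=10**6, seed=0)
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        expected = naive_complete_linkage_heights(dist)
        assert np.allclose(sorted(link[:, 2]), expected, atol=1e-9)

    def test_low_umi_genes_excluded(self, rng):
        counts = pd.DataFrame({
            "ok1": rng.poisson(5, 30), "ok2": rng.poisson(5, 30),
            "rare": np.zeros(30, dtype=int),
        }, index=[f"c{i}" for i in range(30)])
        counts.loc["c0", "rare"] = 2  # below the 5-UMI floor
        modules, _, _ = scoring.gene_modules({"s1": counts}, n_modules=2,
                                             umi_target=10**6, seed=0)
        assert "rare" not in modules.index

    def test_too_few_genes_error(self):
        counts = pd.DataFrame({"only": [10, 10]}, index=["c0", "c1"])
        with pytest.raises(ValueError):
            scoring.gene_modules({"s1": counts}, n_modules=2, umi_target=10**6)

    def test_downsampling_caps_cell_totals(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(10, 20)))
        down = scoring.downsample_counts(counts, 100, rng)
        assert (down.sum(axis=1) <= 100).all()
        small = counts.iloc[[0]] // 100  # below target stays unchanged
        pd.testing.assert_frame_equal(
            scoring.downsample_counts(small, 100, rng), small)


def gaussian_classes(rng, n_per_class, n_dim=10, separation=6.0, k=4):
    X, y = [], []
    for cls in range(k):
        mean = np.zeros(n_dim)
        mean[cls] = separation
        X.append(rng.normal(mean, 1.0, size=(n_per_class, n_dim)))
        y.extend([f"class{cls}"] * n_per_class)
    return pd.DataFrame(np.vstack(X)), np.array(y)


class TestSvmLabelTransfer:
    def test_identical_query_full_recovery(self, rng):
        X, y = gaussian_classes(rng, 50)
        out = scoring.svm_label_transfer(X, y, X, cells_per_class=25, reps=5,
                                         seed=0)
        assert (out["label"].to_numpy() == y).all()
        assert (out["probability"] == 1.0).all()

    def test_separated_gaussians_recovery(self, rng):
        X_ref, y_ref = gaussian_classes(rng, 125)
        X_q, y_q = gaussian_classes(rng, 125)
        out = scoring.svm_label_transfer(X_ref, y_ref, X_q, cells_per_class=50,
                                         reps=25, seed=1)
        assert (out["label"].to_numpy() == y_q).mean() >= 0.95

    def test_permuted_reference_chance_level(self, rng):
        X_ref, y_ref = gaussian_classes(rng, 125)
        X_q, y_q = gaussian_classes(rng, 125)
        permuted = rng.permutation(y_ref)
        out = scoring.svm_label_transfer(X_ref, permuted, X_q,
                                         cells_per_class=50, reps=25, seed=2)
        acc = (out["label"].to_numpy() == y_q).mean()
        # chance = 1/4; cluster-level correlation inflates the SE beyond
        # the 0.02 binomial SE, so allow a generous band around chance
        assert acc < 0.5

    def test_vote_fractions_sum_to_one(self, rng):
        X, y = gaussian_classes(rng, 30)
        out = scoring.svm_label_transfer(X, y, X, cells_per_class=10, reps=4,
                                         seed=0)
        vote_cols = [c for c in out.columns if c.startswith("vote_")]
        assert np.allclose(out[vote_cols].sum(axis=1), 1.0)

    def test_rare_class_upsampled_not_dropped(self, rng):
        X, y = gaussian_classes(rng, 40)
        # shrink one class below cells_per_class
        keep = np.ones(len(y), bool)
        keep[np.where(y == "class3")[0][5:]] = False
        out = scoring.svm_label_transfer(X[keep], y[keep], X, cells_per_class=20,
                                         reps=5, seed=0)
        assert "class3" in set(out["label"])

    def test_dimension_mismatch(self, rng):
        X, y = gaussian_classes(rng, 10)
        with pytest.raises(ValueError, match="dimensionality"):
            scoring.svm_label_transfer(X, y, X.iloc[:, :5], cells_per_class=5,
                                       reps=2, seed=0)
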