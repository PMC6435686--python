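"""The rank-rule classifier: preprocessing, rule space, NB fit, training, prediction."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

import lungssp as L
from lungssp.ssp_core import _posteriors, select_rules

from conftest import random_expression


def _matrix(data, genes, samples, platform=L.Platform.nanostring_counts):
    return L.ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples), platform)


class TestBackgroundCorrect:
    def test_mean_plus_two_sd_rule(self):
        # negatives 8, 10, 12 -> background 10 + 2*2 = 14; endogenous 100 -> 86
        m = _matrix([[100.0], [8.0], [10.0], [12.0]], ["GENE", "N1", "N2", "N3"], ["s"])
        out = L.background_correct(m, ["N1", "N2", "N3"], floor=1.0)
        assert out.values.loc["GENE", "s"] == pytest.approx(86.0)
        assert "N1" not in out.values.index

    def test_floor_clamp(self):
        m = _matrix([[5.0], [8.0], [10.0], [12.0]], ["GENE", "N1", "N2", "N3"], ["s"])
        out = L.background_correct(m, ["N1", "N2", "N3"], floor=1.0)
        assert out.values.loc["GENE", "s"] == 1.0

    def test_zero_negatives_identity(self):
        m = _matrix([[100.0], [0.0], [0.0]], ["GENE", "N1", "N2"], ["s"])
        out = L.background_correct(m, ["N1", "N2"], floor=1.0)
        assert out.values.loc["GENE", "s"] == 100.0

    def test_no_negatives_is_error(self):
        m = _matrix([[100.0]], ["GENE"], ["s"])
        with pytest.raises(ValueError, match="negative-control"):
            L.background_correct(m, ["N1"])


class TestResolvePanel:
    def test_alias_passthrough(self):
        panel = L.default_marker_panel()
        genes = ["NKX2-1" if g == "TTF-1" else g for g in panel.genes]
        m = _matrix(np.arange(22, dtype=float).reshape(11, 2), genes, ["a", "b"])
        out = L.resolve_panel(m, panel)
        assert "TTF-1" in out.values.index
        assert list(out.values.index) == list(panel.genes)

    def test_missing_gene_named(self):
        panel = L.default_marker_panel()
        genes = [g for g in panel.genes if g != "SFTPG"]
        m = _matrix(np.ones((10, 2)), genes, ["a", "b"])
        with pytest.raises(ValueError, match="SFTPG"):
            L.resolve_panel(m, panel)

    def test_ambiguous_alias_collision(self):
        panel = L.default_marker_panel()
        genes = list(panel.genes) + ["NKX2-1"]
        m = _matrix(np.ones((12, 2)), genes, ["a", "b"])
        with pytest.raises(ValueError, match="ambiguous"):
            L.resolve_panel(m, panel)


class TestRuleSpace:
    def test_eleven_genes_give_110_rules(self):
        rules = L.enumerate_pair_rules(L.default_marker_panel())
        assert len(rules) == 110
        assert len(set(rules)) == 110
        assert L.PairRule("KRT5", "NAPSA") in rules and L.PairRule("NAPSA", "KRT5") in rules

    def test_two_genes_give_two_rules(self):
        panel = L.MarkerPanel(classes={"A": ("g1",), "B": ("g2",)})
        assert L.enumerate_pair_rules(panel) == [L.PairRule("g1", "g2"), L.PairRule("g2", "g1")]

    def test_binarize_definition_and_ties(self):
        m = _matrix([[5.0, 3.0], [7.0, 3.0]], ["a", "b"], ["s1", "s2"])
        rules = [L.PairRule("a", "b"), L.PairRule("b", "a")]
        binary = L.binarize_rules(m, rules)
        assert binary[:, 0].tolist() == [1, 0]  # 5 < 7
        assert binary[:, 1].tolist() == [0, 0]  # tie -> both orientations 0

    def test_binarize_monotone_invariance(self):
        rng = np.random.default_rng(42)
        panel = L.default_marker_panel()
        rules = L.enumerate_pair_rules(panel)
        for _ in range(25):
            m = random_expression(rng)
            base = L.binarize_rules(m, rules)
            transformed = m.values.copy()
            for s in transformed.columns:
                a, p, b = rng.uniform(0.5, 3.0), rng.uniform(0.3, 2.5), rng.uniform(0, 10)
                transformed[s] = a * transformed[s] ** p + b  # strictly increasing on x >= 0
            np.testing.assert_array_equal(
                L.binarize_rules(L.ExpressionMatrix(transformed), rules), base
            )


class TestRankRules:
    def _toy(self):
        # three classes, four samples each, three genes with hand-set orderings
        genes = ["a", "b", "c"]
        cols, labels = [], []
        data = {
            "X": [10.0, 5.0, 1.0],   # a > b > c
            "Y": [1.0, 10.0, 5.0],   # b > c > a
            "Z": [5.0, 1.0, 10.0],   # c > a > b
        }
        for cls, vec in data.items():
            for i in range(4):
                cols.append(np.array(vec) + 0.0)
                labels.append(cls)
        df = pd.DataFrame(np.array(cols).T, index=genes,
                          columns=[f"{l}{i}" for i, l in enumerate(labels)])
        return L.ExpressionMatrix(df), np.array(labels)

    def test_maximal_rule_ranks_first(self):
        m, labels = self._toy()
        panel = L.MarkerPanel(classes={"X": ("a",), "Y": ("b",), "Z": ("c",)})
        rules = L.enumerate_pair_rules(panel)
        binary = L.binarize_rules(m, rules)
        ranked = L.rank_rules(binary, labels, rules)
        # rule (b, a) fires in all X (b < a) and in no Y (a < b); score vs rest:
        top_rule = rules[ranked["X"][0]]
        freq_in = binary[rules.index(top_rule), labels == "X"].mean()
        freq_out = binary[rules.index(top_rule), labels != "X"].mean()
        assert abs(freq_in - freq_out) == 1.0

    def test_ranks_match_brute_force(self):
        m, labels = self._toy()
        panel = L.MarkerPanel(classes={"X": ("a",), "Y": ("b",), "Z": ("c",)})
        rules = L.enumerate_pair_rules(panel)
        binary = L.binarize_rules(m, rules)
        ranked = L.rank_rules(binary, labels, rules)
        for cls, lst in ranked.items():
            in_c = labels == cls
            scores = [abs(binary[i, in_c].mean() - binary[i, ~in_c].mean())
                      for i in range(len(rules))]
            # brute force: stable sort by -score, then drop reverse orientations
            order = sorted(range(len(rules)), key=lambda i: (-scores[i], i))
            expected, seen = [], set()
            for i in order:
                pair = frozenset(rules[i])
                if pair not in seen:
                    seen.add(pair)
                    expected.append(i)
            assert lst == expected

    def test_null_rule_scores_zero(self):
        binary = np.array([[1, 1, 1, 1]])  # fires everywhere -> no discrimination
        rules = [L.PairRule("a", "b")]
        ranked = L.rank_rules(binary, np.array(["X", "X", "Y", "Y"]), rules)
        assert ranked["X"] == [0] and ranked["Y"] == [0]

    def test_small_class_rejected(self):
        binary = np.zeros((1, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="fewer than 2"):
            L.rank_rules(binary, np.array(["X", "X", "Y"]), [L.PairRule("a", "b")])


class TestNaiveBayes:
    def test_laplace_arithmetic(self):
        binary = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        labels = np.array(["c", "c", "d", "d"])
        cond, priors, classes = L.fit_naive_bayes(binary, labels, alpha=1.0)
        assert classes == ["c", "d"]
        assert cond[0, 0] == pytest.approx(3 / 4)   # fires 2 of 2 in c
        assert cond[0, 1] == pytest.approx(1 / 4)   # fires 0 of 2 in d
        np.testing.assert_allclose(priors, [0.5, 0.5])

    def test_large_alpha_limit(self):
        binary = np.array([[1, 1, 0, 0]], dtype=np.uint8)
        labels = np.array(["c", "c", "d", "d"])
        cond, _, _ = L.fit_naive_bayes(binary, labels, alpha=1e9)
        np.testing.assert_allclose(cond, 0.5, atol=1e-6)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError, match="alpha"):
            L.fit_naive_bayes(np.zeros((1, 2), dtype=np.uint8), np.array(["c", "d"]), alpha=0.0)

    def test_posteriors_match_brute_force_bernoulli_product(self):
        """Log-space NB equals the direct product of Bernoulli likelihoods (<= 6 rules)."""
        rng = np.random.default_rng(0)
        for n_rules, n_classes in [(1, 2), (3, 3), (6, 3)]:
            cond = rng.uniform(0.05, 0.95, size=(n_rules, n_classes))
            priors = rng.dirichlet(np.ones(n_classes))
            for bits in itertools.product([0, 1], repeat=n_rules):
                x = np.array(bits, dtype=np.uint8).reshape(n_rules, 1)
                post = _posteriors(x, cond, priors)[0]
                direct = priors * np.prod(
                    np.where(x == 1, cond, 1 - cond), axis=0
                )
                direct = direct / direct.sum()
                np.testing.assert_allclose(post, direct, atol=1e-9)
                assert post.sum() == pytest.approx(1.0, abs=1e-9)


class TestRuleCountSelection:
    def test_single_informative_rule_gives_k_one(self):
        # gene pair (a, b) separates the classes perfectly; gene c always on top
        rng = np.random.default_rng(1)
        n = 12
        a = np.concatenate([rng.uniform(1, 5, n), rng.uniform(6, 10, n)])
        b = np.concatenate([rng.uniform(6, 10, n), rng.uniform(1, 5, n)])
        c = np.full(2 * n, 100.0)
        df = pd.DataFrame([a, b, c], index=["a", "b", "c"],
                          columns=[f"s{i}" for i in range(2 * n)])
        labels = pd.Series(["X"] * n + ["Y"] * n, index=df.columns)
        panel = L.MarkerPanel(classes={"X": ("a",), "Y": ("b", "c")})
        rules = L.enumerate_pair_rules(panel)
        # 3 genes -> 3 distinct pairs, so exhaust every feasible k
        k_star, record = L.choose_rule_count(
            L.ExpressionMatrix(df), labels, rules, k_grid=range(1, 4), seed=0
        )
        assert record[1] == 1.0
        assert k_star == 1
        assert record[1] == max(record.values())

    def test_determinism(self, cohort):
        matrix, labels, _ = cohort
        panel = L.default_marker_panel()
        pm = L.resolve_panel(matrix, panel)
        rules = L.enumerate_pair_rules(panel)
        r1 = L.choose_rule_count(pm, labels, rules, k_grid=range(1, 8), seed=5)
        r2 = L.choose_rule_count(pm, labels, rules, k_grid=range(1, 8), seed=5)
        assert r1 == r2

    def test_k_grid_exceeding_rule_count(self, cohort):
        matrix, labels, _ = cohort
        panel = L.default_marker_panel()
        pm = L.resolve_panel(matrix, panel)
        rules = L.enumerate_pair_rules(panel)
        with pytest.raises(ValueError, match="exceeds"):
            L.choose_rule_count(pm, labels, rules, k_grid=[500], seed=0)

    def test_fold_reduction_warns(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(1, 100, (2, 7)), index=["a", "b"],
                          columns=[f"s{i}" for i in range(7)])
        labels = pd.Series(["X"] * 4 + ["Y"] * 3, index=df.columns)
        panel = L.MarkerPanel(classes={"X": ("a",), "Y": ("b",)})
        rules = L.enumerate_pair_rules(panel)
        with pytest.warns(UserWarning, match="reducing folds"):
            L.choose_rule_count(L.ExpressionMatrix(df), labels, rules,
                                k_grid=[1], folds=5, seed=0)


class TestTrainPredict:
    def test_reclassification_on_separable_cohort(self, cohort, model):
        matrix, labels, _ = cohort
        report = L.score_predictions(L.predict_ssp(model, matrix), labels)
        assert report.balanced_accuracy >= 0.95

    def test_same_seed_identical_serialized_model(self, cohort):
        matrix, labels, _ = cohort
        cfg = L.TrainConfig(seed=3)
        m1 = L.train_ssp(matrix, labels, config=cfg)
        m2 = L.train_ssp(matrix, labels, config=cfg)
        assert json.dumps(m1.to_dict(), sort_keys=True) == json.dumps(m2.to_dict(), sort_keys=True)

    def test_tiny_class_rejected(self, cohort):
        matrix, labels, _ = cohort
        labels = labels.copy()
        labels.iloc[0] = "RARE"
        with pytest.raises(ValueError, match="fewer than 3"):
            L.train_ssp(matrix, labels)

    def test_model_never_holds_both_orientations(self, model):
        pairs = [frozenset(r) for r in model.rules]
        assert len(set(pairs)) == len(pairs)

    def test_prototypic_sample_called_with_high_posterior(self, model):
        panel = model.panel
        vals = {g: 50.0 for g in panel.genes}
        for g in panel.classes["SqCC"]:
            vals[g] = 5000.0
        df = pd.DataFrame({"s": pd.Series(vals)}).loc[list(panel.genes)]
        pred = L.predict_ssp(model, L.ExpressionMatrix(df))[0]
        assert pred.predicted_class == "SqCC"
        assert pred.posterior["SqCC"] > 0.9

    def test_single_sample_contract_under_column_changes(self, model, cohort):
        matrix, _, _ = cohort
        full = {p.sample_id: p.posterior for p in L.predict_ssp(model, matrix)}
        # deletion: predict on a 3-column slice
        some = matrix.sample_ids[:3]
        for p in L.predict_ssp(model, matrix.subset_samples(some)):
            assert p.posterior == full[p.sample_id]
        # duplication: both copies identical
        dup = matrix.values[[matrix.sample_ids[0]]].copy()
        dup.columns = ["copy1"]
        both = pd.concat([matrix.values[[matrix.sample_ids[0]]], dup], axis=1)
        preds = L.predict_ssp(model, L.ExpressionMatrix(both))
        assert preds[0].posterior == preds[1].posterior

    def test_monotone_transform_leaves_predictions_unchanged(self, model, cohort):
        matrix, _, _ = cohort
        base = L.predict_ssp(model, matrix)
        cubed = L.ExpressionMatrix(matrix.values ** 3)
        for a, b in zip(base, L.predict_ssp(model, cubed)):
            assert a.predicted_class == b.predicted_class
            assert a.posterior == pytest.approx(b.posterior, abs=1e-12)

    def test_missing_rule_gene_rejected(self, model, cohort):
        matrix, _, _ = cohort
        trimmed = L.ExpressionMatrix(matrix.values.drop(index=["CHGA"]))
        with pytest.raises(ValueError, match="CHGA"):
            L.predict_ssp(model, trimmed)


class TestSelectRules:
    def test_round_robin_skips_duplicates(self):
        rules = [L.PairRule("a", "b"), L.PairRule("b", "a"), L.PairRule("a", "c"),
                 L.PairRule("c", "a"), L.PairRule("b", "c")]
        ranked = {"X": [0, 2, 4], "Y": [1, 3, 4]}
        sel = select_rules(ranked, 3, rules)
        # Y's picks (b,a) and (c,a) reverse X's already-chosen pairs -> skipped,
        # so the third slot falls to (b,c) at the next depth
        assert sel == [0, 2, 4]
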