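import numpy as np
import pytest

from leucidelim import (
    MeristicRecord,
    cva_permutation_test,
    fit_crt,
    fit_cva,
    key_text,
    loo_crossvalidate_cva,
    predict_crt,
)
from leucidelim.classify import ParameterError, best_split, crossvalidate_crt
from leucidelim.io import MERISTIC_CHARACTERS


def _toy_groups(rng, means, n=12, sd=1.0):
    xs, labels = [], []
    for name, mu in means.items():
        xs.append(rng.normal(mu, sd, size=(n, len(mu))))
        labels += [name] * n
    return np.vstack(xs), labels


class TestFitCva:
    def test_two_dim_three_group_matches_closed_form_oracle(self, rng):
        """Axes agree with an explicit 2x2 generalized-eigenproblem solution."""
        x, labels = _toy_groups(rng, {"a": [0, 0], "b": [3, 1], "c": [1, 4]})
        res = fit_cva(x, labels)
        # oracle: Sw^-1 Sb via explicit inverse and characteristic polynomial
        names = sorted(set(labels))
        means = {g: x[[i for i, l in enumerate(labels) if l == g]].mean(axis=0) for g in names}
        n, g = len(labels), len(names)
        sw = np.zeros((2, 2))
        for name in names:
            sub = x[[i for i, l in enumerate(labels) if l == name]] - means[name]
            sw += sub.T @ sub
        sw /= n - g
        grand = x.mean(axis=0)
        sb = np.zeros((2, 2))
        for name in names:
            d = means[name] - grand
            sb += len(labels) // g * np.outer(d, d)
        sb /= g - 1
        a, b, c, d = sw.ravel()
        swinv = np.array([[d, -b], [-c, a]]) / (a * d - b * c)
        m = swinv @ sb
        tr, det = m[0, 0] + m[1, 1], m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        lams = sorted(
            [(tr + np.sqrt(tr**2 - 4 * det)) / 2, (tr - np.sqrt(tr**2 - 4 * det)) / 2],
            reverse=True,
        )
        np.testing.assert_allclose(res.eigenvalues, lams, atol=1e-8)
        for j, lam in enumerate(lams):
            mm = m - lam * np.eye(2)
            v = np.array([mm[0, 1], -mm[0, 0]])
            if np.abs(v).max() < 1e-12:
                v = np.array([mm[1, 1], -mm[1, 0]])
            v = v / np.sqrt(v @ sw @ v)  # unit within-group variance
            fitted = res.canonical_axes[:, j]
            sign = np.sign(fitted @ v)
            np.testing.assert_allclose(fitted, sign * v, atol=1e-8)

    def test_four_groups_high_dim_gives_three_axes(self, small_configs):
        from leucidelim import gpa_align, partial_warp_scores

        w = partial_warp_scores(gpa_align(small_configs))
        res = fit_cva(w.scores, w.taxa)
        assert res.n_axes == 3
        assert res.mahalanobis.shape == (4, 4)
        assert np.allclose(res.mahalanobis, res.mahalanobis.T)
        assert np.all(np.diag(res.mahalanobis) == 0)

    def test_axis_identifies_separating_coordinate(self):
        # groups differ only in coordinate 0 and within-group deviations are
        # exactly balanced, so the axis must load coordinate 0 alone
        dev = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], float
        )
        x = np.vstack([dev, dev + [5.0, 0.0, 0.0]])
        labels = ["a"] * 6 + ["b"] * 6
        res = fit_cva(x, labels)
        load = res.canonical_axes[:, 0]
        assert max(abs(load[1]), abs(load[2])) < 1e-9
        assert abs(load[0]) > 0.1

    def test_scores_have_unit_pooled_within_variance(self, rng):
        x, labels = _toy_groups(rng, {"a": [0, 0, 0], "b": [2, 1, 0], "c": [0, 3, 1]}, n=15)
        res = fit_cva(x, labels)
        names = sorted(set(labels))
        n, g = len(labels), len(names)
        for j in range(res.n_axes):
            pooled = 0.0
            for name in names:
                rows = [i for i, l in enumerate(labels) if l == name]
                pooled += ((res.scores[rows, j] - res.scores[rows, j].mean()) ** 2).sum()
            assert pooled / (n - g) == pytest.approx(1.0, abs=1e-6)

    def test_invariant_to_invertible_linear_transform(self, rng):
        x, labels = _toy_groups(rng, {"a": [0, 0], "b": [3, 1], "c": [1, 4]})
        t = np.array([[2.0, 0.7], [-0.3, 1.5]])
        r1 = fit_cva(x, labels)
        r2 = fit_cva(x @ t, labels)
        for j in range(r1.n_axes):
            s = np.sign(r1.scores[0, j] * r2.scores[0, j])
            np.testing.assert_allclose(r1.scores[:, j], s * r2.scores[:, j], atol=1e-7)
        np.testing.assert_allclose(r1.mahalanobis, r2.mahalanobis, atol=1e-7)

    def test_small_group_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_cva(x, ["a", "a", "a", "a", "b"])


class TestLooCva:
    def test_perfectly_separated_groups(self, rng):
        x, labels = _toy_groups(rng, {"a": [0.0, 0.0], "b": [20.0, 0.0]}, n=10, sd=1.0)
        cm = loo_crossvalidate_cva(x, labels)
        assert cm.overall_correct_pct == 100.0
        assert cm.counts.sum(axis=1).tolist() == [10, 10]

    def test_matches_hand_enumerated_one_dim_oracle(self):
        """6-specimen, 2-group, 1-D instance vs explicit per-fold means."""
        x = np.array([[0.0], [1.0], [2.5], [3.0], [4.0], [5.0]])
        labels = ["a", "a", "a", "b", "b", "b"]
        cm = loo_crossvalidate_cva(x, labels)
        # oracle: for each fold compute group means on the rest and assign
        # by squared distance (the 1-D within variance cancels)
        expected = np.zeros((2, 2), int)
        for i in range(6):
            rest = [j for j in range(6) if j != i]
            ma = np.mean([x[j, 0] for j in rest if labels[j] == "a"])
            mb = np.mean([x[j, 0] for j in rest if labels[j] == "b"])
            assigned = "a" if abs(x[i, 0] - ma) <= abs(x[i, 0] - mb) else "b"
            expected[0 if labels[i] == "a" else 1, 0 if assigned == "a" else 1] += 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_chance_level_on_structureless_data(self):
        """Shuffled labels on noise give accuracy near 1/g."""
        rng = np.random.default_rng(77)
        hits = total = 0
        for _ in range(40):
            x = rng.normal(size=(24, 3))
            labels = list("ab" * 12)
            rng.shuffle(labels)
            cm = loo_crossvalidate_cva(x, labels)
            hits += np.trace(cm.counts)
            total += cm.counts.sum()
        # 99% binomial CI around 0.5 with ~960 trials
        assert abs(hits / total - 0.5) < 2.58 * np.sqrt(0.25 / total) + 0.02

    def test_singleton_group_rejected(self, rng):
        x = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="size 1"):
            loo_crossvalidate_cva(x, ["a", "a", "a", "a", "b"])


class TestCvaPermutation:
    def test_huge_separation_gives_minimum_p(self, rng):
        x, labels = _toy_groups(rng, {"a": [0.0, 0.0], "b": [50.0, 0.0]}, n=8)
        p = cva_permutation_test(x, labels, n_perm=99, seed=1)
        assert p[0, 1] == pytest.approx(1 / 100)

    def test_invariant_to_orthogonal_rotation(self, rng):
        x, labels = _toy_groups(rng, {"a": [0, 0], "b": [1.5, 0.5]}, n=10)
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        p1 = cva_permutation_test(x, labels, n_perm=49, seed=5)
        p2 = cva_permutation_test(x @ q, labels, n_perm=49, seed=5)
        assert p1[0, 1] == p2[0, 1]

    def test_bad_n_perm_rejected(self, rng):
        x, labels = _toy_groups(rng, {"a": [0, 0], "b": [1, 1]}, n=5)
        with pytest.raises(ParameterError):
            cva_permutation_test(x, labels, n_perm=0)


def _records(values_by_char, labels):
    n = len(labels)
    recs = []
    for i in range(n):
        counts = {c: 10 for c in MERISTIC_CHARACTERS}
        for c, vals in values_by_char.items():
            counts[c] = vals[i]
        recs.append(MeristicRecord(f"s{i}", counts, labels[i]))
    return recs


class TestCrt:
    def test_disjoint_ranges_single_split(self):
        recs = _records({"NSLL": [38, 39, 40, 38, 45, 46, 47, 45]}, list("aaaabbbb"))
        tree = fit_crt(recs, min_parent=2, min_child=1, cv_folds=0)
        assert tree.root.predictor == "NSLL"
        assert 40 < tree.root.threshold < 45
        assert all(predict_crt(tree, r) == l for r, l in zip(recs, list("aaaabbbb")))

    def test_root_split_matches_exhaustive_gini_oracle(self):
        """8-row toy table: split and impurity decrease vs exhaustive search."""
        nsll = [40, 41, 42, 43, 60, 61, 62, 63]
        labels = list("aaaabbbb")
        recs = _records({"NSLL": nsll}, labels)
        x = np.array([[r[c] for c in MERISTIC_CHARACTERS] for r in recs], float)
        found = best_split(x, np.array(labels, object), MERISTIC_CHARACTERS, 1)
        pi, thr, dec = found

        # oracle: enumerate every predictor and midpoint naively
        def gini(ls):
            n = len(ls)
            return 1 - sum((ls.count(c) / n) ** 2 for c in set(ls))

        best = (None, None, -1)
        for q, char in enumerate(MERISTIC_CHARACTERS):
            vals = sorted(set(x[:, q]))
            for lo, hi in zip(vals, vals[1:]):
                t = (lo + hi) / 2
                left = [l for v, l in zip(x[:, q], labels) if v <= t]
                right = [l for v, l in zip(x[:, q], labels) if v > t]
                d = gini(labels) - (len(left) * gini(left) + len(right) * gini(right)) / 8
                if d > best[2] + 1e-12:
                    best = (q, t, d)
        assert (pi, thr) == (best[0], best[1]) == (0, 51.5)
        assert dec == pytest.approx(best[2], abs=1e-12)

    def test_planted_predictor_recovered_across_seeds(self, templates):
        """The predictor planted with the largest class separation wins the root."""
        from dataclasses import replace
        from leucidelim import simulate_meristics

        overlap = {c: (10, 14) for c in MERISTIC_CHARACTERS}
        planted = [
            replace(templates[0], meristic_ranges=overlap | {"NRPF": (10, 12)}),
            replace(templates[1], meristic_ranges=overlap | {"NRPF": (15, 17)}),
        ]
        hits = 0
        for seed in range(100):
            recs = simulate_meristics(planted, [12, 12], seed=seed)
            tree = fit_crt(recs, min_parent=4, min_child=2, cv_folds=0)
            hits += tree.root.predictor == "NRPF"
        assert hits >= 95

    def test_threshold_tie_goes_left(self):
        recs = _records({"NSLL": [38, 39, 40, 45, 46, 47]}, list("aaabbb"))
        tree = fit_crt(recs, min_parent=2, min_child=1, cv_folds=0)
        t = tree.root.threshold
        probe = MeristicRecord("p", {c: 10 for c in MERISTIC_CHARACTERS} | {"NSLL": int(t) if t == int(t) else 42}, None)
        probe.counts["NSLL"] = 40  # below or at threshold
        assert predict_crt(tree, probe) == "a"

    def test_single_leaf_tree_constant_prediction(self):
        recs = _records({"NSLL": [40, 41, 40, 41]}, list("aabb"))
        tree = fit_crt(recs, min_parent=10, min_child=1, cv_folds=0)  # too small to split
        assert tree.root.is_leaf
        assert predict_crt(tree, recs[3]) == tree.root.label

    def test_training_impurity_never_increases_down_a_path(self, templates):
        from leucidelim import simulate_meristics

        recs = simulate_meristics(templates, [20, 20, 20, 20], seed=9)
        tree = fit_crt(recs, cv_folds=0)

        def walk(node):
            if node.is_leaf:
                return
            nl, nr, n = node.left.n, node.right.n, node.n
            child = (nl * node.left.impurity + nr * node.right.impurity) / n
            assert child <= node.impurity + 1e-12
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_matches_sklearn_tree_on_toy_data(self, templates):
        """Cross-check the greedy Gini splitter against an independent CART."""
        from sklearn.tree import DecisionTreeClassifier
        from leucidelim import simulate_meristics

        recs = simulate_meristics(templates, [25, 25, 25, 25], seed=21)
        x = np.array([[r[c] for c in MERISTIC_CHARACTERS] for r in recs], float)
        y = [r.taxon for r in recs]
        ours = fit_crt(recs, min_parent=10, min_child=5, max_depth=5, cv_folds=0)
        sk = DecisionTreeClassifier(
            criterion="gini", max_depth=5, min_samples_split=10, min_samples_leaf=5,
            random_state=0,
        ).fit(x, y)
        agree = np.mean([predict_crt(ours, r) == sk.predict(x[i : i + 1])[0] for i, r in enumerate(recs)])
        assert agree >= 0.95

    def test_constant_predictors_rejected(self):
        recs = _records({}, list("aabb"))
        with pytest.raises(ValueError, match="constant"):
            fit_crt(recs, cv_folds=0)

    def test_min_child_ge_min_parent_rejected(self):
        recs = _records({"NSLL": [1, 2, 3, 4]}, list("aabb"))
        with pytest.raises(ParameterError):
            fit_crt(recs, min_parent=5, min_child=5)

    def test_missing_predictor_raises(self):
        recs = _records({"NSLL": [38, 39, 45, 46]}, list("aabb"))
        tree = fit_crt(recs, min_parent=2, min_child=1, cv_folds=0)
        probe = MeristicRecord("p", {c: 10 for c in MERISTIC_CHARACTERS}, None)
        del probe.counts["NSLL"]
        with pytest.raises(KeyError):
            predict_crt(tree, probe)

    def test_key_text_renders_all_leaves(self, templates):
        from leucidelim import simulate_meristics

        recs = simulate_meristics(templates, [15, 15, 15, 15], seed=2)
        tree = fit_crt(recs, cv_folds=0)
        text = key_text(tree)
        for leaf in tree.leaves():
            assert leaf.label in text

    def test_stratified_cv_counts_cover_sample(self, templates):
        from leucidelim import simulate_meristics

        recs = simulate_meristics(templates, [15, 15, 15, 15], seed=5)
        labels = [r.taxon for r in recs]
        cm = crossvalidate_crt(recs, labels, cv_folds=5, seed=1)
        assert cm.counts.sum() == 60
        assert cm.counts.sum(axis=1).tolist() == [15, 15, 15, 15]
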