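import numpy as np
import pytest

from pathrise.pathway_trees import (
    ClassTree,
    Feature,
    TreeConfig,
    build_features,
    cost_complexity_sequence,
    evaluate_tree,
    grow,
    grow_tree,
    prune_and_select,
    taxonomic_sensitivity,
)
from pathrise.pathway_trees import _best_surrogate_for_feature, _split_gain


def balanced_weights(y):
    n1 = y.sum()
    n0 = len(y) - n1
    return np.where(y == 1, 0.5 / n1, 0.5 / n0)


def gini_gain_oracle(x_or_codes, y, w, kind="num", levels=()):
    """Exhaustive enumeration of every binary split (numeric thresholds or
    all category subsets), returning the best prior-weighted Gini decrease."""
    def gini_ext(mask):
        w1 = w[mask & (y == 1)].sum()
        w0 = w[mask & (y == 0)].sum()
        tot = w0 + w1
        return 2 * w0 * w1 / tot if tot > 0 else 0.0

    full = np.ones(len(y), dtype=bool)
    best = 0.0
    if kind == "num":
        vals = np.unique(x_or_codes)
        for thr in (vals[:-1] + vals[1:]) / 2:
            L = x_or_codes < thr
            if L.any() and (~L).any():
                best = max(best, gini_ext(full) - gini_ext(L) - gini_ext(~L))
    else:
        present = np.unique(x_or_codes)
        for mask_bits in range(1, 2 ** len(present) - 1):
            sel = {present[j] for j in range(len(present)) if mask_bits >> j & 1}
            L = np.isin(x_or_codes, list(sel))
            if L.any() and (~L).any():
                best = max(best, gini_ext(full) - gini_ext(L) - gini_ext(~L))
    return best


class TestSplitFinder:
    def test_six_case_toy(self):
        """y=(1,1,1,0,0,0) on x=1..6 must split at x<3.5 with the full
        improvement (pure children)."""
        f = [Feature("x", "num", np.arange(1.0, 7.0))]
        y = np.array([1, 1, 1, 0, 0, 0])
        tree = grow(f, y, TreeConfig(min_node_size=2))
        sp = tree.nodes[0].split
        assert sp.variable == "x"
        assert sp.threshold_or_subset == pytest.approx(3.5)
        assert sp.improvement == pytest.approx(1.0)
        assert tree.n_terminal == 2

    def test_matches_exhaustive_enumeration(self):
        """On 200 random tiny datasets (<= 8 cases, numeric + categorical)
        the chosen first split attains the exhaustively-enumerated optimum."""
        rng = np.random.default_rng(0)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 5, n).astype(float)
            codes = rng.integers(0, 3, n).astype(float)
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            w = balanced_weights(y)
            feats = [
                Feature("x", "num", x),
                Feature("c", "cat", codes, ("a", "b", "c")),
            ]
            cfg = TreeConfig(min_node_size=2, high_category_penalty=False)
            tree = grow(feats, y, cfg)
            sp = tree.nodes[0].split
            want = max(
                gini_gain_oracle(x, y, w, "num"),
                gini_gain_oracle(codes, y, w, "cat"),
            )
            if sp is None:
                assert want <= 1e-12
            else:
                root_gini = 2 * w[y == 0].sum() * w[y == 1].sum() / w.sum()
                got = sp.improvement * root_gini
                assert got == pytest.approx(want, abs=1e-12)
            checked += 1
        assert checked >= 150

    def test_gini_twoing_identity(self):
        """For two classes, twoing and Gini rank splits identically."""
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = 40
            feats = [
                Feature("x", "num", rng.normal(size=n)),
                Feature("c", "cat", rng.integers(0, 4, n).astype(float), ("a", "b", "c", "d")),
            ]
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            tg = grow(feats, y, TreeConfig(min_node_size=5, impurity="gini"))
            tt = grow(feats, y, TreeConfig(min_node_size=5, impurity="twoing"))
            sg, st = tg.nodes[0].split, tt.nodes[0].split
            assert (sg is None) == (st is None)
            if sg is not None:
                same = (
                    sg.variable == st.variable
                    and sg.threshold_or_subset == st.threshold_or_subset
                )
                # a floating-point near-tie may break differently; gains agree
                assert same or sg.improvement == pytest.approx(
                    st.improvement, abs=1e-9
                )

    def test_balanced_weights_equal_minority_duplication(self):
        """Balanced weighting picks the same first split as duplicating the
        minority class to parity and using unweighted impurity."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 60
            x = rng.normal(size=n)
            z = rng.normal(size=n)
            y = (rng.uniform(size=n) < 0.25).astype(int)
            if y.sum() < 2 or n - y.sum() < 2:
                continue
            k = (n - y.sum()) // y.sum()
            if k * y.sum() != n - y.sum():
                continue  # need exact parity for the identity
            feats = [Feature("x", "num", x), Feature("z", "num", z)]
            t_bal = grow(feats, y, TreeConfig(min_node_size=2))
            idx = np.concatenate([np.flatnonzero(y == 0)] + [np.flatnonzero(y == 1)] * k)
            feats_dup = [Feature("x", "num", x[idx]), Feature("z", "num", z[idx])]
            t_dup = grow(
                feats_dup, y[idx],
                TreeConfig(min_node_size=2, balanced_class_weights=False),
            )
            s1, s2 = t_bal.nodes[0].split, t_dup.nodes[0].split
            assert s1.variable == s2.variable
            assert s1.threshold_or_subset == pytest.approx(s2.threshold_or_subset)

    def test_single_class_rejected(self):
        f = [Feature("x", "num", np.arange(4.0))]
        with pytest.raises(ValueError, match="single class"):
            grow(f, np.ones(4, dtype=int), TreeConfig(min_node_size=2))


class TestSurrogates:
    def test_self_surrogate_association_is_one(self):
        """A duplicated predictor is a perfect surrogate (association 1)."""
        rng = np.random.default_rng(1)
        n = 50
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        feats = [Feature("x", "num", x), Feature("copy", "num", x.copy())]
        tree = grow(feats, y, TreeConfig(min_node_size=5), with_surrogates=True)
        sp = tree.nodes[0].split
        names = {v: a for v, _r, a in sp.surrogates}
        assert names["copy"] == pytest.approx(1.0)

    def test_surrogates_sorted_and_bounded(self):
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=n)
        y = (x + 0.3 * rng.normal(size=n) > 0).astype(int)
        feats = [
            Feature("x", "num", x),
            Feature("noisy", "num", x + rng.normal(size=n)),
            Feature("junk", "num", rng.normal(size=n)),
        ]
        tree = grow(feats, y, TreeConfig(min_node_size=10), with_surrogates=True)
        assoc = [a for _v, _r, a in tree.nodes[0].split.surrogates]
        assert all(0 < a <= 1 for a in assoc)
        assert assoc == sorted(assoc, reverse=True)

    def test_missing_cases_routed_never_dropped(self):
        """Children's raw class counts sum to the parent's even when the
        splitter has missing values."""
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        x_miss = x.copy()
        x_miss[rng.uniform(size=n) < 0.25] = np.nan
        feats = [
            Feature("x", "num", x_miss),
            Feature("proxy", "num", x + 0.5 * rng.normal(size=n)),
        ]
        tree = grow(feats, y, TreeConfig(min_node_size=20))
        for nd in tree.nodes:
            if nd.split is not None:
                left, right = tree.nodes[nd.left], tree.nodes[nd.right]
                assert (
                    np.array(nd.n_class)
                    == np.array(left.n_class) + np.array(right.n_class)
                ).all()

    def test_improvements_nonnegative(self, medium_synthetic):
        tree = grow_tree(
            medium_synthetic, "escape", TreeConfig(min_node_size=25)
        )
        for nd in tree.nodes:
            assert nd.improvement >= 0


class TestPruneAndSelect:
    def test_perfectly_separable_two_terminals(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.normal(size=n)
        y = (x > 0).astype(int)
        feats = [Feature("x", "num", x), Feature("z", "num", rng.normal(size=n))]
        cfg = TreeConfig(min_node_size=10, n_cv_repeats=10, seed=5)
        sel = prune_and_select(grow(feats, y, cfg), None, cfg, y=y)
        assert sel.n_terminal == 2
        ev = evaluate_tree(sel, None, cfg, y=y)
        assert ev["cross_validated"]["overall_misclassification"] == 0.0

    def test_no_signal_modal_root_under_one_se(self):
        """Pure label noise: the modal optimal size over repeated CV under
        the one-SE rule is the root-only tree."""
        rng = np.random.default_rng(0)
        n = 400
        y = rng.integers(0, 2, n)
        feats = [
            Feature("x1", "num", rng.normal(size=n)),
            Feature("x2", "num", rng.normal(size=n)),
        ]
        cfg = TreeConfig(
            min_node_size=25, n_cv_repeats=50, seed=1000, selection_rule="one_se"
        )
        sel = prune_and_select(grow(feats, y, cfg), None, cfg, y=y)
        assert sel.selection_report["modal_size"] == 1

    def test_one_se_never_larger_than_minimum_cost(self, medium_synthetic):
        """By construction the one-SE pick is at most the minimum-cost pick,
        repeat by repeat."""
        cfg = TreeConfig(min_node_size=25, n_cv_repeats=10, seed=3)
        tree = grow_tree(medium_synthetic, "escape", cfg)
        sel = prune_and_select(tree, medium_synthetic, cfg)
        rep = sel.selection_report
        assert all(
            o <= m for o, m in zip(rep["picks_one_se"], rep["picks_minimum_cost"])
        )

    def test_pruning_sequence_monotone(self, medium_synthetic):
        cfg = TreeConfig(min_node_size=10)
        tree = grow_tree(medium_synthetic, "contaminant", cfg)
        seq = cost_complexity_sequence(tree)
        alphas = [a for a, _n, _p in seq]
        sizes = [n for _a, n, _p in seq]
        assert sizes[-1] == 1
        assert all(a <= b + 1e-12 for a, b in zip(alphas, alphas[1:]))
        assert all(s1 > s2 for s1, s2 in zip(sizes, sizes[1:]))


class TestEvaluation:
    def test_root_only_tree_is_the_null_model(self):
        rng = np.random.default_rng(9)
        n = 100
        y = np.r_[np.ones(20, dtype=int), np.zeros(80, dtype=int)]
        feats = [Feature("x", "num", rng.normal(size=n))]
        cfg = TreeConfig(min_node_size=200)  # cannot split
        tree = grow(feats, y, cfg)
        assert tree.n_terminal == 1
        ev = evaluate_tree(tree, None, cfg, y=y)
        assert ev["resubstitution"]["overall_misclassification"] == pytest.approx(0.5)

    def test_informative_traits_give_youden_positive(self, medium_synthetic):
        """With informative traits, specificity + sensitivity > 1 for the
        contaminant tree (Youden's J > 0)."""
        cfg = TreeConfig(min_node_size=25, n_cv_repeats=5, seed=2)
        tree = grow_tree(medium_synthetic, "contaminant", cfg)
        sel = prune_and_select(tree, medium_synthetic, cfg)
        ev = evaluate_tree(sel, medium_synthetic, cfg)
        cv = ev["cross_validated"]
        assert cv["specificity"] + cv["sensitivity"] > 1.0


class TestFloraTrees:
    def test_release_tree_splits_on_life_form_woody(self, medium_synthetic):
        """The release tree's first split separates woody species into the
        high-probability child (trees and shrubs are what gets planted in
        the wild)."""
        cfg = TreeConfig(min_node_size=25, n_cv_repeats=5, seed=1)
        tree = grow_tree(medium_synthetic, "release", cfg)
        sp = tree.nodes[0].split
        assert sp.variable == "life_form"
        woody_side_left = "woody" in sp.threshold_or_subset
        child = tree.nodes[tree.nodes[0].left if woody_side_left else tree.nodes[0].right]
        other = tree.nodes[tree.nodes[0].right if woody_side_left else tree.nodes[0].left]
        frac_child = child.n_class[1] / sum(child.n_class)
        frac_other = other.n_class[1] / sum(other.n_class)
        assert frac_child > frac_other

    def test_determinism(self, small_synthetic):
        cfg = TreeConfig(min_node_size=25, n_cv_repeats=3, seed=11)
        a = prune_and_select(grow_tree(small_synthetic, "escape", cfg), small_synthetic, cfg)
        b = prune_and_select(grow_tree(small_synthetic, "escape", cfg), small_synthetic, cfg)
        assert a.selection_report["picks_one_se"] == b.selection_report["picks_one_se"]
        assert a.n_terminal == b.n_terminal

    def test_taxonomic_sensitivity_shuffled_taxonomy_uninformative(self):
        """With taxonomy shuffled at random, taxonomy-only trees hover at
        the 50% null while trait trees do better."""
        import dataclasses
        from pathrise.synthetic_flora import SyntheticConfig, generate

        table = generate(SyntheticConfig(n_species=500, seed=77, missingness={}))
        rng = np.random.default_rng(0)
        genera = [r.genus for r in table]
        rng.shuffle(genera)
        shuffled = dataclasses.replace(table)
        shuffled.records = [
            dataclasses.replace(r, genus=g, family=g, order=g)
            for r, g in zip(table.records, genera)
        ]
        cfg = TreeConfig(min_node_size=25, n_cv_repeats=3, seed=5)
        reports = taxonomic_sensitivity(shuffled, "contaminant", cfg)
        tax_err = reports["genus"].evaluation["cross_validated"]["overall_misclassification"]
        trait_err = reports["traits"].evaluation["cross_validated"]["overall_misclassification"]
        assert abs(tax_err - 0.5) < 0.07
        assert trait_err < tax_err
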