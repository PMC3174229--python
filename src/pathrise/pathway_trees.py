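"""Binary classification trees for pathway membership.

A from-scratch CART-style engine: binary recursive partitioning of a yes/no
target (was the species introduced by a given pathway?) from mixed numeric
and categorical trait predictors, with

* balanced class weights (each class carries prior mass 1/2 regardless of
  prevalence, so the null model misclassifies 50%);
* six split-homogeneity measures (Gini, symmetric Gini, entropy, class
  probability, twoing, ordered twoing — the twoing pair coincides with Gini
  for two-class problems);
* surrogate splits ranked by association, used to route cases with missing
  splitter values (cases are never dropped);
* optional penalties on high-level categorical splitters (improvement
  divided by log2(L) for L > 2 levels) and on splitters with missing values
  (improvement scaled by the observed-weight fraction);
* minimal cost-complexity pruning and optimal-size selection by repeated
  stratified 10-fold cross-validation under the minimum-cost and one-SE
  rules, taking the modal size over repeats.

Split improvements are prior-weighted impurity decreases normalized by the
root-node impurity, so they are comparable across trees and sum along a
branch like explained variance.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import (
    DISPERSAL_MODES,
    LIFE_FORMS,
    LIFE_SPANS,
    PATHWAYS,
    STRATEGIES,
    FloraTable,
)

__all__ = [
    "TreeConfig",
    "Feature",
    "Split",
    "Node",
    "ClassTree",
    "build_features",
    "grow_tree",
    "grow",
    "cost_complexity_sequence",
    "prune_and_select",
    "evaluate_tree",
    "taxonomic_sensitivity",
]

IMPURITIES = (
    "gini",
    "symmetric_gini",
    "entropy",
    "class_probability",
    "twoing",
    "ordered_twoing",
)

_EXHAUSTIVE_CAT_LEVELS = 12  # exhaustive subset search up to this many levels


@dataclass
class TreeConfig:
    impurity: str = "gini"
    min_node_size: int | None = None          # splitting-node size actually used
    min_node_sizes_to_try: tuple = (2, 5, 10, 25)
    n_cv_folds: int = 10
    n_cv_repeats: int = 50
    selection_rule: str = "both"              # minimum_cost | one_se | both
    balanced_class_weights: bool = True
    high_category_penalty: bool = True
    missing_penalty: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.impurity not in IMPURITIES:
            raise ValueError(f"impurity must be one of {IMPURITIES}")
        if self.n_cv_folds < 2:
            raise ValueError("n_cv_folds must be >= 2")
        sizes = self.sizes_to_try
        if any(s < 2 for s in sizes):
            raise ValueError("min node sizes must be >= 2")
        if self.selection_rule not in ("minimum_cost", "one_se", "both"):
            raise ValueError("selection_rule must be minimum_cost, one_se or both")

    @property
    def sizes_to_try(self) -> tuple:
        if self.min_node_size is not None:
            return (self.min_node_size,)
        return tuple(self.min_node_sizes_to_try)

    @property
    def effective_min_node_size(self) -> int:
        return self.sizes_to_try[0]


@dataclass
class Feature:
    """One predictor column: numeric (NaN = missing) or categorical
    (integer codes, -1 = missing)."""

    name: str
    kind: str                      # "num" | "cat"
    values: np.ndarray
    levels: tuple = ()

    def observed(self) -> np.ndarray:
        if self.kind == "num":
            return ~np.isnan(self.values)
        return self.values >= 0


@dataclass
class Split:
    variable: str
    kind: str                      # "numeric-threshold" | "category-subset"
    threshold_or_subset: object    # float, or frozenset of level names
    improvement: float
    surrogates: list = field(default_factory=list)  # (variable, rule, association)
    n_left: int = 0
    n_right: int = 0


@dataclass
class Node:
    id: int
    depth: int
    n_class: tuple                 # raw counts (absent, present)
    w_class: tuple                 # prior-weighted masses
    pred: int                      # majority class under priors
    split: Split | None = None
    left: int | None = None
    right: int | None = None
    majority_left: bool = True
    improvement: float = 0.0       # root-normalized prior-weighted decrease

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def pct_class(self) -> tuple:
        n = sum(self.n_class)
        return tuple(100.0 * c / n for c in self.n_class) if n else (0.0, 0.0)


@dataclass
class ClassTree:
    nodes: list                    # index = node id; root = 0
    features: list                 # list[Feature] used to grow
    target: str
    config: TreeConfig
    pruned: frozenset = frozenset()   # internal node ids treated as leaves
    selection_report: dict | None = None
    evaluation: dict | None = None

    def _effective_split(self, node: Node) -> Split | None:
        if node.id in self.pruned:
            return None
        return node.split

    @property
    def n_terminal(self) -> int:
        return sum(1 for nd in self._reachable() if self._effective_split(nd) is None)

    def _reachable(self):
        stack = [self.nodes[0]]
        while stack:
            nd = stack.pop()
            yield nd
            sp = self._effective_split(nd)
            if sp is not None:
                stack.append(self.nodes[nd.left])
                stack.append(self.nodes[nd.right])

    def predict(self, features: list) -> np.ndarray:
        """Class predictions (0/1) for cases described by parallel features."""
        cols = {f.name: f for f in features}
        n = len(features[0].values)
        out = np.empty(n, dtype=int)
        for i in range(n):
            nd = self.nodes[0]
            while True:
                sp = self._effective_split(nd)
                if sp is None:
                    out[i] = nd.pred
                    break
                go_left = _route_case(sp, cols, i, nd.majority_left)
                nd = self.nodes[nd.left if go_left else nd.right]
        return out

    def risk(self, features: list, y: np.ndarray, weights: np.ndarray) -> float:
        pred = self.predict(features)
        return float(np.sum(weights * (pred != y)) / np.sum(weights))


def _rule_left(rule: tuple, feat: Feature, i: int) -> bool | None:
    kind, value, reversed_ = rule
    v = feat.values[i]
    if kind == "numeric-threshold":
        if np.isnan(v):
            return None
        left = v < value
    else:
        if v < 0:
            return None
        left = feat.levels[int(v)] in value
    return (not left) if reversed_ else left


def _route_case(split: Split, cols: dict, i: int, majority_left: bool) -> bool:
    feat = cols.get(split.variable)
    if feat is not None:
        primary = _rule_left((split.kind, split.threshold_or_subset, False), feat, i)
        if primary is not None:
            return primary
    for var, rule, _assoc in split.surrogates:
        f = cols.get(var)
        if f is None:
            continue
        side = _rule_left(rule, f, i)
        if side is not None:
            return side
    return majority_left


# --------------------------------------------------------------------------
# impurity arithmetic (two classes, extensive form)


def _impurity_ext(name: str, w0, w1):
    w0 = np.asarray(w0, dtype=float)
    w1 = np.asarray(w1, dtype=float)
    w = w0 + w1
    with np.errstate(divide="ignore", invalid="ignore"):
        if name in ("gini", "symmetric_gini", "twoing", "ordered_twoing"):
            out = np.where(w > 0, 2.0 * w0 * w1 / np.maximum(w, 1e-300), 0.0)
        elif name == "entropy":
            p0 = np.where(w > 0, w0 / np.maximum(w, 1e-300), 0.0)
            p1 = np.where(w > 0, w1 / np.maximum(w, 1e-300), 0.0)
            out = -(
                np.where(w0 > 0, w0 * np.log(np.maximum(p0, 1e-300)), 0.0)
                + np.where(w1 > 0, w1 * np.log(np.maximum(p1, 1e-300)), 0.0)
            )
        elif name == "class_probability":
            out = np.minimum(w0, w1)
        else:
            raise ValueError(f"unknown impurity {name!r}")
    return out


def _split_gain(name: str, wl0, wl1, wr0, wr1):
    """Extensive impurity decrease of candidate splits (vectorized)."""
    wl0 = np.asarray(wl0, dtype=float); wl1 = np.asarray(wl1, dtype=float)
    wr0 = np.asarray(wr0, dtype=float); wr1 = np.asarray(wr1, dtype=float)
    if name in ("twoing", "ordered_twoing"):
        wl = wl0 + wl1
        wr = wr0 + wr1
        w = wl + wr
        with np.errstate(divide="ignore", invalid="ignore"):
            p1l = np.where(wl > 0, wl1 / np.maximum(wl, 1e-300), 0.0)
            p1r = np.where(wr > 0, wr1 / np.maximum(wr, 1e-300), 0.0)
            gain = np.where(
                (wl > 0) & (wr > 0), wl * wr / np.maximum(w, 1e-300) * (p1l - p1r) ** 2, 0.0
            )
        return gain
    parent = _impurity_ext(name, wl0 + wr0, wl1 + wr1)
    return parent - _impurity_ext(name, wl0, wl1) - _impurity_ext(name, wr0, wr1)


# --------------------------------------------------------------------------
# split search


def _cat_masks(n_levels: int) -> np.ndarray:
    """All proper, canonical (level-0-in-left) subsets as boolean rows."""
    masks = []
    for m in range(1, 2**n_levels - 1, 2):  # odd masks keep level 0 left
        masks.append([(m >> j) & 1 == 1 for j in range(n_levels)])
    return np.array(masks, dtype=bool)


def _best_split_for_feature(
    feat: Feature,
    y: np.ndarray,
    w: np.ndarray,
    idx: np.ndarray,
    config: TreeConfig,
):
    """Best (gain, rule) for one feature at one node; gain already carries
    the missing-value and high-category penalties."""
    obs = feat.observed()[idx]
    if not obs.any():
        return None
    sub = idx[obs]
    yv = y[sub]
    wv = w[sub]
    w_node = w[idx].sum()
    w_obs = wv.sum()
    if w_obs <= 0:
        return None
    penalty = 1.0
    if config.missing_penalty:
        penalty *= w_obs / w_node

    if feat.kind == "num":
        x = feat.values[sub]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        w1 = np.where(yv[order] == 1, wv[order], 0.0)
        w0 = wv[order] - w1
        c1 = np.cumsum(w1)[:-1]
        c0 = np.cumsum(w0)[:-1]
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            return None
        gains = _split_gain(config.impurity, c0, c1, c0[-1] + w0[-1] - c0, c1[-1] + w1[-1] - c1)
        gains = np.where(valid, gains, -np.inf)
        k = int(np.argmax(gains))
        if not np.isfinite(gains[k]) or gains[k] <= 0:
            return None
        thr = 0.5 * (xs[k] + xs[k + 1])
        return gains[k] * penalty, ("numeric-threshold", float(thr), False)

    codes = feat.values[sub].astype(int)
    present = np.unique(codes)
    if len(present) < 2:
        return None
    s1 = np.bincount(codes, weights=np.where(yv == 1, wv, 0.0), minlength=len(feat.levels))
    s0 = np.bincount(codes, weights=wv, minlength=len(feat.levels)) - s1
    s1 = s1[present]
    s0 = s0[present]
    L = len(present)
    if config.high_category_penalty and L > 2:
        penalty /= math.log2(L)
    if L <= _EXHAUSTIVE_CAT_LEVELS:
        masks = _cat_masks(L)
        wl1 = masks @ s1
        wl0 = masks @ s0
        gains = _split_gain(config.impurity, wl0, wl1, s0.sum() - wl0, s1.sum() - wl1)
        k = int(np.argmax(gains))
        if gains[k] <= 0:
            return None
        subset = frozenset(feat.levels[present[j]] for j in range(L) if masks[k, j])
        return gains[k] * penalty, ("category-subset", subset, False)
    # many levels: order by class-1 rate and scan contiguous splits
    rate = s1 / np.maximum(s0 + s1, 1e-300)
    order = np.argsort(rate, kind="stable")
    c1 = np.cumsum(s1[order])[:-1]
    c0 = np.cumsum(s0[order])[:-1]
    gains = _split_gain(config.impurity, c0, c1, s0.sum() - c0, s1.sum() - c1)
    k = int(np.argmax(gains))
    if gains[k] <= 0:
        return None
    subset = frozenset(feat.levels[present[j]] for j in order[: k + 1])
    return gains[k] * penalty, ("category-subset", subset, False)


def _best_surrogate_for_feature(
    feat: Feature, go_left: np.ndarray, w: np.ndarray, idx: np.ndarray
):
    """Best rule on ``feat`` mimicking the primary routing ``go_left``.

    Returns (association, rule) with the CART association
    (min(pL, pR) - missend) / min(pL, pR); reversed rules are allowed.
    """
    obs = feat.observed()[idx]
    if not obs.any():
        return None
    sub = idx[obs]
    gl = go_left[obs]
    wv = w[sub]
    w_both = wv.sum()
    wl = wv[gl].sum()
    wr = w_both - wl
    if w_both <= 0 or min(wl, wr) <= 0:
        return None
    p_min = min(wl, wr) / w_both

    best = None
    if feat.kind == "num":
        x = feat.values[sub]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        wl_cum = np.cumsum(np.where(gl[order], wv[order], 0.0))[:-1]
        w_cum = np.cumsum(wv[order])[:-1]
        valid = xs[1:] > xs[:-1]
        if not valid.any():
            return None
        agree = wl_cum + (wr - (w_cum - wl_cum))
        agree = np.where(valid, np.maximum(agree, w_both - agree), -np.inf)
        k = int(np.argmax(agree))
        if not np.isfinite(agree[k]):
            return None
        thr = 0.5 * (xs[k] + xs[k + 1])
        direct = wl_cum[k] + (wr - (w_cum[k] - wl_cum[k]))
        reversed_ = direct < w_both - direct
        best = (float(agree[k]), ("numeric-threshold", float(thr), bool(reversed_)))
    else:
        codes = feat.values[sub].astype(int)
        present = np.unique(codes)
        if len(present) < 2:
            return None
        sl = np.bincount(codes, weights=np.where(gl, wv, 0.0), minlength=len(feat.levels))[present]
        st = np.bincount(codes, weights=wv, minlength=len(feat.levels))[present]
        # optimal agreement subset: include level iff its left-mass dominates
        take = sl > st - sl
        agree = float(sl[take].sum() + (st[~take] - sl[~take]).sum())
        if agree <= w_both - agree:
            return None
        subset = frozenset(feat.levels[present[j]] for j in range(len(present)) if take[j])
        best = (agree, ("category-subset", subset, False))
    agreement, rule = best
    missend = 1.0 - agreement / w_both
    assoc = (p_min - missend) / p_min
    if assoc <= 0:
        return None
    return float(assoc), rule


# --------------------------------------------------------------------------
# growing


def grow(
    features: list,
    y: np.ndarray,
    config: TreeConfig,
    target: str = "target",
    with_surrogates: bool | None = None,
) -> ClassTree:
    """Grow a maximal tree on explicit feature columns.

    ``with_surrogates=None`` computes surrogates only when some feature has
    missing values (they are needed for routing then); True/False forces.
    """
    config.validate()
    y = np.asarray(y, dtype=int)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("target has a single class; nothing to model")
    if config.balanced_class_weights:
        w = np.where(y == 1, 0.5 / n1, 0.5 / n0)
    else:
        w = np.full(n, 1.0 / n)
    any_missing = any(not f.observed().all() for f in features)
    if with_surrogates is None:
        with_surrogates = any_missing

    root_imp = float(_impurity_ext(config.impurity, w[y == 0].sum(), w[y == 1].sum()))
    if config.impurity in ("twoing", "ordered_twoing"):
        # two-class twoing gain is exactly half the Gini gain; normalizing by
        # half the root Gini makes improvements numerically identical
        root_imp = 0.5 * float(_impurity_ext("gini", w[y == 0].sum(), w[y == 1].sum()))
    root_imp = max(root_imp, 1e-300)
    min_size = config.effective_min_node_size

    nodes: list[Node] = []

    def make_node(idx: np.ndarray, depth: int) -> int:
        nid = len(nodes)
        yv = y[idx]
        wv = w[idx]
        w1 = float(wv[yv == 1].sum())
        w0 = float(wv.sum()) - w1
        node = Node(
            id=nid,
            depth=depth,
            n_class=(int((yv == 0).sum()), int((yv == 1).sum())),
            w_class=(w0, w1),
            pred=int(w1 >= w0),
        )
        nodes.append(node)

        if len(idx) < min_size or min(node.n_class) == 0:
            return nid
        best = None
        for fi, feat in enumerate(features):
            res = _best_split_for_feature(feat, y, w, idx, config)
            if res is None:
                continue
            gain, rule = res
            if best is None or gain > best[0]:
                best = (gain, fi, rule)
        if best is None or best[0] <= 1e-12:
            return nid
        gain, fi, rule = best
        feat = features[fi]
        go_left = np.array(
            [_rule_left(rule, feat, i) for i in idx], dtype=object
        )
        split = Split(
            variable=feat.name,
            kind=rule[0],
            threshold_or_subset=rule[1],
            improvement=float(gain) / root_imp,
        )
        if with_surrogates:
            defined = np.array([g is not None for g in go_left])
            gl = np.array([bool(g) for g in np.where(defined, go_left, False)])
            surr = []
            for fj, other in enumerate(features):
                if fj == fi:
                    continue
                res = _best_surrogate_for_feature(
                    other, gl[defined], w, idx[defined]
                )
                if res is not None:
                    assoc, srule = res
                    surr.append((other.name, srule, assoc))
            surr.sort(key=lambda s: -s[2])
            split.surrogates = surr[:5]
        node.split = split
        # weighted majority direction among routed cases
        defined = np.array([g is not None for g in go_left])
        gl_def = np.array([bool(g) for g in go_left[defined]])
        w_def = w[idx[defined]]
        node.majority_left = bool(w_def[gl_def].sum() >= w_def[~gl_def].sum())
        # route every case (surrogates, then majority)
        cols = {f.name: f for f in features}
        final_left = np.empty(len(idx), dtype=bool)
        for k, i in enumerate(idx):
            if go_left[k] is not None:
                final_left[k] = bool(go_left[k])
            else:
                final_left[k] = _route_case(split, cols, i, node.majority_left)
        li, ri = idx[final_left], idx[~final_left]
        if len(li) == 0 or len(ri) == 0:
            node.split = None
            return nid
        split.n_left, split.n_right = len(li), len(ri)
        node.improvement = split.improvement
        node.left = make_node(li, depth + 1)
        node.right = make_node(ri, depth + 1)
        return nid

    make_node(np.arange(n), 0)
    return ClassTree(nodes=nodes, features=features, target=target, config=config)


# --------------------------------------------------------------------------
# feature construction from a flora table


def _set_field_features(name: str, sets: list, levels: tuple) -> list:
    """Encode a set-valued trait: one categorical if everyone has <= 1 value,
    else one 0/1 indicator feature per level (missing stays missing)."""
    if all(s is None or len(s) <= 1 for s in sets):
        codes = np.array(
            [-1 if not s else levels.index(next(iter(s))) for s in
             (set(s) if s else set() for s in sets)],
            dtype=float,
        )
        return [Feature(name, "cat", codes, levels)]
    feats = []
    for lev in levels:
        vals = np.array(
            [np.nan if s is None else float(lev in s) for s in sets], dtype=float
        )
        codes = np.where(np.isnan(vals), -1.0, vals)
        feats.append(Feature(f"{name}={lev}", "cat", codes, ("no", "yes")))
    return feats


def build_features(table: FloraTable, predictor_set: str = "traits") -> list:
    """Predictor columns for the trees.

    ``predictor_set`` is "traits" (biology + residence time + origin) or one
    of "genus"/"family"/"order" (taxonomy-only trees used to gauge how much
    of the trait signal is phylogenetically structured).
    """
    recs = list(table)
    if predictor_set in ("genus", "family", "order"):
        names = [getattr(r, predictor_set) for r in recs]
        levels = tuple(sorted(set(names)))
        codes = np.array([levels.index(v) for v in names], dtype=float)
        return [Feature(predictor_set, "cat", codes, levels)]
    if predictor_set != "traits":
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    feats: list[Feature] = []
    feats += _set_field_features("life_form", [r.life_form for r in recs], LIFE_FORMS)
    feats += _set_field_features("life_span", [r.life_span for r in recs], LIFE_SPANS)
    feats += _set_field_features("strategy", [r.strategy for r in recs], STRATEGIES)
    feats.append(
        Feature(
            "height_m",
            "num",
            np.array([np.nan if r.height_m is None else r.height_m for r in recs]),
        )
    )
    feats += _set_field_features(
        "reproduction",
        [None if r.reproduction is None else {r.reproduction} for r in recs],
        ("seed_only", "seed_and_vegetative"),
    )
    feats.append(
        Feature(
            "propagule_size_mg",
            "num",
            np.array(
                [np.nan if r.propagule_size_mg is None else r.propagule_size_mg for r in recs]
            ),
        )
    )
    feats += _set_field_features("dispersal", [r.dispersal for r in recs], DISPERSAL_MODES)
    feats += _set_field_features(
        "origin",
        [None if r.origin is None else {r.origin} for r in recs],
        ("europe", "other_continent"),
    )
    years = [r.first_record_year for r in recs]
    known = [y for y in years if y is not None]
    ref = max(known) if known else 0
    feats.append(
        Feature(
            "residence_time",
            "num",
            np.array([np.nan if y is None else float(ref - y) for y in years]),
        )
    )
    return feats


def _target_vector(table: FloraTable, pathway: str) -> np.ndarray:
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    return np.array([int(pathway in r.pathways) for r in table], dtype=int)


def grow_tree(
    table: FloraTable,
    target_pathway: str,
    config: TreeConfig,
    predictor_set: str = "traits",
) -> ClassTree:
    """Grow the maximal tree predicting membership in ``target_pathway``."""
    y = _target_vector(table, target_pathway)
    features = build_features(table, predictor_set)
    if len(y) < 2 * config.effective_min_node_size:
        raise ValueError("too few cases for the configured splitting-node size")
    return grow(features, y, config, target=target_pathway)


# --------------------------------------------------------------------------
# pruning


def _subtree_stats(tree: ClassTree, pruned: frozenset):
    """risk and leaf count of every node's (pruned) subtree."""
    n_nodes = len(tree.nodes)
    risk_leaf = np.empty(n_nodes)
    w_total = sum(tree.nodes[0].w_class)
    for nd in tree.nodes:
        risk_leaf[nd.id] = min(nd.w_class) / w_total
    risk_sub = risk_leaf.copy()
    leaves = np.ones(n_nodes, dtype=int)
    for nd in sorted(tree.nodes, key=lambda x: -x.depth):
        if nd.split is not None and nd.id not in pruned:
            risk_sub[nd.id] = risk_sub[nd.left] + risk_sub[nd.right]
            leaves[nd.id] = leaves[nd.left] + leaves[nd.right]
    return risk_leaf, risk_sub, leaves


def cost_complexity_sequence(tree: ClassTree) -> list:
    """Weakest-link pruning sequence [(alpha, n_terminals, pruned_set), ...]
    from the maximal tree (alpha = 0) down to the root-only tree."""
    pruned: frozenset = frozenset()
    seq = [(0.0, ClassTree(**{**tree.__dict__, "pruned": pruned}).n_terminal, pruned)]
    while True:
        risk_leaf, risk_sub, leaves = _subtree_stats(tree, pruned)
        internal = [
            nd for nd in tree.nodes
            if nd.split is not None and nd.id not in pruned and _is_reachable(tree, nd.id, pruned)
            and leaves[nd.id] > 1
        ]
        if not internal:
            break
        g = {
            nd.id: (risk_leaf[nd.id] - risk_sub[nd.id]) / (leaves[nd.id] - 1)
            for nd in internal
        }
        alpha = min(g.values())
        to_prune = {nid for nid, val in g.items() if val <= alpha + 1e-15}
        pruned = frozenset(pruned | to_prune)
        n_term = ClassTree(**{**tree.__dict__, "pruned": pruned}).n_terminal
        seq.append((float(alpha), n_term, pruned))
    return seq


def _is_reachable(tree: ClassTree, nid: int, pruned: frozenset) -> bool:
    # walk from root following unpruned splits
    target_depth = tree.nodes[nid].depth
    stack = [0]
    while stack:
        cur = stack.pop()
        if cur == nid:
            return True
        nd = tree.nodes[cur]
        if nd.split is not None and cur not in pruned:
            stack.append(nd.left)
            stack.append(nd.right)
    return False


def _pruned_at_alpha(seq: list, alpha: float) -> frozenset:
    best = seq[0][2]
    for a, _n, pr in seq:
        if a <= alpha + 1e-15:
            best = pr
        else:
            break
    return best


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(len(y), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def _balanced_error(pred: np.ndarray, y: np.ndarray) -> tuple:
    """(error, se) under balanced priors: mean of the two class error rates."""
    errs = []
    var = 0.0
    for cls in (0, 1):
        m = y == cls
        n = int(m.sum())
        e = float((pred[m] != cls).mean()) if n else 0.0
        errs.append(e)
        if n:
            var += 0.25 * e * (1 - e) / n
    return 0.5 * sum(errs), math.sqrt(var)


def prune_and_select(
    tree: ClassTree, table: FloraTable | None, config: TreeConfig, y: np.ndarray | None = None
) -> ClassTree:
    """Select the optimal subtree size by repeated stratified k-fold CV.

    Each repeat r (seeded ``config.seed + r``) grows fold trees, maps their
    pruning sequences onto the master sequence through geometric-mean alphas,
    and records the optimal size under the minimum-cost and one-SE rules.
    The modal size across repeats (per the configured rule, pooled for
    "both") picks the final subtree; the full distribution is kept in
    ``selection_report``.
    """
    config.validate()
    features = tree.features
    if y is None:
        y = _target_vector(table, tree.target)
    y = np.asarray(y, dtype=int)
    master_seq = cost_complexity_sequence(tree)
    alphas = np.maximum(np.array([a for a, _n, _p in master_seq]), 0.0)
    sizes = np.array([n for _a, n, _p in master_seq])
    mid = np.sqrt(alphas[:-1] * np.maximum(alphas[1:], 1e-300))
    mid = np.concatenate([mid, [np.inf]])
    n_seq = len(master_seq)

    picks_min: list[int] = []
    picks_ose: list[int] = []
    rep_curves = None
    for r in range(config.n_cv_repeats):
        rng = np.random.default_rng(config.seed + r)
        folds = _stratified_folds(y, config.n_cv_folds, rng)
        preds = np.empty((n_seq, len(y)), dtype=int)
        fold_errs = np.empty((n_seq, config.n_cv_folds))
        for f in range(config.n_cv_folds):
            train = folds != f
            test = ~train
            for _attempt in range(20):
                if y[train].min() != y[train].max():
                    break
                folds = _stratified_folds(y, config.n_cv_folds, rng)
                train = folds != f
                test = ~train
            sub_feats = [
                Feature(ft.name, ft.kind, ft.values[train], ft.levels) for ft in features
            ]
            ft_tree = grow(sub_feats, y[train], config, target=tree.target)
            fold_seq = cost_complexity_sequence(ft_tree)
            test_feats = [
                Feature(ft.name, ft.kind, ft.values[test], ft.levels) for ft in features
            ]
            for m in range(n_seq):
                pr = _pruned_at_alpha(fold_seq, mid[m])
                sub = ClassTree(**{**ft_tree.__dict__, "pruned": pr})
                preds[m, test] = sub.predict(test_feats)
                fold_errs[m, f] = _balanced_error(preds[m, test], y[test])[0]
        errs = np.empty(n_seq)
        ses = np.empty(n_seq)
        for m in range(n_seq):
            errs[m], binom_se = _balanced_error(preds[m], y)
            # the error estimate carries two independent noise sources: the
            # binomial sampling of the cases and the fold-assignment /
            # fold-tree variability; combine them
            fold_se = fold_errs[m].std(ddof=1) / math.sqrt(config.n_cv_folds)
            ses[m] = math.sqrt(binom_se**2 + fold_se**2)
        best = int(np.argmin(errs))
        picks_min.append(int(sizes[best]))
        within = errs <= errs[best] + ses[best]
        picks_ose.append(int(sizes[within].min()))
        if rep_curves is None:
            rep_curves = pd.DataFrame({"size": sizes, "cv_error": errs, "se": ses})

    pooled = {
        "minimum_cost": picks_min,
        "one_se": picks_ose,
        "both": picks_min + picks_ose,
    }[config.selection_rule]
    modal = Counter(pooled).most_common()
    top = max(c for _s, c in modal)
    modal_size = min(s for s, c in modal if c == top)  # smaller tree on ties
    k = int(np.argmin(np.abs(sizes - modal_size)))
    out = ClassTree(**{**tree.__dict__, "pruned": master_seq[k][2]})
    out.selection_report = {
        "modal_size": int(modal_size),
        "picks_minimum_cost": picks_min,
        "picks_one_se": picks_ose,
        "cv_curve": rep_curves,
        "master_sizes": sizes.tolist(),
    }
    return out


# --------------------------------------------------------------------------
# evaluation


def evaluate_tree(
    tree: ClassTree, table: FloraTable | None, config: TreeConfig, y: np.ndarray | None = None
) -> dict:
    """Misclassification, specificity and sensitivity of a selected tree.

    Resubstitution figures come from predicting the training cases;
    cross-validated figures from out-of-fold predictions of fold trees
    pruned to the selected size.  The balanced-priors null model
    misclassifies 50%, the benchmark for the overall rate.
    """
    if y is None:
        y = _target_vector(table, tree.target)
    y = np.asarray(y, dtype=int)
    features = tree.features
    pred = tree.predict(features)

    def _metrics(p):
        tn = int(((p == 0) & (y == 0)).sum())
        fp = int(((p == 1) & (y == 0)).sum())
        fn = int(((p == 0) & (y == 1)).sum())
        tp = int(((p == 1) & (y == 1)).sum())
        spec = tn / (tn + fp) if tn + fp else float("nan")
        sens = tp / (tp + fn) if tp + fn else float("nan")
        err, _se = _balanced_error(p, y)
        return {"overall_misclassification": err, "specificity": spec, "sensitivity": sens}

    out = {"resubstitution": _metrics(pred), "null_misclassification": 0.5}
    size = tree.n_terminal
    rng = np.random.default_rng(config.seed)
    folds = _stratified_folds(y, config.n_cv_folds, rng)
    cv_pred = np.empty(len(y), dtype=int)
    for f in range(config.n_cv_folds):
        train = folds != f
        sub_feats = [Feature(ft.name, ft.kind, ft.values[train], ft.levels) for ft in features]
        ft_tree = grow(sub_feats, y[train], config, target=tree.target)
        seq = cost_complexity_sequence(ft_tree)
        ns = np.array([n for _a, n, _p in seq])
        k = int(np.argmin(np.abs(ns - size)))
        sub = ClassTree(**{**ft_tree.__dict__, "pruned": seq[k][2]})
        test_feats = [Feature(ft.name, ft.kind, ft.values[~train], ft.levels) for ft in features]
        cv_pred[~train] = sub.predict(test_feats)
    out["cross_validated"] = _metrics(cv_pred)
    return out


def taxonomic_sensitivity(
    table: FloraTable, target_pathway: str, config: TreeConfig
) -> dict:
    """Selected trees from traits vs from each taxonomy-only predictor set,
    with their evaluation metrics side by side."""
    out = {}
    y = _target_vector(table, target_pathway)
    for pset in ("traits", "genus", "family", "order"):
        maximal = grow_tree(table, target_pathway, config, predictor_set=pset)
        selected = prune_and_select(maximal, table, config, y=y)
        selected.evaluation = evaluate_tree(selected, table, config, y=y)
        out[pset] = selected
    return out
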