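"""Posterior probability of function for every node of a tree.

After the upward (pruning) pass has produced, for each node, the
probability of its induced annotated subtree conditional on its own
state, a downward root-to-leaves pass combines each node's subtree term
with the information carried by the rest of the tree through its parent.
The root posterior is available in closed form from the root partials;
every other node divides its parent's joint probability by the
parent-conditional contribution of its own subtree, applies the
branch-specific transition probabilities, and sums over parent states.
Per-node rescaling from the upward pass cancels in these ratios, so the
pass is numerically stable on trees of any size.

Leave-one-out (LOO) predictions — used for honest error estimation —
recompute the posterior of each annotated leaf after deleting that
leaf's own annotation.  Credible intervals propagate parameter
uncertainty by re-running the decoding under parameter draws from an
MCMC trace.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .inference import MCMCTrace, summarize
from .likelihood import PruningCache, TreeSizeError, prune
from .model import ModelParameters
from .treeio import AnnotationSet, PhyloTree

try:  # pragma: no cover
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

PREDICTION_COLUMNS = ["tree", "node", "function", "posterior_prob",
                      "ci_low", "ci_high", "loo"]


@njit(cache=True)
def _down_pass(parent, bevent, partials, trans, pi, joint):
    """Root-to-leaves pass filling joint[i, s] ~ P(tree data, x_i = s).

    Arrays are in post-order (root last), so iterating in reverse visits
    parents before children.  All values share one arbitrary scale factor
    inherited from the normalized upward partials; posteriors are ratios
    so the factor cancels.
    """
    n = parent.shape[0]
    joint[n - 1, 0] = (1.0 - pi) * partials[n - 1, 0]
    joint[n - 1, 1] = pi * partials[n - 1, 1]
    for i in range(n - 2, -1, -1):
        p = parent[i]
        e = bevent[i]
        c0 = 0.0
        c1 = 0.0
        for sp in range(2):
            den = partials[i, 0] * trans[e, sp, 0] + partials[i, 1] * trans[e, sp, 1]
            if den > 0.0 and joint[p, sp] > 0.0:
                w = joint[p, sp] / den
                c0 += w * trans[e, sp, 0]
                c1 += w * trans[e, sp, 1]
        joint[i, 0] = partials[i, 0] * c0
        joint[i, 1] = partials[i, 1] * c1


def _decode(tree: PhyloTree, ann: AnnotationSet, params: ModelParameters,
            function: Optional[str] = None) -> Tuple[np.ndarray, PruningCache]:
    """Posterior P(x_n = 1 | data) for every node, indexed by node id."""
    ll, cache = prune(tree, ann, params, function, reduced=False)
    flat = cache.flat
    n = flat.n_nodes
    trans = np.stack([params.transition_matrix("speciation"),
                      params.transition_matrix("duplication")])
    joint = np.empty((n, 2))
    _down_pass(flat.parent, flat.bevent, cache.partials, trans, params.pi, joint)
    total = joint.sum(axis=1)
    post = np.full(tree.n_nodes, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(total > 0.0, joint[:, 1] / total, 0.5)
    post[flat.orig_ids] = p1
    return post, cache


def _table(tree: PhyloTree, post: np.ndarray, function: str, tree_id: str,
           loo: bool = False, node_ids: Optional[Iterable[int]] = None
           ) -> pd.DataFrame:
    ids = list(node_ids) if node_ids is not None else [n.id for n in tree.nodes]
    return pd.DataFrame({
        "tree": tree_id,
        "node": [tree.nodes[i].label for i in ids],
        "function": function,
        "posterior_prob": [post[i] for i in ids],
        "ci_low": np.nan,
        "ci_high": np.nan,
        "loo": loo,
    })


def node_posteriors(tree: PhyloTree, ann: AnnotationSet,
                    params: ModelParameters, function: Optional[str] = None,
                    tree_id: str = "t0") -> pd.DataFrame:
    """Posterior probability of function for ALL nodes, annotated or not.

    With an empty annotation set the root posterior is exactly pi and
    every other node is the prior marginal obtained by chaining the
    branch transition matrices down from the root.
    """
    function = function or (ann.functions[0] if len(ann) else "fn")
    post, _ = _decode(tree, ann, params, function if len(ann) else None)
    return _table(tree, post, function, tree_id)


def brute_force_posteriors(tree: PhyloTree, ann: AnnotationSet,
                           params: ModelParameters,
                           function: Optional[str] = None,
                           tree_id: str = "t0") -> pd.DataFrame:
    """Exact per-node posteriors by enumeration of all 2^|N| assignments.

    Independent test oracle for :func:`node_posteriors` (<= 12 nodes).
    """
    import itertools

    if tree.n_nodes > 12:
        raise TreeSizeError(f"{tree.n_nodes} nodes exceeds the enumeration limit of 12")
    states = ann.leaf_states(function) if len(ann) else {}
    function = function or (ann.functions[0] if len(ann) else "fn")
    err = params.error_matrix()
    joint = np.zeros((tree.n_nodes, 2))
    root_id = tree.root.id
    for assign in itertools.product((0, 1), repeat=tree.n_nodes):
        p = params.pi if assign[root_id] == 1 else 1.0 - params.pi
        for node in tree.nodes:
            if node.parent_id is not None:
                ev = tree.nodes[node.parent_id].kind
                p *= params.transition_matrix(ev)[assign[node.parent_id], assign[node.id]]
            if node.is_leaf and node.label in states:
                p *= err[assign[node.id], states[node.label]]
        for nid in range(tree.n_nodes):
            joint[nid, assign[nid]] += p
    post = joint[:, 1] / joint.sum(axis=1)
    return _table(tree, post, function, tree_id)


def loo_predictions(tree: PhyloTree, ann: AnnotationSet,
                    params: ModelParameters, function: Optional[str] = None,
                    tree_id: str = "t0") -> pd.DataFrame:
    """Leave-one-out posterior for every annotated leaf.

    Each annotated leaf's posterior is recomputed with that single
    annotation removed, so a leaf never informs its own prediction.  The
    returned table carries the held-out observed state in ``observed``.
    """
    if len(ann) == 0:
        raise ValueError("leave-one-out requires at least one annotated leaf")
    rows = []
    for (leaf, func), z in sorted(ann):
        if function is not None and func != function:
            continue
        reduced = ann.without(leaf, func)
        post, _ = _decode(tree, reduced, params, func if len(reduced) else None)
        nid = tree.node_by_label(leaf).id
        rows.append({
            "tree": tree_id, "node": leaf, "function": func,
            "posterior_prob": post[nid], "ci_low": np.nan, "ci_high": np.nan,
            "loo": True, "observed": z,
        })
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS + ["observed"])


def credible_intervals(tree: PhyloTree, ann: AnnotationSet, trace: MCMCTrace,
                       n_draws: int = 200, level: float = 0.95, seed: int = 0,
                       function: Optional[str] = None,
                       tree_id: str = "t0") -> pd.DataFrame:
    """Equal-tailed credible intervals for each node's posterior.

    ``n_draws`` parameter vectors are resampled (with replacement) from
    the kept MCMC draws; the decoding is repeated per draw and per-node
    empirical percentiles at (1 - level)/2 and (1 + level)/2 form the
    interval.  The point estimate is the posterior at the trace mean.
    """
    if trace.n_kept == 0:
        raise ValueError("empty trace")
    if n_draws < 2:
        raise ValueError("need at least two parameter draws")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    stacked = trace.stacked()
    space = trace.space()
    idx = rng.integers(0, stacked.shape[0], size=n_draws)
    sims = np.empty((n_draws, tree.n_nodes))
    for k, i in enumerate(idx):
        post, _ = _decode(tree, ann, space.to_params(stacked[i]), function)
        sims[k] = post
    lo, hi = np.percentile(sims, [50 * (1 - level), 50 * (1 + level)], axis=0)
    point = summarize(trace).point
    post, _ = _decode(tree, ann, point, function)
    table = node_posteriors(tree, ann, point, function, tree_id)
    table["posterior_prob"] = [post[tree.node_by_label(l).id] for l in table["node"]]
    table["ci_low"] = [lo[tree.node_by_label(l).id] for l in table["node"]]
    table["ci_high"] = [hi[tree.node_by_label(l).id] for l in table["node"]]
    return table


def high_confidence(table: pd.DataFrame, low: float = 0.1,
                    high: float = 0.9) -> pd.DataFrame:
    """Rows whose credible interval lies entirely below ``low`` (confident
    absence) or entirely above ``high`` (confident presence)."""
    if table["ci_low"].isna().any() or table["ci_high"].isna().any():
        raise ValueError("high-confidence selection requires credible intervals")
    keep = (table["ci_high"] < low) | (table["ci_low"] > high)
    return table[keep].reset_index(drop=True)
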