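"""Likelihood of experimentally annotated trees by pruning.

The probability of the observed leaf annotations is computed by the
classic post-order pruning (peeling) recursion for a two-state character,
with three twists: (i) an observation-error layer at annotated leaves,
(ii) gain/loss probabilities selected by the event class (duplication or
speciation) of each branch's parent node, and (iii) a *reduced* pruning
order that skips subtrees without any annotation, which contribute a
factor of one.

Trees are flattened to parallel arrays in post-order so the hot loop is a
single pass over nodes, compiled with numba.  Partial likelihoods are
rescaled per node with a log-scale accumulator to avoid underflow on
large pooled tree sets.  A full-enumeration oracle over all 2^|N| state
assignments is provided for testing on tiny trees.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import ModelParameters
from .treeio import AnnotationSet, PhyloTree, reduced_pruning_order

try:  # pragma: no cover - exercised implicitly by every test
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

#: event-class codes used in flattened arrays
EV_SPECIATION = 0
EV_DUPLICATION = 1


class TreeSizeError(ValueError):
    """Raised when a brute-force oracle is asked to enumerate too large a tree."""


@njit(cache=True)
def _forest_pass(parent, bevent, leafz, isleaf, trans, err, pi,
                 partials, tree_ll, tree_scale):
    """One post-order pruning pass over a flattened forest.

    ``partials`` must enter filled with ones; on exit row i holds the
    max-normalized conditional probabilities (L0, L1) of node i's induced
    subtree.  Per-tree log-likelihood and accumulated log-scale are written
    to ``tree_ll``/``tree_scale``; returns the total log-likelihood.
    """
    n = parent.shape[0]
    total = 0.0
    scale = 0.0
    ok = True
    t = 0
    for i in range(n):
        if isleaf[i] and leafz[i] >= 0:
            z = leafz[i]
            L0 = err[0, z]
            L1 = err[1, z]
        else:
            L0 = partials[i, 0]
            L1 = partials[i, 1]
        m = L0 if L0 > L1 else L1
        if m > 0.0:
            L0 /= m
            L1 /= m
            scale += math.log(m)
        else:
            ok = False
        partials[i, 0] = L0
        partials[i, 1] = L1
        p = parent[i]
        if p >= 0:
            e = bevent[i]
            partials[p, 0] *= L0 * trans[e, 0, 0] + L1 * trans[e, 0, 1]
            partials[p, 1] *= L0 * trans[e, 1, 0] + L1 * trans[e, 1, 1]
        else:
            lik = pi * L1 + (1.0 - pi) * L0
            if ok and lik > 0.0:
                ll = scale + math.log(lik)
            else:
                ll = -np.inf
            tree_ll[t] = ll
            tree_scale[t] = scale
            total += ll
            t += 1
            scale = 0.0
            ok = True
    return total


@dataclass
class FlatTree:
    """A single tree flattened to post-order parallel arrays.

    Index i is the i-th node of the (possibly reduced) post-order; the
    root is last.  ``bevent`` holds the event class of the *parent* node
    (the class governing the branch above node i); ``leafz`` is the
    observed state at annotated leaves and -1 elsewhere.
    """

    parent: np.ndarray       # int64, -1 at root
    bevent: np.ndarray       # int8, EV_* of parent node (-1 at root)
    leafz: np.ndarray        # int8, -1 when unannotated/internal
    isleaf: np.ndarray       # bool
    orig_ids: np.ndarray     # int64, node ids in the source PhyloTree

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]


def flatten_tree(tree: PhyloTree, ann: AnnotationSet,
                 function: Optional[str] = None,
                 reduced: bool = True) -> Optional[FlatTree]:
    """Flatten one tree; returns None when the reduced order is empty."""
    states = ann.leaf_states(function) if len(ann) else {}
    ann.validate_against(tree)
    order = (reduced_pruning_order(tree, ann, function) if reduced
             else tree.postorder())
    if not order:
        return None
    pos = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    parent = np.full(n, -1, dtype=np.int64)
    bevent = np.full(n, -1, dtype=np.int8)
    leafz = np.full(n, -1, dtype=np.int8)
    isleaf = np.zeros(n, dtype=np.bool_)
    for i, nid in enumerate(order):
        node = tree.nodes[nid]
        if node.parent_id is not None and node.parent_id in pos:
            parent[i] = pos[node.parent_id]
            pkind = tree.nodes[node.parent_id].kind
            bevent[i] = EV_DUPLICATION if pkind == "duplication" else EV_SPECIATION
        if node.is_leaf:
            isleaf[i] = True
            if node.label in states:
                leafz[i] = states[node.label]
    return FlatTree(parent, bevent, leafz, isleaf,
                    np.array(order, dtype=np.int64))


@dataclass
class FlatForest:
    """Several flattened trees concatenated for a single kernel pass."""

    parent: np.ndarray
    bevent: np.ndarray
    leafz: np.ndarray
    isleaf: np.ndarray
    slices: List[Tuple[int, int]]
    _buf: Optional[np.ndarray] = None

    @classmethod
    def from_trees(cls, flats: Sequence[FlatTree]) -> "FlatForest":
        if not flats:
            return cls(np.empty(0, np.int64), np.empty(0, np.int8),
                       np.empty(0, np.int8), np.empty(0, np.bool_), [])
        parts, slices, offset = [], [], 0
        for ft in flats:
            shifted = ft.parent.copy()
            shifted[shifted >= 0] += offset
            parts.append(shifted)
            slices.append((offset, offset + ft.n_nodes))
            offset += ft.n_nodes
        return cls(
            np.concatenate(parts),
            np.concatenate([ft.bevent for ft in flats]),
            np.concatenate([ft.leafz for ft in flats]),
            np.concatenate([ft.isleaf for ft in flats]),
            slices,
        )

    @property
    def n_trees(self) -> int:
        return len(self.slices)

    def loglik(self, params: ModelParameters,
               keep_partials: bool = False):
        """Total log-likelihood; optionally also (partials, per-tree ll/scale)."""
        n = self.parent.shape[0]
        if n == 0:
            return (0.0, None, None, None) if keep_partials else 0.0
        if self._buf is None or keep_partials:
            partials = np.ones((n, 2))
            if not keep_partials:
                self._buf = partials
        else:
            partials = self._buf
            partials.fill(1.0)
        trans = np.stack([params.transition_matrix("speciation"),
                          params.transition_matrix("duplication")])
        tree_ll = np.empty(self.n_trees)
        tree_scale = np.empty(self.n_trees)
        total = _forest_pass(self.parent, self.bevent, self.leafz, self.isleaf,
                             trans, params.error_matrix(), params.pi,
                             partials, tree_ll, tree_scale)
        if keep_partials:
            return float(total), partials, tree_ll, tree_scale
        return float(total)


@dataclass
class PruningCache:
    """Per-node conditional subtree probabilities retained for prediction.

    ``partials[i]`` is (L0, L1) for the i-th node of ``flat``'s post-order,
    normalized by its maximum; the discarded scale is accumulated in
    ``logscale`` so that exp(loglik) remains exactly recoverable.
    """

    flat: FlatTree
    partials: np.ndarray
    logscale: float
    loglik: float

    def partial(self, node_id: int) -> Tuple[float, float]:
        i = int(np.nonzero(self.flat.orig_ids == node_id)[0][0])
        return float(self.partials[i, 0]), float(self.partials[i, 1])


@dataclass
class AnnotatedTreeSet:
    """Sequence of (tree, annotations, function) triples sharing parameters.

    Each triple refers to a single binary function; trees annotated with
    several functions are expanded to one triple per function.
    """

    triples: List[Tuple[PhyloTree, AnnotationSet, str]] = field(default_factory=list)
    tree_ids: List[str] = field(default_factory=list)
    _forest: Optional[FlatForest] = None

    def add(self, tree: PhyloTree, ann: AnnotationSet,
            function: Optional[str] = None, tree_id: Optional[str] = None) -> None:
        funcs = ann.functions
        if function is None and len(funcs) > 1:
            for f in funcs:
                self.add(tree, ann.restrict(f), f, tree_id)
            return
        function = function or (funcs[0] if funcs else "fn")
        self.triples.append((tree, ann.restrict(function) if funcs else ann, function))
        self.tree_ids.append(tree_id or f"t{len(self.triples) - 1}")
        self._forest = None

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)

    def forest(self) -> FlatForest:
        """Reduced flattened forest, built once and cached."""
        if self._forest is None:
            flats = []
            for tree, ann, function in self.triples:
                ft = flatten_tree(tree, ann, function, reduced=True)
                if ft is not None:
                    flats.append(ft)
            self._forest = FlatForest.from_trees(flats)
        return self._forest


def prune(tree: PhyloTree, ann: AnnotationSet, params: ModelParameters,
          function: Optional[str] = None,
          reduced: bool = True) -> Tuple[float, Optional[PruningCache]]:
    """Log-likelihood of one annotated tree plus the pruning cache.

    With no annotated leaf the log-likelihood is 0 by convention (the
    observation set is empty) and the cache is None — unless
    ``reduced=False``, in which case partials are computed for every node
    (unannotated leaves contribute a unit factor), as prediction needs.
    """
    flat = flatten_tree(tree, ann, function, reduced=reduced)
    if flat is None:
        return 0.0, None
    forest = FlatForest.from_trees([flat])
    total, partials, tree_ll, tree_scale = forest.loglik(params, keep_partials=True)
    cache = PruningCache(flat, partials, float(tree_scale[0]), float(tree_ll[0]))
    return float(tree_ll[0]), cache


def pooled_loglik(data: AnnotatedTreeSet, params: ModelParameters) -> float:
    """Sum of pruning log-likelihoods over all triples, shared parameters."""
    if len(data) == 0:
        return 0.0
    return data.forest().loglik(params)


def brute_force_loglik(tree: PhyloTree, ann: AnnotationSet,
                       params: ModelParameters,
                       function: Optional[str] = None) -> float:
    """Exact log-likelihood by summation over all 2^|N| state assignments.

    Independent test oracle for :func:`prune`; refuses trees with more
    than 12 nodes.
    """
    if tree.n_nodes > 12:
        raise TreeSizeError(f"{tree.n_nodes} nodes exceeds the enumeration limit of 12")
    states = ann.leaf_states(function) if len(ann) else {}
    err = params.error_matrix()
    total = 0.0
    root_id = tree.root.id
    for assign in itertools.product((0, 1), repeat=tree.n_nodes):
        p = params.pi if assign[root_id] == 1 else 1.0 - params.pi
        for node in tree.nodes:
            if node.parent_id is not None:
                ev = tree.nodes[node.parent_id].kind
                p *= params.transition_matrix(ev)[assign[node.parent_id], assign[node.id]]
            if node.is_leaf and node.label in states:
                p *= err[assign[node.id], states[node.label]]
        total += p
    return math.log(total) if total > 0.0 else -np.inf
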