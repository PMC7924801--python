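"""Reading and writing trees, event classes, annotations, and predictions.

Gene trees are rooted Newick, optionally carrying NHX ``D=Y``/``D=N`` tags
marking internal nodes as duplication or speciation events (the two event
classes of a reconciled gene tree).  Leaf annotations are sparse binary
states in a TSV.  The module also computes the *reduced pruning order*: the
post-order traversal restricted to nodes with at least one annotated
descendant, which is all the likelihood ever touches.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEAF = "leaf"
DUPLICATION = "duplication"
SPECIATION = "speciation"

_EVENT_NAMES = (DUPLICATION, SPECIATION)


class TreeParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class EventConflictError(ValueError):
    """Raised when an NHX tag and an event table disagree for the same node."""


class AnnotationConflictError(ValueError):
    """Raised when duplicate (leaf, function) rows carry different states."""


@dataclass
class Node:
    """A single node record of a :class:`PhyloTree`."""

    id: int
    label: str
    parent_id: Optional[int]
    offspring_ids: List[int] = field(default_factory=list)
    kind: str = LEAF

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEAF


class PhyloTree:
    """Rooted gene tree with a duplication/speciation class per internal node.

    Node ids are consecutive 0-based integers assigned in post-order (the
    root is always the last id).  Leaves are identified by their Newick
    label; unlabeled internal nodes receive a deterministic generated label
    ``_<id>``.  Polytomies are permitted.
    """

    def __init__(self, nodes: Sequence[Node]):
        self.nodes: List[Node] = list(nodes)
        self._validate()
        self._by_label: Dict[str, Node] = {n.label: n for n in self.nodes}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_parents(
        cls,
        parent_ids: Sequence[Optional[int]],
        kinds: Sequence[str],
        labels: Optional[Sequence[Optional[str]]] = None,
    ) -> "PhyloTree":
        """Build a tree from parallel arrays of parent ids and node kinds."""
        n = len(parent_ids)
        if labels is None:
            labels = [None] * n
        offspring: List[List[int]] = [[] for _ in range(n)]
        for i, p in enumerate(parent_ids):
            if p is not None:
                offspring[p].append(i)
        nodes = []
        for i in range(n):
            lab = labels[i] if labels[i] is not None else f"_{i}"
            nodes.append(Node(i, lab, parent_ids[i], offspring[i], kinds[i]))
        return cls(nodes)

    def _validate(self) -> None:
        roots = [n for n in self.nodes if n.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        seen = set()
        for n in self.nodes:
            if n.kind not in (LEAF,) + _EVENT_NAMES:
                raise ValueError(f"unknown node kind {n.kind!r}")
            if n.kind == LEAF and n.offspring_ids:
                raise ValueError(f"leaf node {n.label!r} has offspring")
            if n.kind != LEAF and not n.offspring_ids and len(self.nodes) > 1:
                raise ValueError(f"internal node {n.label!r} has no offspring")
            for c in n.offspring_ids:
                if self.nodes[c].parent_id != n.id:
                    raise ValueError("inconsistent parent/offspring links")
                if c in seen:
                    raise ValueError("node has two parents")
                seen.add(c)
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicated node labels: {dupes}")

    # -- queries --------------------------------------------------------------

    @property
    def root(self) -> Node:
        return next(n for n in self.nodes if n.parent_id is None)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> List[Node]:
        return [n for n in self.nodes if n.is_leaf]

    def node_by_label(self, label: str) -> Node:
        return self._by_label[label]

    def postorder(self) -> List[int]:
        """Full post-order over node ids (iterative, polytomy-safe)."""
        order: List[int] = []
        stack: List[Tuple[int, bool]] = [(self.root.id, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                order.append(nid)
            else:
                stack.append((nid, True))
                for c in reversed(self.nodes[nid].offspring_ids):
                    stack.append((c, False))
        return order

    def preorder(self) -> List[int]:
        order: List[int] = []
        stack = [self.root.id]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].offspring_ids))
        return order

    def duplication_fraction(self) -> float:
        """Observed proportion of duplication nodes among internal nodes."""
        internal = [n for n in self.nodes if not n.is_leaf]
        if not internal:
            raise ValueError("tree has no internal nodes")
        return sum(n.kind == DUPLICATION for n in internal) / len(internal)

    def to_newick(self) -> str:
        """Serialize topology, labels and NHX event tags."""

        def rec(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_leaf:
                return node.label
            inner = ",".join(rec(c) for c in node.offspring_ids)
            tag = "[&&NHX:D=Y]" if node.kind == DUPLICATION else "[&&NHX:D=N]"
            lab = "" if node.label.startswith("_") else node.label
            return f"({inner}){lab}{tag}"

        return rec(self.root.id) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<PhyloTree {len(self.leaves)} leaves, {self.n_nodes} nodes>"


class AnnotationSet:
    """Sparse observed binary states at leaves, keyed by (leaf, function).

    A leaf absent from the map is unannotated: missingness is represented by
    absence, never by a sentinel state.
    """

    def __init__(self, entries: Optional[Mapping[Tuple[str, str], int]] = None):
        self.entries: Dict[Tuple[str, str], int] = {}
        if entries:
            for key, state in entries.items():
                self[key] = state

    def __setitem__(self, key: Tuple[str, str], state: int) -> None:
        if state not in (0, 1):
            raise ValueError(f"state must be 0 or 1, got {state!r}")
        self.entries[(str(key[0]), str(key[1]))] = int(state)

    def __getitem__(self, key: Tuple[str, str]) -> int:
        return self.entries[key]

    def __contains__(self, key: Tuple[str, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    @property
    def functions(self) -> List[str]:
        return sorted({f for (_, f) in self.entries})

    def leaf_states(self, function: Optional[str] = None) -> Dict[str, int]:
        """Map leaf label -> state for one function.

        When the set holds a single function, ``function`` may be omitted.
        """
        funcs = self.functions
        if function is None:
            if len(funcs) > 1:
                raise ValueError(
                    f"annotation set has multiple functions {funcs}; specify one"
                )
            function = funcs[0] if funcs else None
        return {l: s for (l, f), s in self.entries.items() if f == function}

    def restrict(self, function: str) -> "AnnotationSet":
        return AnnotationSet(
            {(l, f): s for (l, f), s in self.entries.items() if f == function}
        )

    def without(self, leaf: str, function: str) -> "AnnotationSet":
        """Copy with one (leaf, function) entry removed (leave-one-out)."""
        out = AnnotationSet(self.entries)
        out.entries.pop((leaf, function), None)
        return out

    def validate_against(self, tree: PhyloTree) -> None:
        leaf_labels = {n.label for n in tree.leaves}
        for (leaf, func) in self.entries:
            if leaf not in leaf_labels:
                raise ValueError(
                    f"annotated leaf {leaf!r} (function {func!r}) is not a leaf of the tree"
                )


def _event_from_nhx(node: dendropy.Node) -> Optional[str]:
    for ann in node.annotations:
        if ann.name == "D":
            val = str(ann.value).strip().upper()
            if val in ("Y", "T", "TRUE", "1"):
                return DUPLICATION
            if val in ("N", "F", "FALSE", "0"):
                return SPECIATION
            raise TreeParseError(f"unrecognized NHX D tag value {ann.value!r}")
    return None


def read_tree(
    newick_text: str,
    events: Optional[Mapping[str, str]] = None,
) -> PhyloTree:
    """Parse a rooted Newick string into a :class:`PhyloTree`.

    Event classes come from NHX ``D=Y``/``D=N`` tags or from the ``events``
    table (node label -> 'duplication'/'speciation'), but not both for the
    same node.  Internal nodes with no event information default to
    speciation — the majority class in reconciled gene trees — with a
    logged warning.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            extract_comment_metadata=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc

    events = {str(k): v for k, v in (events or {}).items()}
    for v in events.values():
        if v not in _EVENT_NAMES:
            raise ValueError(f"unknown event class {v!r} in events table")

    # Assign 0-based post-order ids; root last.
    dnodes = list(dtree.postorder_node_iter())
    index = {id(dn): i for i, dn in enumerate(dnodes)}

    parent_ids: List[Optional[int]] = []
    kinds: List[str] = []
    labels: List[Optional[str]] = []
    defaulted: List[str] = []
    for i, dn in enumerate(dnodes):
        parent_ids.append(index[id(dn.parent_node)] if dn.parent_node else None)
        label = dn.taxon.label if dn.taxon is not None else dn.label
        labels.append(label)
        if dn.is_leaf():
            kinds.append(LEAF)
            continue
        nhx = _event_from_nhx(dn)
        table = events.get(label) if label is not None else None
        if nhx is not None and table is not None and nhx != table:
            raise EventConflictError(
                f"node {label!r}: NHX tag says {nhx}, events table says {table}"
            )
        kind = nhx or table
        if kind is None:
            kind = SPECIATION
            defaulted.append(label or f"_{i}")
        kinds.append(kind)
    if defaulted:
        logger.warning(
            "no event class for %d internal node(s) (%s%s); defaulting to speciation",
            len(defaulted),
            ", ".join(defaulted[:5]),
            ", ..." if len(defaulted) > 5 else "",
        )
    return PhyloTree.from_parents(parent_ids, kinds, labels)


def read_trees(newick_text: str, events: Optional[Mapping[str, Mapping[str, str]]] = None
               ) -> Dict[str, PhyloTree]:
    """Read one tree per non-empty line; keys are root labels or ``t<i>``."""
    out: Dict[str, PhyloTree] = {}
    for i, line in enumerate(l for l in newick_text.splitlines() if l.strip()):
        tree = read_tree(line, (events or {}).get(f"t{i}"))
        root_label = tree.root.label
        tree_id = root_label if not root_label.startswith("_") else f"t{i}"
        out[tree_id] = tree
    return out


def read_events_table(tsv_text: str) -> Dict[str, str]:
    """Node-events TSV with columns ``node`` and ``event``."""
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str)
    missing = {"node", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    bad = set(df["event"]) - set(_EVENT_NAMES)
    if bad:
        raise ValueError(f"unknown event classes: {sorted(bad)}")
    return dict(zip(df["node"], df["event"]))


def read_annotations(tsv_text: str) -> Dict[str, AnnotationSet]:
    """Parse an annotations TSV (columns tree, leaf, function, state).

    Returns one :class:`AnnotationSet` per tree id.  Duplicate
    (tree, leaf, function) rows with the same state are deduplicated with a
    warning; conflicting states raise :class:`AnnotationConflictError`.
    """
    df = pd.read_csv(
        io.StringIO(tsv_text), sep="\t",
        dtype={"tree": str, "leaf": str, "function": str},
    )
    missing = {"tree", "leaf", "function", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"annotations TSV missing columns: {sorted(missing)}")
    if len(df) == 0:
        return {}
    if not df["state"].isin([0, 1]).all():
        bad = df.loc[~df["state"].isin([0, 1])]
        raise ValueError(f"states outside {{0,1}} in rows: {bad.index.tolist()}")

    grouped = df.groupby(["tree", "leaf", "function"])["state"].agg(["nunique", "count", "first"])
    conflicts = grouped[grouped["nunique"] > 1]
    if len(conflicts):
        raise AnnotationConflictError(
            "conflicting annotation states for: "
            + ", ".join(map(str, conflicts.index.tolist()))
        )
    dupes = grouped[grouped["count"] > 1]
    if len(dupes):
        warnings.warn(
            f"deduplicated {len(dupes)} repeated annotation row(s)", stacklevel=2
        )

    out: Dict[str, AnnotationSet] = {}
    for (tree, leaf, func), row in grouped.iterrows():
        out.setdefault(tree, AnnotationSet())[(leaf, func)] = int(row["first"])
    return out


def annotations_to_tsv(ann_by_tree: Mapping[str, AnnotationSet]) -> str:
    rows = [
        {"tree": t, "leaf": l, "function": f, "state": s}
        for t, ann in ann_by_tree.items()
        for (l, f), s in ann
    ]
    df = pd.DataFrame(rows, columns=["tree", "leaf", "function", "state"])
    return df.to_csv(sep="\t", index=False)


def reduced_pruning_order(tree: PhyloTree, ann: AnnotationSet,
                          function: Optional[str] = None) -> List[int]:
    """Post-order node ids over the induced annotated subtree.

    A node is retained iff it is an annotated leaf or has at least one
    retained descendant; unannotated subtrees never contribute to the
    likelihood and are skipped.  Empty iff no leaf is annotated.
    """
    states = ann.leaf_states(function) if len(ann) else {}
    retained = np.zeros(tree.n_nodes, dtype=bool)
    full = tree.postorder()
    for nid in full:
        node = tree.nodes[nid]
        if node.is_leaf:
            retained[nid] = node.label in states
        else:
            retained[nid] = any(retained[c] for c in node.offspring_ids)
    return [nid for nid in full if retained[nid]]


def write_predictions(table: pd.DataFrame, path: str) -> None:
    """Write a predictions table as TSV.

    Expected columns: tree, node, function, posterior_prob and optionally
    ci_low, ci_high, loo.  Probabilities are printed with 8 significant
    digits; absent credible-interval bounds are left blank.
    """
    cols = ["tree", "node", "function", "posterior_prob", "ci_low", "ci_high"]
    out = table.copy()
    for c in ("ci_low", "ci_high"):
        if c not in out.columns:
            out[c] = np.nan
    extra = [c for c in out.columns if c not in cols]
    out[cols + extra].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_predictions(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tree": str, "node": str, "function": str})
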