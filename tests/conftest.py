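import numpy as np
import pytest

from phylofunc import AnnotationSet, ModelParameters, read_tree, simulate_tree


@pytest.fixture
def toy_tree():
    """((A,B)n1,(C,D)n2)r with a duplication at the root."""
    return read_tree(
        "((A,B)n1,(C,D)n2)r;",
        events={"n1": "speciation", "n2": "speciation", "r": "duplication"},
    )


@pytest.fixture
def two_leaf_tree():
    return read_tree("(A,B)r;", events={"r": "speciation"})


def random_instance(seed, max_leaves=6, p_annot=0.7):
    """A small random (tree, annotations, parameters) triple for oracle tests."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(2, max_leaves))
    tree = simulate_tree(n_leaves, p_dup=0.3, seed=int(rng.integers(2**31)))
    params = ModelParameters.from_array(rng.uniform(0.05, 0.95, 7))
    ann = AnnotationSet()
    for leaf in tree.leaves:
        if rng.random() < p_annot:
            ann[(leaf.label, "f")] = int(rng.random() < 0.5)
    return tree, ann, params


@pytest.fixture
def chain_tree_factory():
    """Linear chains of k speciation nodes ending in one leaf."""

    def make(k, kind="speciation"):
        from phylofunc.treeio import PhyloTree

        # ids in post-order: leaf=0, then internals up to root=k
        parents = [1] + [i + 1 for i in range(1, k)] + [None]
        kinds = ["leaf"] + [kind] * k
        return PhyloTree.from_parents(parents, kinds)

    return make
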