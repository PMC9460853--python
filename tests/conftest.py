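import io

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def reference_table():
    from fennelpop.distances import load_reference_table

    return load_reference_table()


@pytest.fixture(scope="session")
def reference_report():
    from fennelpop.pipeline import run_reference

    return run_reference()


def random_additive_tree(rng, n_leaves):
    """A random binary unrooted tree with positive branch lengths.

    Grown by attaching each new leaf to the midpoint of a random edge, so
    the tip-to-tip matrix is exactly additive on the returned tree.
    """
    from skbio import TreeNode

    lengths = rng.uniform(0.1, 1.0, size=3)
    tree = TreeNode.read(
        io.StringIO(f"(t0:{lengths[0]},t1:{lengths[1]},t2:{lengths[2]});")
    )
    for k in range(3, n_leaves):
        edges = list(tree.traverse(include_self=False))
        edge = edges[rng.integers(len(edges))]
        parent = edge.parent
        split = TreeNode(length=float(edge.length) / 2)
        edge.length = float(edge.length) / 2
        leaf = TreeNode(name=f"t{k}", length=float(rng.uniform(0.1, 1.0)))
        parent.remove(edge)
        parent.append(split)
        split.append(edge)
        split.append(leaf)
    return tree


@pytest.fixture
def make_additive_tree():
    return random_additive_tree
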