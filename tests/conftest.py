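import numpy as np
import pytest

from paleorates.tree import Phylogeny, read_newick


def random_binary_tree(rng: np.random.Generator, n_tips: int,
                       min_len: float = 0.1, max_len: float = 5.0) -> Phylogeny:
    """Random binary topology by sequential joins, random edge durations."""
    parent = {0: -1}
    children = {0: []}
    lengths = {0: np.nan}
    next_id = 1
    leaves = [0]
    while len(leaves) < n_tips:
        leaf = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            parent[next_id] = leaf
            children[leaf] = children.get(leaf, []) + [next_id]
            children[next_id] = []
            lengths[next_id] = float(rng.uniform(min_len, max_len))
            leaves.append(next_id)
            next_id += 1
    # re-index preorder
    order, stack = [], [0]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(reversed(children.get(v, [])))
    remap = {old: new for new, old in enumerate(order)}
    n = len(order)
    p = np.empty(n, dtype=np.int64)
    e = np.empty(n)
    labels = {}
    t = 0
    for old in order:
        new = remap[old]
        p[new] = -1 if parent[old] == -1 else remap[parent[old]]
        e[new] = lengths[old]
        if not children.get(old):
            t += 1
            labels[new] = f"t{t}"
    e[0] = np.nan
    return Phylogeny(p, e, labels, root_age=100.0)


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);", root_age=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20140223)


@pytest.fixture(scope="session")
def scenario71():
    from paleorates.synthetic import make_scenario

    return make_scenario("study71", seed=42)
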