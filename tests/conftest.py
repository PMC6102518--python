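import numpy as np
import pytest

from sympatree import (
    AgeTable,
    ScenarioConfig,
    calibrate_bladj,
    cophenetic,
    parse_newick,
    simulate_tree_and_ranges,
)


@pytest.fixture(scope="session")
def four_tip_tree():
    """((A,B),(C,D)) with root at 3 Myr and both cherries at 1 Myr.

    Cophenetic distances: cherry partners 2, everything else 6.
    """
    tree = parse_newick("((A,B)x,(C,D)y)r;")
    return calibrate_bladj(tree, AgeTable({"r": 3.0, "x": 1.0, "y": 1.0}))


@pytest.fixture(scope="session")
def four_tip_D(four_tip_tree):
    return cophenetic(four_tip_tree)


def random_calibrated_tree(rng, n_tips, root_age=100.0, max_children=2):
    """Independent random ultrametric tree builder used as a test substrate.

    Grows a topology by repeatedly splitting a random tip into 2..max_children
    children, then assigns each interior node an age strictly between its
    parent's age and its oldest child's age by stick-breaking from the root.
    """
    from sympatree.trees import Node, Tree

    root = Node("r")
    tips = [root]
    while len(tips) < n_tips:
        node = tips.pop(rng.integers(len(tips)))
        k = int(rng.integers(2, max_children + 1))
        k = min(k, n_tips - len(tips) + 1)
        for _ in range(k):
            tips.append(node.add_child(Node()))
    tree = Tree(root)
    for i, tip in enumerate(tree.tips()):
        tip.name = f"t{i}"
        tip.age = 0.0
    counter = 0
    for node in tree.preorder():
        if node.is_tip:
            continue
        counter += 1
        node.name = f"i{counter}"
        node.fixed = True
        if node.parent is None:
            node.age = root_age
        else:
            node.age = node.parent.age * (0.5 + 0.45 * rng.random())
    tree.set_lengths_from_ages()
    return tree


def brute_force_path_distance(tree, a, b):
    """Path-sum oracle: total branch length between two named tips."""
    nodes = {n.name: n for n in tree.preorder() if n.name}
    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out
    pa = ancestors(nodes[a])
    pb = ancestors(nodes[b])
    ids_b = {id(n): i for i, n in enumerate(pb)}
    for i, n in enumerate(pa):
        if id(n) in ids_b:
            lca = n
            da = sum(x.length for x in pa[:i])
            db = sum(x.length for x in pb[: ids_b[id(n)]])
            return da + db
    raise AssertionError("no common ancestor")


@pytest.fixture(scope="session")
def small_sympatric_dataset():
    """One compact sympatric landscape reused across tests (3 x 4 communities)."""
    config = ScenarioConfig(
        mode="sympatric",
        seed=20240917,
        n_regions=3,
        communities_per_region=4,
        n_founders=9,
        n_speciation=91,
        dispersal_scale_km=40.0,
    )
    return simulate_tree_and_ranges(config)
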