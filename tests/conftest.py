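import numpy as np
import pytest

from polysuper.tree import Node, RootedTree


def random_binary_tree(labels, rng, with_lengths=False, scale=1.0) -> RootedTree:
    """Random rooted binary topology by repeated random joins."""
    nodes = [Node(lab, rng.uniform(0.1, 1.0) * scale if with_lengths else None)
             for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node(None, rng.uniform(0.1, 1.0) * scale if with_lengths else None)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    nodes[0].length = None
    return RootedTree(nodes[0])


def relabel(tree: RootedTree, mapping: dict) -> RootedTree:
    def rec(node):
        new = Node(mapping.get(node.label, node.label) if node.label else None, node.length)
        for c in node.children:
            new.add_child(rec(c))
        return new

    return RootedTree(rec(tree.root))


def enumerate_rooted_binary(labels) -> list[RootedTree]:
    """All rooted binary topologies on the given labels ((2n-3)!! of them)."""
    labels = list(labels)

    def clone(node):
        new = Node(node.label)
        for c in node.children:
            new.add_child(clone(c))
        return new

    def grow(trees, label):
        out = []
        for root in trees:
            # insert above every node (including the root)
            nodes = []
            stack = [root]
            while stack:
                v = stack.pop()
                nodes.append(v)
                stack.extend(v.children)
            for i in range(len(nodes)):
                new_root = clone(root)
                flat = []
                stack = [new_root]
                while stack:
                    v = stack.pop()
                    flat.append(v)
                    stack.extend(v.children)
                target = flat[i]
                joint = Node()
                parent = target.parent
                joint.add_child(target)
                joint.add_child(Node(label))
                if parent is None:
                    out.append(joint)
                else:
                    parent.children[parent.children.index(target)] = joint
                    joint.parent = parent
                    out.append(new_root)
        return out

    forest = [Node(labels[0])]
    for lab in labels[1:]:
        forest = grow(forest, lab)
    return [RootedTree(r) for r in forest]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
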