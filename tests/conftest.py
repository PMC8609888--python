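"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pytest

from tollscan.phylo import leaf_labels, read_tree


@pytest.fixture
def species_tree():
    from tollscan.scenario import load_species_tree

    return load_species_tree()


@pytest.fixture
def presence_fixture():
    from tollscan.scenario import load_presence_fixture

    return load_presence_fixture()


# ---------------------------------------------------------------------------
# random rooted binary trees for oracle tests

def random_binary_tree(n_leaves: int, rng: np.random.Generator):
    """Random rooted binary tree newick with named internals and unit-ish
    branch lengths; returns (dendropy tree, newick string)."""
    counter = itertools.count()

    def name():
        return f"n{next(counter)}"

    subtrees = [f"t{i}:{rng.uniform(0.5, 2.0):.3f}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        merged = f"({a},{b}){name()}:{rng.uniform(0.5, 2.0):.3f}"
        subtrees.append(merged)
    newick = subtrees[0].rsplit(":", 1)[0] + ";"
    tree = read_tree(newick, is_path=False)
    tree.is_rooted = True
    return tree, newick


# ---------------------------------------------------------------------------
# brute-force Dollo oracle

def brute_force_min_losses(tree, column: dict[str, bool], forced_gain=None) -> int:
    """Exhaustive minimum loss count over all single-gain + loss-edge-subset
    placements reproducing the leaf states. Independent of the package's
    reconstruction: subsets are enumerated in ascending size until feasible."""
    nodes = list(tree.preorder_node_iter())
    present = {t for t, v in column.items() if v}
    assert present, "oracle needs at least one presence leaf"

    def nname(node):
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    best = None
    for gain in nodes:
        if gain.is_leaf():
            if leaf_labels(gain) != frozenset(present):
                continue
        if not (present <= leaf_labels(gain)):
            continue
        if forced_gain is not None and nname(gain) != forced_gain:
            continue
        below = [n for n in gain.preorder_iter() if n is not gain]
        edge_idx = {id(n): k for k, n in enumerate(below)}
        paths = {}  # leaf label -> bitmask of edges from gain to leaf
        for leaf in gain.leaf_iter():
            mask = 0
            node = leaf
            while node is not gain:
                mask |= 1 << edge_idx[id(node)]
                node = node.parent_node
            paths[leaf.taxon.label] = mask
        absent_below = [t for t in paths if t in column and not column[t]]
        present_below = [t for t in paths if column.get(t)]

        found = None
        for k in range(len(below) + 1):
            if best is not None and k >= best:
                break
            for combo in itertools.combinations(range(len(below)), k):
                cut = 0
                for c in combo:
                    cut |= 1 << c
                if any(paths[t] & cut for t in present_below):
                    continue
                if all(paths[t] & cut for t in absent_below):
                    found = k
                    break
            if found is not None:
                break
        if found is not None and (best is None or found < best):
            best = found
    assert best is not None, "no feasible gain placement"
    return best


# ---------------------------------------------------------------------------
# brute-force similarity oracle (max identical aligned pairs = LCS)

def brute_force_max_matches(a: str, b: str) -> int:
    """Enumerate all global alignments recursively; max identical pairs."""
    if not a or not b:
        return 0
    options = [
        brute_force_max_matches(a[1:], b[1:]) + (a[0] == b[0]),
        brute_force_max_matches(a[1:], b),
        brute_force_max_matches(a, b[1:]),
    ]
    return max(options)


# ---------------------------------------------------------------------------
# brute-force single-linkage clustering oracle

def brute_force_collapse(records, threshold: float):
    """Transitive closure over >threshold identity within species; returns the
    set of kept representative ids under the longest-then-lexicographic rule."""
    from tollscan.receptor_survey import pairwise_identity

    kept = set()
    by_species: dict[str, list] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    for group in by_species.values():
        edges = {
            (a.id, b.id)
            for a in group for b in group
            if a.id != b.id and pairwise_identity(a, b) > threshold
        }
        clusters = [{r.id} for r in group]
        changed = True
        while changed:
            changed = False
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    if any((x, y) in edges for x in clusters[i] for y in clusters[j]):
                        clusters[i] |= clusters[j]
                        del clusters[j]
                        changed = True
                        break
                if changed:
                    break
        by_id = {r.id: r for r in group}
        for cluster in clusters:
            rep = min(cluster, key=lambda x: (-len(by_id[x].residues), x))
            kept.add(rep)
    return kept
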