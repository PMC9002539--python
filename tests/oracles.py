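"""Independent brute-force oracles used by the test suite.

Deliberately naive and built on a different tree library (dendropy) and
different code paths than the package: per-branch enumeration for UniFrac
and Faith's PD, explicit double loops for PERMANOVA sums of squares, and
full label-permutation enumeration for exact p-values.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np


def branch_leaf_sets(newick: str) -> list[tuple[float, frozenset]]:
    """(length, descendant tip labels) for every non-root branch."""
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        out.append((float(length), leaves))
    return out


def faith_pd_oracle(newick: str, present: set) -> float:
    """Sum of branch lengths on any root-to-present-tip path."""
    return sum(l for l, leaves in branch_leaf_sets(newick) if leaves & present)


def unweighted_unifrac_oracle(newick: str, set_a: set, set_b: set) -> float:
    unique = shared = 0.0
    for l, leaves in branch_leaf_sets(newick):
        in_a, in_b = bool(leaves & set_a), bool(leaves & set_b)
        if in_a and in_b:
            shared += l
        elif in_a or in_b:
            unique += l
    total = unique + shared
    return 0.0 if total == 0 else unique / total


def weighted_unifrac_oracle(
    newick: str, counts_a: dict, counts_b: dict, normalized: bool = False
) -> float:
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for l, leaves in branch_leaf_sets(newick):
        pa = sum(counts_a.get(t, 0) for t in leaves) / ta
        pb = sum(counts_b.get(t, 0) for t in leaves) / tb
        num += l * abs(pa - pb)
        den += l * (pa + pb)
    if not normalized:
        return num
    return 0.0 if den == 0 else num / den


def permanova_f_oracle(d: np.ndarray, labels: list) -> float:
    """Pseudo-F from explicit pair loops (no shared code with the package)."""
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d[idx[a], idx[b]] ** 2
        ss_within += s / len(idx)
    k = len(set(labels))
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def permanova_exact_p_oracle(d: np.ndarray, labels: list) -> float:
    """Exact p by enumerating every permutation of the label vector."""
    f_obs = permanova_f_oracle(d, labels)
    hits = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        if permanova_f_oracle(d, list(perm)) >= f_obs - 1e-12:
            hits += 1
    return hits / total


def random_tree_newick(rng: np.random.Generator, n_tips: int, prefix: str = "T") -> str:
    """Random bifurcating newick with uniform(0.1, 2) branch lengths."""
    frags = [f"{prefix}{i}" for i in range(1, n_tips + 1)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        li, lj = rng.uniform(0.1, 2.0, size=2)
        merged = f"({frags[i]}:{li:.6f},{frags[j]}:{lj:.6f})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
    return frags[0] + ";"
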