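"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration or via a
third-party implementation, never by calling the code path it checks.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def sw_score_exhaustive(query: str, subject: str, sub_score,
                        gap_open: int, gap_extend: int) -> float:
    """Optimal local alignment score by exhaustive path search.

    Explores every alignment path (match / query-gap / subject-gap
    moves with affine costs, free start and stop anywhere), memoized on
    (position, gap state).  Practical for sequences of length <= ~10.
    """
    n, m = len(query), len(subject)

    @lru_cache(maxsize=None)
    def best_from(i: int, j: int, state: str) -> float:
        options = [0.0]  # stopping here is always allowed
        if i < n and j < m:
            options.append(sub_score(query[i], subject[j])
                           + best_from(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if state == "Q" else gap_open
            options.append(-cost + best_from(i + 1, j, "Q"))
        if j < m:
            cost = gap_extend if state == "S" else gap_open
            options.append(-cost + best_from(i, j + 1, "S"))
        return max(options)

    return max(best_from(i, j, "M")
               for i in range(n + 1) for j in range(m + 1))


def blosum62_scorer():
    """Pair scorer on BLOSUM62 with 'X' scoring 0 (matches the gate)."""
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load("BLOSUM62")

    def score(a: str, b: str) -> float:
        if a == "X" or b == "X":
            return 0.0
        return float(mat[a, b])

    return score


# ---------------------------------------------------------------------------
# Clade extraction / partition by brute force over all internal nodes


def _leafset(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def bruteforce_family(tree, refs: set, classify, min_class):
    """(leaf set, supported flag) of the family clade by enumeration.

    Enumerates every internal node; candidates contain all refs and
    have branch class >= min_class (root branch counts as unsupported).
    Largest leaf set wins; ties go to the smallest depth.
    """
    candidates = []
    depths = {}
    stack = [(tree.seed_node, 0)]
    while stack:
        node, d = stack.pop()
        depths[id(node)] = d
        for ch in node.child_nodes():
            stack.append((ch, d + 1))
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = _leafset(node)
        if not refs <= leaves:
            continue
        if node.parent_node is None:
            cls = classify(None, None)
        else:
            cls = classify(node.alrt, node.ufboot)
        if cls >= min_class:
            candidates.append((len(leaves), -depths[id(node)], leaves))
    if not candidates:
        mrca = tree.mrca(taxon_labels=sorted(refs))
        return _leafset(mrca), False
    candidates.sort(reverse=True)
    return candidates[0][2], True


def bruteforce_subfamilies(tree, family_leaves: frozenset, classify,
                           min_class) -> list[frozenset]:
    """Maximal supported proper sub-clades of the family, by set logic.

    Collects every internal node strictly inside the family whose
    branch class >= min_class and leaf count >= 2, then keeps the
    set-maximal ones (none contained in another kept one).
    """
    supported = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = _leafset(node)
        if leaves == family_leaves or not leaves < family_leaves:
            continue
        if classify(node.alrt, node.ufboot) >= min_class \
                and len(leaves) >= 2:
            supported.append(leaves)
    maximal = [s for s in supported
               if not any(s < t for t in supported)]
    # Deduplicate identical leaf sets (unary paths cannot occur in
    # binary trees, but be safe) and order by smallest leaf.
    uniq = sorted(set(maximal), key=min)
    return uniq


# ---------------------------------------------------------------------------
# Ward clustering ESS oracle


def ess(points: np.ndarray) -> float:
    """Within-cluster error sum of squares."""
    centroid = points.mean(axis=0)
    return float(((points - centroid) ** 2).sum())


def ward_merge_heights(X: np.ndarray) -> list[float]:
    """Greedy Ward merge heights by direct ESS computation.

    At each step merges the pair of clusters with the smallest increase
    in total ESS; reports sqrt(2 * increase), the Euclidean-scale height
    convention.
    """
    clusters: list[list[int]] = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                merged = clusters[a] + clusters[b]
                delta = ess(X[merged]) - ess(X[clusters[a]]) \
                    - ess(X[clusters[b]])
                if best is None or delta < best[0]:
                    best = (delta, a, b)
        delta, a, b = best
        heights.append((2.0 * delta) ** 0.5)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights
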