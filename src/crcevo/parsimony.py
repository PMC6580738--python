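"""Maximum-parsimony machinery shared by the SNA and CNA tree builders.

Unrooted topologies over n taxa are represented as rooted binary nested
tuples over taxa 1..n-1, with taxon 0 (the outgroup: germline for SNA
trees, the synthetic diploid for CNA trees) implicitly attached at the
top join.  For small problems (<= ``exhaustive_limit`` non-outgroup
taxa) every topology is enumerated — (2m-3)!! trees for m taxa — and
the minimum-score tree is returned; larger problems use stepwise
addition from random taxon orders followed by nearest-neighbour-
interchange hill climbing.  Among equally parsimonious trees the one
with the lexicographically smallest canonical newick is kept, which
makes every search deterministic given its seed.

Two scorers implement the small-parsimony step: Fitch counting for
unordered binary characters (mutation presence/absence) and the Sankoff
dynamic programme for ordered integer characters (binned total copy
number, cost |a - b|).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

from .tree import PhyloTree, TreeNode

Topology = Union[int, tuple]

__all__ = [
    "FitchScorer",
    "SankoffScorer",
    "enumerate_topologies",
    "nni_neighbors",
    "canonical_newick",
    "search_tree",
    "topology_splits",
    "bootstrap_splits",
]

_BIG = np.int64(1 << 40)


# ---------------------------------------------------------------------------
# Topology combinatorics
# ---------------------------------------------------------------------------


def _insertions(tree: Topology, leaf: int) -> Iterable[Topology]:
    yield (tree, leaf)
    if not isinstance(tree, int):
        left, right = tree
        for nl in _insertions(left, leaf):
            yield (nl, right)
        for nr in _insertions(right, leaf):
            yield (left, nr)


def enumerate_topologies(taxa: Sequence[int]) -> list[Topology]:
    """All rooted binary shapes over ``taxa`` (equivalently, all unrooted
    topologies once the implicit taxon 0 is attached above the root)."""
    if not taxa:
        raise ValueError("need at least one taxon")
    trees: list[Topology] = [taxa[0]]
    for t in taxa[1:]:
        trees = [nt for tr in trees for nt in _insertions(tr, t)]
    return trees


def nni_neighbors(tree: Topology) -> list[Topology]:
    """All nearest-neighbour-interchange rearrangements of ``tree``."""
    out: list[Topology] = []

    def rec(node: Topology, rebuild: Callable[[Topology], Topology]) -> None:
        if isinstance(node, int):
            return
        left, right = node
        if not isinstance(left, int):
            a, b = left
            out.append(rebuild(((a, right), b)))
            out.append(rebuild(((b, right), a)))
        if not isinstance(right, int):
            a, b = right
            out.append(rebuild(((a, left), b)))
            out.append(rebuild(((b, left), a)))
        rec(left, lambda s, right=right, rebuild=rebuild: rebuild((s, right)))
        rec(right, lambda s, left=left, rebuild=rebuild: rebuild((left, s)))

    rec(tree, lambda s: s)
    return out


def canonical_newick(tree: Topology, names: Sequence[str]) -> str:
    """Canonical (child-sorted) newick string of the shape, without
    branch lengths; used for deterministic tie-breaking."""

    def rec(node: Topology) -> str:
        if isinstance(node, int):
            return names[node]
        parts = sorted(rec(c) for c in node)
        return "(" + ",".join(parts) + ")"

    return rec(tree) + ";"


def topology_splits(tree: Topology, names: Sequence[str]) -> set[frozenset[str]]:
    """Non-trivial splits of the unrooted tree (with the implicit taxon
    0 attached at the top), as below-edge leaf-name sets."""
    n_taxa = len(names)
    out: set[frozenset[str]] = set()

    def rec(node: Topology) -> frozenset[str]:
        if isinstance(node, int):
            return frozenset([names[node]])
        below = frozenset().union(*(rec(c) for c in node))
        if 1 < len(below) < n_taxa - 1:
            out.add(below)
        return below

    rec(tree)
    return out


# ---------------------------------------------------------------------------
# Scorers
# ---------------------------------------------------------------------------


class FitchScorer:
    """Fitch small parsimony for binary characters.

    ``matrix`` is (n_taxa, n_char) in {0, 1}; row 0 is the outgroup.
    Identical columns are collapsed to unique patterns with multiplicity
    weights, so scoring cost scales with the number of distinct
    presence patterns rather than with the raw character count.  State
    sets are encoded as bitmasks (1 = {0}, 2 = {1}, 3 = {0, 1}).
    """

    def __init__(self, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2 or not np.isin(matrix, (0, 1)).all():
            raise ValueError("character matrix must be binary")
        self.n_taxa, self.n_char = matrix.shape
        uniq, inv, counts = np.unique(
            matrix, axis=1, return_inverse=True, return_counts=True)
        self._inv = inv.ravel()
        self.weights = counts.astype(np.int64)
        self.masks = (uniq.astype(np.uint8) + 1).copy()  # 0 -> 1, 1 -> 2

    def _pass(self, node: Topology, counts: np.ndarray) -> np.ndarray:
        if isinstance(node, int):
            return self.masks[node]
        ml = self._pass(node[0], counts)
        mr = self._pass(node[1], counts)
        inter = ml & mr
        empty = inter == 0
        counts += empty
        return np.where(empty, ml | mr, inter)

    def _pattern_changes(self, tree: Topology) -> np.ndarray:
        counts = np.zeros(self.masks.shape[1], dtype=np.int64)
        top = self._pass(tree, counts)
        counts += (top & self.masks[0]) == 0
        return counts

    def per_char_changes(self, tree: Topology) -> np.ndarray:
        return self._pattern_changes(tree)[self._inv]

    def score(self, tree: Topology) -> int:
        return int((self._pattern_changes(tree) * self.weights).sum())

    def min_changes(self) -> np.ndarray:
        """Lower bound per character: 1 for variable characters, else 0."""
        variable = (self.masks != self.masks[0]).any(axis=0)
        return variable.astype(np.int64)[self._inv]

    # -- most-parsimonious reconstruction ---------------------------------

    def assign_states(self, tree: Topology) -> tuple[dict, np.ndarray]:
        """One deterministic MPR: returns ({node id -> state vector},
        root state vector).  The uppass prefers the parent's state when
        the downpass set is ambiguous, which yields a valid minimum-
        change reconstruction for binary characters."""
        down: dict[int, np.ndarray] = {}

        def downpass(node: Topology) -> np.ndarray:
            if isinstance(node, int):
                mask = self.masks[node]
            else:
                ml, mr = downpass(node[0]), downpass(node[1])
                inter = ml & mr
                mask = np.where(inter == 0, ml | mr, inter)
            down[id(node)] = mask
            return mask

        top = downpass(tree)
        # Root join with the outgroup (all rows of masks[0]).
        root_mask = np.where(top & self.masks[0] != 0, top & self.masks[0], self.masks[0])
        root_state = (root_mask == 2).astype(np.int8)  # forced or outgroup-matching

        states: dict[int, np.ndarray] = {}

        def uppass(node: Topology, parent_state: np.ndarray) -> None:
            mask = down[id(node)]
            parent_bit = (parent_state.astype(np.uint8) + 1)
            keep = (mask & parent_bit) != 0
            forced = (mask == 2).astype(np.int8)
            state = np.where(keep, parent_state, forced)
            states[id(node)] = state.astype(np.int8)
            if not isinstance(node, int):
                uppass(node[0], states[id(node)])
                uppass(node[1], states[id(node)])

        uppass(tree, root_state)
        return states, root_state


class SankoffScorer:
    """Sankoff small parsimony for ordered integer characters.

    ``matrix`` is (n_taxa, n_char) of non-negative integer states; row 0
    is the reference (diploid) taxon.  ``ordered=True`` uses cost
    |a - b| between states; ``ordered=False`` costs every change 1.
    """

    def __init__(self, matrix: np.ndarray, ordered: bool = True) -> None:
        matrix = np.asarray(matrix, dtype=np.int64)
        if matrix.ndim != 2 or (matrix < 0).any():
            raise ValueError("state matrix must be non-negative integers")
        self.n_taxa, self.n_char = matrix.shape
        uniq, inv, counts = np.unique(
            matrix, axis=1, return_inverse=True, return_counts=True)
        self._inv = inv.ravel()
        self.weights = counts.astype(np.int64)
        self.states = uniq  # compressed unique column patterns
        self.k = int(matrix.max()) + 1
        s = np.arange(self.k)
        if ordered:
            self.D = np.abs(s[:, None] - s[None, :]).astype(np.int64)
        else:
            self.D = (s[:, None] != s[None, :]).astype(np.int64)
        # Leaf cost tables: 0 at the observed state, +inf-ish elsewhere.
        n_pat = uniq.shape[1]
        eye = np.full((self.n_taxa, n_pat, self.k), _BIG, dtype=np.int64)
        rows = np.arange(self.n_taxa)[:, None]
        cols = np.arange(n_pat)[None, :]
        eye[rows, cols, uniq] = 0
        self._leaf_cost = eye

    def _cost(self, node: Topology) -> np.ndarray:
        if isinstance(node, int):
            return self._leaf_cost[node]
        cl, cr = self._cost(node[0]), self._cost(node[1])
        # min over child state t of child_cost[:, t] + D[s, t]
        contrib_l = (cl[:, None, :] + self.D[None, :, :]).min(axis=2)
        contrib_r = (cr[:, None, :] + self.D[None, :, :]).min(axis=2)
        return contrib_l + contrib_r

    def _pattern_changes(self, tree: Topology) -> np.ndarray:
        cost = self._cost(tree)
        ref = self.states[0]
        total = cost + self.D[:, ref].T  # join with the reference leaf
        return total.min(axis=1)

    def per_char_changes(self, tree: Topology) -> np.ndarray:
        return self._pattern_changes(tree)[self._inv]

    def score(self, tree: Topology) -> int:
        return int((self._pattern_changes(tree) * self.weights).sum())

    def min_changes(self) -> np.ndarray:
        """Lower bound per character: range of observed states."""
        rng = (self.states.max(axis=0) - self.states.min(axis=0)).astype(np.int64)
        return rng[self._inv]

    def assign_states(self, tree: Topology) -> tuple[dict, np.ndarray]:
        """Deterministic minimum-cost state assignment.  Ties at a node
        are broken toward the parent state, then toward the lower state."""
        costs: dict[int, np.ndarray] = {}

        def downpass(node: Topology) -> np.ndarray:
            if isinstance(node, int):
                c = self._leaf_cost[node]
            else:
                cl, cr = downpass(node[0]), downpass(node[1])
                contrib_l = (cl[:, None, :] + self.D[None, :, :]).min(axis=2)
                contrib_r = (cr[:, None, :] + self.D[None, :, :]).min(axis=2)
                c = contrib_l + contrib_r
            costs[id(node)] = c
            return c

        top = downpass(tree)
        ref = self.states[0]
        states: dict[int, np.ndarray] = {}

        def pick(cost: np.ndarray, parent_state: np.ndarray) -> np.ndarray:
            # Lexicographic: minimise cost, then |s - parent|, then s.
            dist = np.abs(np.arange(self.k)[None, :] - parent_state[:, None])
            key = cost * (self.k * self.k) + dist * self.k + np.arange(self.k)[None, :]
            return key.argmin(axis=1).astype(np.int64)

        root_state = pick(top + self.D[:, ref].T, ref)

        def uppass(node: Topology, parent_state: np.ndarray) -> None:
            cost = costs[id(node)]
            total = cost + self.D.T[parent_state]  # (n_char, k): + D[s, parent]
            states[id(node)] = pick(total, parent_state)
            if not isinstance(node, int):
                uppass(node[0], states[id(node)])
                uppass(node[1], states[id(node)])

        uppass(tree, root_state)
        return states, root_state


Scorer = Union[FitchScorer, SankoffScorer]


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


def _stepwise(scorer: Scorer, order: Sequence[int]) -> Topology:
    tree: Topology = order[0]
    for leaf in order[1:]:
        best, best_score = None, None
        for cand in _insertions(tree, leaf):
            s = scorer.score(cand)
            if best_score is None or s < best_score:
                best, best_score = cand, s
        tree = best
    return tree


def _remove_leaf(tree: Topology, leaf: int) -> Optional[Topology]:
    if isinstance(tree, int):
        return None if tree == leaf else tree
    left = _remove_leaf(tree[0], leaf)
    right = _remove_leaf(tree[1], leaf)
    if left is None:
        return right
    if right is None:
        return left
    return (left, right)


def _leaves_of(tree: Topology) -> list[int]:
    if isinstance(tree, int):
        return [tree]
    return _leaves_of(tree[0]) + _leaves_of(tree[1])


def _hill_climb(scorer: Scorer, tree: Topology, names: Sequence[str]) -> tuple[Topology, int]:
    """NNI hill climbing augmented with leaf re-insertion moves (prune
    one leaf, try every attachment edge) to escape shallow local
    optima."""
    score = scorer.score(tree)
    while True:
        improved = False
        seen: set[str] = set()
        for cand in nni_neighbors(tree):
            key = canonical_newick(cand, names)
            if key in seen:
                continue
            seen.add(key)
            s = scorer.score(cand)
            if s < score:
                tree, score = cand, s
                improved = True
                break
        if improved:
            continue
        for leaf in _leaves_of(tree):
            pruned = _remove_leaf(tree, leaf)
            if pruned is None:
                continue
            for cand in _insertions(pruned, leaf):
                s = scorer.score(cand)
                if s < score:
                    tree, score = cand, s
                    improved = True
                    break
            if improved:
                break
        if not improved:
            return tree, score


def search_tree(
    scorer: Scorer,
    names: Sequence[str],
    exhaustive_limit: int = 7,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[Topology, int]:
    """Find a minimum-score topology over taxa 1..n-1 (taxon 0 is the
    implicit outgroup).  Deterministic given ``seed``: equally
    parsimonious trees are resolved to the lexicographically smallest
    canonical newick."""
    n = len(names)
    if n < 3:
        raise ValueError("need at least 3 taxa including the outgroup")
    taxa = list(range(1, n))
    best: Optional[Topology] = None
    best_score: Optional[int] = None
    best_key: Optional[str] = None

    def consider(tree: Topology, score: int) -> None:
        nonlocal best, best_score, best_key
        key = canonical_newick(tree, names)
        if best_score is None or score < best_score or (score == best_score and key < best_key):
            best, best_score, best_key = tree, score, key

    if n - 1 <= exhaustive_limit:
        for tree in enumerate_topologies(taxa):
            consider(tree, scorer.score(tree))
    else:
        rng = np.random.default_rng(seed)
        for _ in range(max(1, restarts)):
            order = [int(t) for t in rng.permutation(taxa)]
            tree = _stepwise(scorer, order)
            tree, score = _hill_climb(scorer, tree, names)
            consider(tree, score)
    return best, best_score


def bootstrap_splits(
    matrix: np.ndarray,
    names: Sequence[str],
    make_scorer: Callable[[np.ndarray], Scorer],
    b: int,
    seed: int,
    exhaustive_limit: int = 7,
    restarts: int = 5,
) -> dict[frozenset[str], float]:
    """Column-bootstrap clade support.

    Resamples characters with replacement ``b`` times, rebuilds the tree
    for each replicate, and reports for every non-trivial split the
    percentage of replicate trees containing it.  Splits never seen get
    0; the returned map covers every split observed in any replicate.
    """
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    rng = np.random.default_rng(seed)
    n_char = matrix.shape[1]
    tally: dict[frozenset[str], int] = {}
    for _ in range(b):
        cols = rng.integers(0, n_char, size=n_char)
        scorer = make_scorer(matrix[:, cols])
        tree, _ = search_tree(
            scorer, names, exhaustive_limit=exhaustive_limit,
            restarts=restarts, seed=int(rng.integers(0, 2**31 - 1)),
        )
        for split in topology_splits(tree, names):
            tally[split] = tally.get(split, 0) + 1
    return {s: 100.0 * c / b for s, c in tally.items()}


# ---------------------------------------------------------------------------
# Conversion to PhyloTree with reconstructed branch lengths
# ---------------------------------------------------------------------------


def topology_to_phylotree(
    tree: Topology,
    names: Sequence[str],
    scorer: Scorer,
) -> PhyloTree:
    """Root the searched topology at the outgroup attachment and set
    integer branch lengths from one deterministic most-parsimonious
    state reconstruction."""
    states, root_state = scorer.assign_states(tree)
    w = scorer.weights
    if isinstance(scorer, FitchScorer):
        leaf_state = {i: (scorer.masks[i] == 2).astype(np.int8) for i in range(scorer.n_taxa)}
        dist = lambda a, b: int((np.abs(a.astype(int) - b.astype(int)) * w).sum())
    else:
        leaf_state = {i: scorer.states[i] for i in range(scorer.n_taxa)}
        dist = lambda a, b: int((scorer.D[a, b] * w).sum())

    def build(node: Topology, parent_state: np.ndarray) -> TreeNode:
        state = states[id(node)]
        if isinstance(node, int):
            tn = TreeNode(name=names[node])
        else:
            tn = TreeNode(name="")
            for child in node:
                tn.add(build(child, state))
        tn.length = dist(state, parent_state)
        return tn

    root = TreeNode(name="root")
    out = TreeNode(name=names[0])
    out.length = dist(leaf_state[0], root_state)
    root.add(out)
    root.add(build(tree, root_state))
    return PhyloTree(root)
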