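"""Maximum-parsimony phylogenies from multiregion mutation presence/absence.

Per patient, mutation calls become a binary character matrix over the
sequenced regions plus an all-absent germline outgroup.  Trees are
found by exhaustive enumeration for small patients and heuristic search
otherwise, scored by the Fitch algorithm; clade stability is assessed
by character bootstrap, and tree quality by the homoplasy index
HI = 1 - CI where the consistency index CI is the ratio of the minimum
possible to the observed number of character changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Effect, MutationCall, RegionSample
from .parsimony import (
    FitchScorer,
    bootstrap_splits,
    search_tree,
    topology_to_phylotree,
)
from .tree import PhyloTree, TreeNode, rf_distance

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryCharacterMatrix",
    "ParsimonyStats",
    "build_character_matrix",
    "fitch_score",
    "search_mp_tree",
    "bootstrap_support",
    "apply_support",
    "annotate_branches",
    "rf_distance",
]

OUTGROUP_ID = "germline"


@dataclass
class BinaryCharacterMatrix:
    """Samples x mutations presence/absence with an all-absent outgroup.

    Row 0 is the outgroup; ``values`` is (n_samples + 1, n_mutations) in
    {0, 1}.  Columns carry the mutation id plus gene/effect annotation.
    """

    sample_ids: list[str]  # row order, outgroup first
    mutation_ids: list[str]
    values: np.ndarray
    genes: list[str] = field(default_factory=list)
    effects: list[Optional[Effect]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.mutation_ids)):
            raise ValueError("matrix shape does not match row/column labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("character values must be binary")
        if self.values[0].any():
            raise ValueError("outgroup row must be all-absent")
        if not self.genes:
            self.genes = [""] * len(self.mutation_ids)
        if not self.effects:
            self.effects = [None] * len(self.mutation_ids)

    @property
    def n_samples(self) -> int:
        """Number of non-outgroup samples."""
        return len(self.sample_ids) - 1

    def column(self, mutation_id: str) -> np.ndarray:
        return self.values[:, self.mutation_ids.index(mutation_id)]

    def subset_columns(self, idx: Sequence[int]) -> "BinaryCharacterMatrix":
        idx = list(idx)
        return BinaryCharacterMatrix(
            self.sample_ids,
            [self.mutation_ids[i] for i in idx],
            self.values[:, idx],
            [self.genes[i] for i in idx],
            [self.effects[i] for i in idx],
        )


@dataclass
class ParsimonyStats:
    """Per-character observed and minimum change counts on a tree."""

    per_char_changes: np.ndarray  # s_i
    per_char_min: np.ndarray  # m_i

    @property
    def score(self) -> int:
        return int(self.per_char_changes.sum())

    @property
    def consistency_index(self) -> float:
        s = self.per_char_changes.sum()
        return float(self.per_char_min.sum() / s) if s > 0 else 1.0

    @property
    def homoplasy_index(self) -> float:
        return 1.0 - self.consistency_index


def build_character_matrix(
    calls: Sequence[MutationCall],
    samples: Sequence[RegionSample],
    detection_threshold: float = 0.05,
) -> BinaryCharacterMatrix:
    """Binary presence/absence over samples: a mutation is present in a
    sample iff a call exists there with VAF >= ``detection_threshold``.
    All-absent columns are dropped (with a log line); an error is raised
    when no variable column remains."""
    if len(samples) < 2:
        raise ValueError("need at least 2 non-outgroup samples")
    sample_ids = [s.sample_id for s in samples]
    order: dict[str, int] = {}
    genes: dict[str, str] = {}
    effects: dict[str, Effect] = {}
    present: dict[tuple[str, str], bool] = {}
    for call in calls:
        if call.sample_id not in sample_ids:
            continue
        mid = call.mutation_id
        if mid not in order:
            order[mid] = len(order)
            genes[mid] = call.gene
            effects[mid] = call.effect
        if call.vaf >= detection_threshold:
            present[(call.sample_id, mid)] = True

    mutation_ids = sorted(order, key=order.get)
    values = np.zeros((len(sample_ids) + 1, len(mutation_ids)), dtype=np.int8)
    for j, mid in enumerate(mutation_ids):
        for i, sid in enumerate(sample_ids):
            if present.get((sid, mid)):
                values[i + 1, j] = 1
    keep = values.any(axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d all-absent mutation columns", dropped)
    if not keep.any():
        raise ValueError("no variable characters above the detection threshold")
    mutation_ids = [m for m, k in zip(mutation_ids, keep) if k]
    return BinaryCharacterMatrix(
        [OUTGROUP_ID] + sample_ids,
        mutation_ids,
        values[:, keep],
        [genes[m] for m in mutation_ids],
        [effects[m] for m in mutation_ids],
    )


def _leaf_rows(tree: PhyloTree, matrix: BinaryCharacterMatrix) -> dict[str, int]:
    rows = {s: i for i, s in enumerate(matrix.sample_ids)}
    names = tree.leaf_names()
    if set(names) != set(matrix.sample_ids):
        raise ValueError(
            f"tree leaves do not match matrix rows: {sorted(set(names) ^ set(matrix.sample_ids))}"
        )
    return rows


def fitch_score(tree: PhyloTree, matrix: BinaryCharacterMatrix) -> ParsimonyStats:
    """Fitch change counts for each character on a given rooted topology
    (the outgroup is one of the leaves).  Polytomies are resolved as a
    left-to-right fold, which never undercounts for binary characters."""
    rows = _leaf_rows(tree, matrix)
    masks = (matrix.values.astype(np.uint8) + 1)
    counts = np.zeros(matrix.values.shape[1], dtype=np.int64)

    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node_mask[id(node)] = masks[rows[node.name]]
        else:
            acc = node_mask[id(node.children[0])]
            for child in node.children[1:]:
                m = node_mask[id(child)]
                inter = acc & m
                empty = inter == 0
                counts += empty
                acc = np.where(empty, acc | m, inter)
            node_mask[id(node)] = acc

    variable = (matrix.values != matrix.values[0]).any(axis=0)
    return ParsimonyStats(counts, variable.astype(np.int64))


def search_mp_tree(
    matrix: BinaryCharacterMatrix,
    exhaustive_limit: int = 7,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[PhyloTree, ParsimonyStats]:
    """Maximum-parsimony tree rooted at the germline outgroup.

    Exhaustive over all topologies up to ``exhaustive_limit``
    non-outgroup samples, heuristic (stepwise addition + NNI,
    ``restarts`` random orders) beyond.  Branch lengths are the changes
    assigned by one deterministic most-parsimonious reconstruction.
    """
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 non-outgroup samples")
    scorer = FitchScorer(matrix.values)
    topo, _ = search_tree(
        scorer, matrix.sample_ids,
        exhaustive_limit=exhaustive_limit, restarts=restarts, seed=seed,
    )
    tree = topology_to_phylotree(topo, matrix.sample_ids, scorer)
    stats = ParsimonyStats(scorer.per_char_changes(topo), scorer.min_changes())
    return tree, stats


def bootstrap_support(
    matrix: BinaryCharacterMatrix,
    b: int = 1000,
    seed: int = 0,
    exhaustive_limit: int = 7,
    restarts: int = 5,
) -> dict[frozenset[str], float]:
    """Character-bootstrap percentages for every non-trivial split seen
    in any replicate tree (column resampling with replacement)."""
    return bootstrap_splits(
        matrix.values, matrix.sample_ids,
        lambda m: FitchScorer(m), b, seed,
        exhaustive_limit=exhaustive_limit, restarts=restarts,
    )


def apply_support(tree: PhyloTree, supports: dict[frozenset[str], float]) -> PhyloTree:
    """Attach bootstrap percentages (and display bands) to the clades of
    ``tree``; clades absent from ``supports`` get 0."""
    n_leaves = len(tree.leaf_names())
    for split, node in tree.clade_sets().items():
        if node.is_leaf or node is tree.root or not 1 < len(split) < n_leaves - 1:
            continue
        node.support = supports.get(split, 0.0)
    return tree


def _mpr_states(tree: PhyloTree, matrix: BinaryCharacterMatrix) -> dict[int, np.ndarray]:
    """Deterministic most-parsimonious 0/1 state assignment on an
    arbitrary rooted tree; root preference is the outgroup state."""
    rows = _leaf_rows(tree, matrix)
    masks = (matrix.values.astype(np.uint8) + 1)
    node_mask: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            node_mask[id(node)] = masks[rows[node.name]]
        else:
            acc = node_mask[id(node.children[0])]
            for child in node.children[1:]:
                m = node_mask[id(child)]
                inter = acc & m
                acc = np.where(inter == 0, acc | m, inter)
            node_mask[id(node)] = acc

    states: dict[int, np.ndarray] = {}
    outgroup_bit = masks[0]  # all-absent: bit 1
    for node in tree.preorder():
        mask = node_mask[id(node)]
        if node is tree.root:
            parent_bit = outgroup_bit
        else:
            parent_bit = (states[id(node.parent)].astype(np.uint8) + 1)
        keep = (mask & parent_bit) != 0
        forced = (mask == 2).astype(np.int8)
        parent_state = (parent_bit == 2).astype(np.int8)
        states[id(node)] = np.where(keep, parent_state, forced).astype(np.int8)
    return states


def annotate_branches(
    tree: PhyloTree,
    matrix: BinaryCharacterMatrix,
    driver_genes: Sequence[str],
) -> PhyloTree:
    """Label branches with driver-gene mutations at their reconstructed
    gain edges.  A mutation whose reconstruction needs more than one
    gain (homoplasy) is labelled on every gain branch with a flag."""
    if not driver_genes:
        raise ValueError("driver gene list must be non-empty")
    drivers = set(driver_genes)
    cols = [j for j, g in enumerate(matrix.genes) if g in drivers]
    if not cols:
        return tree
    states = _mpr_states(tree, matrix)
    for j in cols:
        gain_nodes: list[TreeNode] = []
        for node in tree.preorder():
            child_state = states[id(node)][j]
            parent_state = 0 if node is tree.root else states[id(node.parent)][j]
            if parent_state == 0 and child_state == 1:
                gain_nodes.append(node)
        effect = matrix.effects[j]
        label = matrix.genes[j]
        if effect is not None:
            label += f" [{effect.value}]"
        flag = " (homoplastic)" if len(gain_nodes) > 1 else ""
        for node in gain_nodes:
            node.annotations.append(label + flag)
    return tree
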