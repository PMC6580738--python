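"""Binned copy-number phylogenies and punctuated-burst detection.

Copy-number profiles are discretised into fixed-width bins (default
500 kbp) of integer total copy number, a synthetic diploid reference
row is added as the outgroup, and a maximum-parsimony tree is built
with ordered (Wagner) characters: the cost of changing a bin from
state a to state b is |a - b|, scored by the Sankoff algorithm.  The
resulting branch lengths — total copy-number changes per lineage
segment — expose whether aneuploidy accrued gradually or in a
punctuated burst at the transition from low- to high-grade disease.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cna import CNProfile
from .model import GenomeLayout, TissueClass
from .parsimony import (
    SankoffScorer,
    bootstrap_splits,
    search_tree,
    topology_to_phylotree,
)
from .phylogeny import ParsimonyStats
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedCNMatrix",
    "bin_profiles",
    "cna_tree",
    "cna_bootstrap",
    "punctuation_profile",
    "PunctuationProfile",
]

REFERENCE_ID = "diploid"
DEFAULT_BIN_SIZE = 500_000


@dataclass
class BinnedCNMatrix:
    """Samples x fixed-width bins of integer total copy number.

    Row 0 is the synthetic diploid reference (all bins 2).  Bins tile
    the covered autosomes; bins without coverage in every sample are
    dropped from all samples.
    """

    sample_ids: list[str]  # row order, reference first
    bins: list[tuple[str, int, int]]  # (chrom, start, end), half-open
    states: np.ndarray  # (n_samples + 1, n_bins) int

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.shape != (len(self.sample_ids), len(self.bins)):
            raise ValueError("state matrix shape does not match labels")
        if (self.states < 0).any():
            raise ValueError("copy-number states must be >= 0")
        if (self.states[0] != 2).any():
            raise ValueError("reference row must be uniformly diploid")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids) - 1


def _majority_state(weights: dict[int, int]) -> int:
    """Length-weighted majority copy state; ties go to the state closer
    to 2, then to the lower state."""
    best = None
    for state, w in weights.items():
        key = (-w, abs(state - 2), state)
        if best is None or key < best[0]:
            best = (key, state)
    return best[1]


def bin_profiles(
    profiles: Sequence[CNProfile],
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinnedCNMatrix:
    """Discretise each profile into fixed-width autosomal bins.

    A bin's state is the length-weighted majority total copy number of
    the segments overlapping it; bins with no coverage in any one
    sample are dropped from all samples.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins: list[tuple[str, int, int]] = []
    for chrom in layout.autosomes():
        for start in range(0, chrom.length, bin_size):
            bins.append((chrom.name, start, min(start + bin_size, chrom.length)))

    n_bins = len(bins)
    bin_index: dict[str, list[int]] = {}
    for i, (chrom, _, _) in enumerate(bins):
        bin_index.setdefault(chrom, []).append(i)

    states = np.full((len(profiles), n_bins), -1, dtype=np.int64)
    for r, profile in enumerate(profiles):
        weights: list[dict[int, int]] = [dict() for _ in range(n_bins)]
        for seg in profile.segments:
            idxs = bin_index.get(seg.chrom)
            if not idxs:
                continue
            first = bins[idxs[0]]
            lo = max(0, (seg.start - first[1]) // bin_size)
            hi = min(len(idxs) - 1, (seg.end - 1 - first[1]) // bin_size)
            for k in range(lo, hi + 1):
                i = idxs[k]
                chrom, bstart, bend = bins[i]
                ov = min(seg.end, bend) - max(seg.start, bstart)
                if ov > 0:
                    weights[i][seg.cn_total] = weights[i].get(seg.cn_total, 0) + ov
        for i, w in enumerate(weights):
            if w:
                states[r, i] = _majority_state(w)

    keep = (states >= 0).all(axis=0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("bin_profiles: dropped %d bins without full coverage", n_dropped)
    kept_bins = [b for b, k in zip(bins, keep) if k]
    full = np.vstack([np.full(keep.sum(), 2, dtype=np.int64), states[:, keep]])
    return BinnedCNMatrix(
        [REFERENCE_ID] + [p.sample_id for p in profiles], kept_bins, full,
    )


def cna_tree(
    binned: BinnedCNMatrix,
    ordered: bool = True,
    exhaustive_limit: int = 7,
    restarts: int = 20,
    seed: int = 0,
) -> tuple[PhyloTree, ParsimonyStats]:
    """Maximum-parsimony copy-number tree rooted at the diploid
    reference.  ``ordered=True`` (default) uses Wagner |a-b| event
    costs; ``ordered=False`` counts any state change as one event."""
    if binned.n_samples < 3:
        raise ValueError("need at least 3 samples")
    scorer = SankoffScorer(binned.states, ordered=ordered)
    topo, _ = search_tree(
        scorer, binned.sample_ids,
        exhaustive_limit=exhaustive_limit, restarts=restarts, seed=seed,
    )
    tree = topology_to_phylotree(topo, binned.sample_ids, scorer)
    stats = ParsimonyStats(scorer.per_char_changes(topo), scorer.min_changes())
    return tree, stats


def cna_bootstrap(
    binned: BinnedCNMatrix,
    b: int = 1000,
    seed: int = 0,
    ordered: bool = True,
    exhaustive_limit: int = 7,
    restarts: int = 5,
) -> dict[frozenset[str], float]:
    """Bin-column bootstrap clade support for the copy-number tree."""
    return bootstrap_splits(
        binned.states, binned.sample_ids,
        lambda m: SankoffScorer(m, ordered=ordered), b, seed,
        exhaustive_limit=exhaustive_limit, restarts=restarts,
    )


@dataclass(frozen=True)
class PunctuationProfile:
    trunk_changes: int
    mean_clade_changes: float
    punctuation_ratio: float
    n_clade_samples: int
    low_confidence: bool


def punctuation_profile(
    tree: PhyloTree,
    grade_labels: Mapping[str, TissueClass],
    high_grades: Sequence[TissueClass] = (TissueClass.HGD, TissueClass.CARCINOMA),
) -> PunctuationProfile:
    """Quantify punctuated copy-number accrual at the transition to
    high-grade disease.

    ``trunk_changes`` is the length of the branch entering the smallest
    clade containing every high-grade (HGD/carcinoma) sample;
    ``mean_clade_changes`` averages all branch lengths inside that
    clade.  A high ratio indicates a burst of changes followed by
    stability (punctuated pattern); a ratio near 1 indicates ongoing
    gradual instability.  With a single high-grade sample the profile
    degenerates to the leaf branch and is flagged low-confidence.
    """
    grades = set(grade_labels.values())
    if TissueClass.LGD not in grades:
        raise ValueError("punctuation profile needs LGD samples")
    high = [s for s, g in grade_labels.items() if g in high_grades]
    if not high:
        raise ValueError("punctuation profile needs HGD or carcinoma samples")
    present = set(tree.leaf_names())
    high = [s for s in high if s in present]
    if not high:
        raise ValueError("no high-grade samples present in the tree")

    mrca = tree.mrca(high)
    trunk = int(mrca.length)
    low_confidence = len(high) == 1
    if mrca.is_leaf:
        clade_lengths = [mrca.length]
        low_confidence = True
    else:
        clade_lengths = []
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            clade_lengths.append(node.length)
            stack.extend(node.children)
    mean_clade = float(np.mean(clade_lengths)) if clade_lengths else 0.0
    ratio = trunk / max(1.0, mean_clade)
    return PunctuationProfile(trunk, mean_clade, ratio, len(high), low_confidence)
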