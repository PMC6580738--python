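"""Synthetic multiregion patients with known evolutionary ground truth.

Each simulated patient carries a rooted clone tree over its biopsy
regions (non-dysplastic mucosa, LGD, HGD, carcinoma) with an all-absent
germline outgroup:

    root ── germline
         └─ field ──── mucosa leaves          (field SNAs, early CNAs)
                 └─ trunk ── LGD leaves       (truncal SNAs + CNAs)
                        └─ lgd_to_hgd ── HGD leaves
                                   └─ carcinoma subtree (random binary)

SNAs accrue per branch as Poisson draws around stated means, with
trinucleotide contexts sampled from an epoch-specific mixture over a
reference signature set.  CNAs accrue as whole-arm gain/loss/cnLOH
events plus optional per-bin drift, and an optional punctuated burst of
exactly ``punctuated_burst_bins`` bin changes on the LGD-to-HGD branch
— the pattern whereby copy-number change arrives abruptly at the
transition to high-grade disease.  Observed VAFs follow
purity * m / (purity * cn_total + 2 (1 - purity)) with binomial
sequencing noise at the configured depth; a mutation is detected in a
region when its sampled VAF reaches the detection threshold.

The study this emulates is observational and states no generative
model; every distributional choice here is a documented stand-in, and
the generator's value is that all downstream truth (tree topology,
clonality labels, signature mixtures, burst sizes) is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .cna import CNProfile
from .model import (
    CHANNELS_96,
    Chromosome,
    CNSegment,
    Effect,
    GenomeLayout,
    MutationCall,
    RegionSample,
    SignatureMatrix,
    TissueClass,
    revcomp,
)
from .phylogeny import OUTGROUP_ID, BinaryCharacterMatrix
from .tree import PhyloTree, TreeNode

__all__ = [
    "SimulationParams",
    "SyntheticPatient",
    "simulate_patient",
    "simulate_cohort",
    "synthetic_genome",
    "synthetic_signatures",
]

# Approximate human autosome lengths and centromere positions (Mb),
# scaled to 10% so 500-kbp bins stay numerous (~575) but fast.
_HUMAN_MB = [
    (249.0, 123.4), (242.2, 93.9), (198.3, 90.9), (190.2, 50.0),
    (181.5, 48.8), (170.8, 59.8), (159.3, 60.1), (145.1, 45.2),
    (138.4, 43.0), (133.8, 39.8), (135.1, 53.4), (133.3, 35.5),
    (114.4, 17.7), (107.0, 17.2), (102.0, 19.0), (90.3, 36.8),
    (83.3, 25.1), (80.4, 18.5), (58.6, 26.2), (64.4, 28.1),
    (46.7, 12.0), (50.8, 15.0),
]


def synthetic_genome(scale: float = 0.10, bin_size: int = 500_000) -> GenomeLayout:
    """22 autosomes scaled from human proportions; lengths are rounded
    up to whole bins so bins tile the genome exactly."""
    chroms = []
    for i, (length_mb, cen_mb) in enumerate(_HUMAN_MB, start=1):
        length = int(round(length_mb * 1e6 * scale / bin_size)) * bin_size
        cen = int(round(cen_mb * 1e6 * scale / bin_size)) * bin_size
        cen = min(max(cen, bin_size), length - bin_size)
        chroms.append(Chromosome(f"chr{i}", length, cen, is_autosome=True))
    return GenomeLayout(chroms)


def synthetic_signatures() -> SignatureMatrix:
    """Three near-orthogonal synthetic signatures for testing.

    SigAge concentrates on C>T at NpCpG sites (deamination-like),
    SigFlat spreads over C>A channels, and SigMMR concentrates on C>T
    and T>C in a disjoint flank set.  These are deliberate synthetic
    stand-ins, not COSMIC signatures; a real reference matrix can be
    loaded with :func:`crcevo.io.read_signature_matrix`.
    """
    probs = np.zeros((96, 3))
    for i, ch in enumerate(CHANNELS_96):
        five, sub, three = ch[0], ch[2:5], ch[6]
        if sub == "C>T" and three == "G":
            probs[i, 0] = 2.0 if five in "AC" else 1.0
        if sub == "C>A":
            probs[i, 1] = 1.0
        if sub == "T>C" and three in "AT":
            probs[i, 2] = 1.0
        if sub == "C>T" and three == "A" and five in "GT":
            probs[i, 2] = 1.5
    probs /= probs.sum(axis=0, keepdims=True)
    return SignatureMatrix(["SigAge", "SigFlat", "SigMMR"], probs)


def _check_weights(w: Sequence[float], label: str) -> None:
    w = np.asarray(w, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"{label}: mixture weights must be >= 0 and sum to 1")


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated patient.

    SNA means follow the observed architecture: a mutational field of
    ~21 shared SNAs in the mucosa, a long trunk (~85 further truncal
    SNAs, so clonal burden ~ 106), long private branches (~30 SNAs per
    region) and ~26 additional private mucosal SNAs (mucosa burden
    ~ 47).  Epoch mixtures default to an ageing-dominated 70/15/15
    blend in every epoch.
    """

    patient_id: str = "SIM01"
    n_mucosa: int = 1
    n_lgd: int = 1
    n_hgd: int = 1
    n_carcinoma: int = 3
    # SNA accrual (Poisson means; exact counts when noise=False)
    mean_field_snas: float = 21.0
    mean_truncal_snas: float = 85.0
    mean_branch_snas: float = 15.0
    mean_private_snas: float = 30.0
    mean_mucosa_private_snas: float = 26.0
    # signature mixture per epoch (over the signature set columns)
    weights_precancer: tuple = (0.70, 0.15, 0.15)
    weights_truncal: tuple = (0.70, 0.15, 0.15)
    weights_branch: tuple = (0.70, 0.15, 0.15)
    # CNA accrual
    arm_gain_rate: float = 1.0
    arm_loss_rate: float = 1.0
    cnloh_rate: float = 0.5
    whole_genome_doubling: bool = False
    punctuated_burst_bins: int = 0
    drift_bins_mean: float = 5.0
    # observation model
    detection_threshold: float = 0.05
    purity: float = 0.7
    depth: int = 100
    noise: bool = True
    bin_size: int = 500_000
    fraction_indel: float = 0.05
    include_drivers: bool = True

    def __post_init__(self) -> None:
        for name in ("n_mucosa", "n_lgd", "n_hgd", "n_carcinoma",
                     "punctuated_burst_bins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mean_field_snas", "mean_truncal_snas", "mean_branch_snas",
                     "mean_private_snas", "mean_mucosa_private_snas",
                     "arm_gain_rate", "arm_loss_rate", "cnloh_rate",
                     "drift_bins_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        _check_weights(self.weights_precancer, "weights_precancer")
        _check_weights(self.weights_truncal, "weights_truncal")
        _check_weights(self.weights_branch, "weights_branch")
        if not 0 < self.detection_threshold < 1:
            raise ValueError("detection_threshold must be in (0, 1)")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass
class SyntheticPatient:
    """A simulated patient together with its complete ground truth."""

    patient_id: str
    params: SimulationParams
    seed: int
    layout: GenomeLayout
    signatures: SignatureMatrix
    samples: list[RegionSample]
    calls: list[MutationCall]
    segments: list[CNSegment]
    truth_tree: PhyloTree
    mutation_branch: dict[str, str]  # mutation id -> truth branch id
    branch_cna_events: dict[str, list[dict]]
    presence: dict[str, frozenset[str]]  # mutation id -> pre-noise carrier samples
    truth_clonality: dict[str, str]  # mutation id -> truncal/shared_subclonal/private/mucosa_only

    def truth_matrix(self) -> BinaryCharacterMatrix:
        """Pre-noise presence/absence matrix (simulator ground truth)."""
        sample_ids = [s.sample_id for s in self.samples]
        mids = sorted(self.presence, key=lambda m: self.mutation_order[m])
        values = np.zeros((len(sample_ids) + 1, len(mids)), dtype=np.int8)
        for j, mid in enumerate(mids):
            for sid in self.presence[mid]:
                values[sample_ids.index(sid) + 1, j] = 1
        return BinaryCharacterMatrix([OUTGROUP_ID] + sample_ids, mids, values)

    @property
    def mutation_order(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.mutation_branch)}

    def cn_profiles(self) -> list[CNProfile]:
        by_sample: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            by_sample.setdefault(seg.sample_id, []).append(seg)
        return [CNProfile(s.sample_id, by_sample.get(s.sample_id, []))
                for s in self.samples]

    def tissue_roles(self) -> dict[str, TissueClass]:
        return {s.sample_id: s.tissue_class for s in self.samples}


# ---------------------------------------------------------------------------
# Internal clone-tree scaffolding
# ---------------------------------------------------------------------------


class _Clone:
    def __init__(self, branch_id: str, parent: Optional["_Clone"]) -> None:
        self.branch_id = branch_id
        self.parent = parent
        self.children: list["_Clone"] = []
        self.sample_id: Optional[str] = None
        self.tissue: Optional[TissueClass] = None
        self.major: Optional[np.ndarray] = None
        self.minor: Optional[np.ndarray] = None
        self.cna_events: list[dict] = []
        self.n_snas = 0
        if parent is not None:
            parent.children.append(self)

    def leaves(self) -> list["_Clone"]:
        if not self.children:
            return [self]
        return [l for c in self.children for l in c.leaves()]


def _random_binary_subtree(parent: _Clone, leaves: list[_Clone], rng, counter: list[int]) -> None:
    """Attach ``leaves`` below ``parent`` as a random rooted binary tree
    whose internal branches are fresh clones."""
    if len(leaves) == 1:
        leaves[0].parent = parent
        parent.children.append(leaves[0])
        return
    k = int(rng.integers(1, len(leaves)))
    idx = rng.permutation(len(leaves))
    left = [leaves[i] for i in idx[:k]]
    right = [leaves[i] for i in idx[k:]]
    for group in (left, right):
        if len(group) == 1:
            group[0].parent = parent
            parent.children.append(group[0])
        else:
            counter[0] += 1
            node = _Clone(f"carc_internal_{counter[0]}", parent)
            _random_binary_subtree(node, group, rng, counter)


def _draw_count(rng, mean: float, noise: bool) -> int:
    if noise:
        return int(rng.poisson(mean))
    return int(round(mean))


_EFFECTS = [Effect.MISSENSE, Effect.SYNONYMOUS, Effect.NONSENSE, Effect.SPLICE, Effect.OTHER]
_EFFECT_P = [0.55, 0.25, 0.07, 0.05, 0.08]


def simulate_patient(params: SimulationParams, seed: int) -> SyntheticPatient:
    """Simulate one multiregion patient; deterministic given
    (params, seed)."""
    if params.n_carcinoma < 1:
        raise ValueError("need at least one carcinoma region")
    rng = np.random.default_rng(seed)
    layout = synthetic_genome(bin_size=params.bin_size)
    signatures = synthetic_signatures()
    pid = params.patient_id

    # --- clone tree scaffold ---------------------------------------------
    root = _Clone("root", None)
    field = _Clone("field", root)
    trunk = _Clone("trunk", field)
    hgd_node = _Clone("lgd_to_hgd", trunk)

    def leaf(parent: _Clone, branch_id: str, sid: str, tissue: TissueClass) -> _Clone:
        c = _Clone(branch_id, parent)
        c.sample_id, c.tissue = sid, tissue
        return c

    mucosa = [leaf(field, f"leaf_M{i+1}", f"{pid}_M{i+1}", TissueClass.NORMAL_MUCOSA)
              for i in range(params.n_mucosa)]
    lgd = [leaf(trunk, f"leaf_L{i+1}", f"{pid}_L{i+1}", TissueClass.LGD)
           for i in range(params.n_lgd)]
    hgd = [leaf(hgd_node, f"leaf_H{i+1}", f"{pid}_H{i+1}", TissueClass.HGD)
           for i in range(params.n_hgd)]
    carcinomas = []
    for i in range(params.n_carcinoma):
        c = _Clone(f"leaf_C{i+1}", None)
        c.sample_id, c.tissue = f"{pid}_C{i+1}", TissueClass.CARCINOMA
        carcinomas.append(c)
    if params.n_carcinoma == 1:
        carcinomas[0].parent = hgd_node
        hgd_node.children.append(carcinomas[0])
    else:
        counter = [1]
        carc_anc = _Clone("carc_internal_1", hgd_node)
        _random_binary_subtree(carc_anc, carcinomas, rng, counter)

    clones: list[_Clone] = []

    def collect(c: _Clone) -> None:
        clones.append(c)
        for ch in c.children:
            collect(ch)

    collect(root)
    leaves = [c for c in clones if c.sample_id is not None]

    # --- copy-number histories -------------------------------------------
    bin_size = params.bin_size
    bins: list[tuple[str, int, int]] = []
    for chrom in layout.autosomes():
        for start in range(0, chrom.length, bin_size):
            bins.append((chrom.name, start, min(start + bin_size, chrom.length)))
    n_bins = len(bins)
    arms = layout.arms()
    arm_bins = {
        arm.name: np.array([i for i, (c, s, e) in enumerate(bins)
                            if c == arm.chrom and s >= arm.start and e <= arm.end])
        for arm in arms
    }
    arm_names = [a.name for a in arms]

    cna_branches = {"field", "trunk", "lgd_to_hgd"}

    def apply_events(clone: _Clone) -> None:
        if clone.parent is None:
            clone.major = np.ones(n_bins, dtype=np.int64)
            clone.minor = np.ones(n_bins, dtype=np.int64)
            return
        clone.major = clone.parent.major.copy()
        clone.minor = clone.parent.minor.copy()
        events: list[dict] = []
        arm_like = clone.branch_id in cna_branches or clone.branch_id.startswith("carc_internal")
        if arm_like:
            for etype, rate in (("gain", params.arm_gain_rate),
                                ("loss", params.arm_loss_rate),
                                ("cnLOH", params.cnloh_rate)):
                for _ in range(_draw_count(rng, rate, params.noise)):
                    arm = arm_names[int(rng.integers(0, len(arm_names)))]
                    idx = arm_bins[arm]
                    if etype == "gain":
                        clone.major[idx] += 1
                    elif etype == "loss":
                        has_minor = clone.minor[idx] > 0
                        clone.minor[idx[has_minor]] -= 1
                        lost = idx[~has_minor]
                        clone.major[lost] = np.maximum(clone.major[lost] - 1, 0)
                    else:
                        clone.major[idx] += clone.minor[idx]
                        clone.minor[idx] = 0
                    events.append({"type": etype, "arm": arm})
        if clone.branch_id == "lgd_to_hgd":
            if params.whole_genome_doubling:
                clone.major *= 2
                clone.minor *= 2
                events.append({"type": "WGD"})
            if params.punctuated_burst_bins > 0:
                chosen = rng.choice(n_bins, size=min(params.punctuated_burst_bins, n_bins),
                                    replace=False)
                deltas = rng.choice([-1, 1], size=chosen.size)
                deltas[clone.major[chosen] + deltas < 0] = 1
                deltas[deltas == 0] = 1
                clone.major[chosen] += deltas
                events.append({"type": "burst", "n_bins": int(chosen.size),
                               "bins": sorted(int(i) for i in chosen)})
        # Per-bin drift on every non-root branch.
        n_drift = _draw_count(rng, params.drift_bins_mean, params.noise)
        if n_drift > 0:
            chosen = rng.choice(n_bins, size=min(n_drift, n_bins), replace=False)
            deltas = rng.choice([-1, 1], size=chosen.size)
            deltas[clone.major[chosen] + deltas < 0] = 1
            clone.major[chosen] += deltas
            events.append({"type": "drift", "n_bins": int(chosen.size),
                           "bins": sorted(int(i) for i in chosen)})
        # Renormalise so minor is the smaller allele count.
        lo = np.minimum(clone.major, clone.minor)
        hi = np.maximum(clone.major, clone.minor)
        clone.major, clone.minor = hi, lo
        clone.cna_events = events

    for clone in clones:
        apply_events(clone)

    # --- SNA accrual -------------------------------------------------------
    chrom_names = [c.name for c in layout.autosomes()]
    chrom_lengths = np.array([c.length for c in layout.autosomes()], dtype=float)
    chrom_p = chrom_lengths / chrom_lengths.sum()
    epoch_weights = {
        "precancer": np.asarray(params.weights_precancer, dtype=float),
        "truncal": np.asarray(params.weights_truncal, dtype=float),
        "branch": np.asarray(params.weights_branch, dtype=float),
    }
    channel_p = {e: signatures.probs @ w for e, w in epoch_weights.items()}

    # A branch belongs to the truncal epoch when every carcinoma region
    # descends from it (its mutations will be clonal in the cancer);
    # field and mucosa branches are the precancer epoch, the rest are
    # the branch (subclonal) epoch.
    all_carc = frozenset(c.sample_id for c in carcinomas)
    carc_below: dict[str, frozenset] = {}

    def _collect_carc(clone: _Clone) -> frozenset:
        if clone.sample_id is not None:
            below = frozenset([clone.sample_id]) & all_carc
        else:
            below = frozenset().union(*(_collect_carc(ch) for ch in clone.children))
        carc_below[clone.branch_id] = below
        return below

    _collect_carc(root)

    def branch_epoch(branch_id: str) -> str:
        if branch_id == "field" or branch_id.startswith("leaf_M") or branch_id == "root":
            return "precancer"
        if carc_below[branch_id] == all_carc:
            return "truncal"
        return "branch"

    def branch_mean(clone: _Clone) -> float:
        b = clone.branch_id
        if b == "field":
            return params.mean_field_snas
        if b == "trunk":
            return params.mean_truncal_snas
        if b.startswith("leaf_M"):
            return params.mean_mucosa_private_snas
        if b.startswith("leaf_"):
            return params.mean_private_snas
        if b in ("lgd_to_hgd",) or b.startswith("carc_internal"):
            return params.mean_branch_snas
        return 0.0

    used_positions: set[tuple[str, int]] = set()
    mutation_branch: dict[str, str] = {}
    mutation_meta: dict[str, MutationCall] = {}  # template call (sample-free fields)

    def new_mutation(branch_id: str, gene: str = "", effect: Optional[Effect] = None,
                     protein_pos: Optional[int] = None,
                     chrom: Optional[str] = None) -> str:
        epoch = branch_epoch(branch_id)
        if chrom is None:
            chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_p))]
        length = layout[chrom].length
        while True:
            pos = int(rng.integers(1, length + 1))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                break
        is_indel = effect is None and rng.random() < params.fraction_indel
        if effect is None:
            effect = Effect.FRAMESHIFT if is_indel else _EFFECTS[
                int(rng.choice(len(_EFFECTS), p=_EFFECT_P))]
        if gene == "":
            gene = f"G{int(rng.integers(0, 400)):03d}"
        if protein_pos is None:
            protein_pos = int(rng.integers(1, 501))
        if is_indel or effect == Effect.FRAMESHIFT:
            base = "ACGT"[int(rng.integers(0, 4))]
            ins = "ACGT"[int(rng.integers(0, 4))]
            ref, alt, context = base, base + ins, None
        else:
            ch = CHANNELS_96[int(rng.choice(96, p=channel_p[epoch]))]
            five, sub, three = ch[0], ch[2:5], ch[6]
            ref, alt, context = sub[0], sub[2], five + sub[0] + three
            if rng.random() < 0.5:  # emit on the purine strand half the time
                ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
        template = MutationCall(
            sample_id="", chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
            effect=effect, protein_pos=protein_pos, vaf=0.0, context=context,
        )
        mid = template.mutation_id
        mutation_branch[mid] = branch_id
        mutation_meta[mid] = template
        clone_by_branch[branch_id].n_snas += 1
        return mid

    clone_by_branch = {c.branch_id: c for c in clones}
    for clone in clones:
        mean = branch_mean(clone)
        for _ in range(_draw_count(rng, mean, params.noise)):
            new_mutation(clone.branch_id)
    if params.include_drivers:
        new_mutation("trunk", gene="TP53", effect=Effect.MISSENSE,
                     protein_pos=245, chrom="chr17")
        new_mutation("trunk", gene="KRAS", effect=Effect.MISSENSE,
                     protein_pos=12, chrom="chr12")
        if params.n_carcinoma >= 2:
            new_mutation(carcinomas[0].branch_id, gene="ARID1A",
                         effect=Effect.NONSENSE, protein_pos=300, chrom="chr1")

    # --- observation model --------------------------------------------------
    bin_of: dict[tuple[str, int], int] = {}
    first_bin: dict[str, int] = {}
    for i, (chrom, start, _) in enumerate(bins):
        if chrom not in first_bin:
            first_bin[chrom] = i

    def locus_bin(chrom: str, pos: int) -> int:
        return first_bin[chrom] + (pos - 1) // bin_size

    carriers: dict[str, list[_Clone]] = {mid: [] for mid in mutation_branch}
    for leaf_clone in leaves:
        lineage: set[str] = set()
        node: Optional[_Clone] = leaf_clone
        while node is not None:
            lineage.add(node.branch_id)
            node = node.parent
        for mid, branch in mutation_branch.items():
            if branch in lineage:
                carriers[mid].append(leaf_clone)

    purity = params.purity
    calls: list[MutationCall] = []
    presence: dict[str, set[str]] = {mid: set() for mid in mutation_branch}
    for mid, template in mutation_meta.items():
        b = locus_bin(template.chrom, template.pos)
        for leaf_clone in carriers[mid]:
            total = int(leaf_clone.major[b] + leaf_clone.minor[b])
            # The mutated copy is assumed retained (no homozygous loss of
            # mutated loci), so the effective total is at least 1.
            total = max(total, 1)
            vaf_true = purity * 1.0 / (purity * total + 2.0 * (1.0 - purity))
            if vaf_true >= params.detection_threshold:
                presence[mid].add(leaf_clone.sample_id)
            vaf_obs = (rng.binomial(params.depth, vaf_true) / params.depth
                       if params.noise else vaf_true)
            if vaf_obs >= params.detection_threshold:
                calls.append(replace(template, sample_id=leaf_clone.sample_id,
                                     vaf=float(vaf_obs)))

    # --- outputs -------------------------------------------------------------
    samples = [RegionSample(c.sample_id, pid, c.tissue, purity) for c in leaves]

    segments: list[CNSegment] = []
    for leaf_clone in leaves:
        total = leaf_clone.major + leaf_clone.minor
        minor = leaf_clone.minor
        i = 0
        while i < n_bins:
            chrom, start, end = bins[i]
            j = i
            while (j + 1 < n_bins and bins[j + 1][0] == chrom
                   and total[j + 1] == total[i] and minor[j + 1] == minor[i]):
                j += 1
            segments.append(CNSegment(leaf_clone.sample_id, chrom, start,
                                      bins[j][2], int(total[i]), int(minor[i])))
            i = j + 1

    def build_tree(clone: _Clone) -> TreeNode:
        node = TreeNode(name=clone.sample_id or clone.branch_id,
                        length=clone.n_snas)
        for ch in clone.children:
            node.add(build_tree(ch))
        return node

    troot = TreeNode(name="root")
    troot.add(TreeNode(name=OUTGROUP_ID, length=0))
    for ch in root.children:
        troot.add(build_tree(ch))
    truth_tree = PhyloTree(troot)

    carcinoma_ids = {c.sample_id for c in carcinomas}
    mucosa_ids = {c.sample_id for c in mucosa}
    truth_clonality: dict[str, str] = {}
    for mid, carrier_ids in presence.items():
        n_carc = len(carrier_ids & carcinoma_ids)
        if n_carc == 0:
            # Mutations confined to mucosa get the field-only label;
            # LGD/HGD-only mutations carry no carcinoma pattern.
            truth_clonality[mid] = "mucosa_only" if carrier_ids & mucosa_ids else "none"
        elif n_carc == len(carcinoma_ids):
            truth_clonality[mid] = "truncal"
        elif n_carc > 1:
            truth_clonality[mid] = "shared_subclonal"
        else:
            truth_clonality[mid] = "private"

    return SyntheticPatient(
        patient_id=pid,
        params=params,
        seed=seed,
        layout=layout,
        signatures=signatures,
        samples=samples,
        calls=calls,
        segments=segments,
        truth_tree=truth_tree,
        mutation_branch=mutation_branch,
        branch_cna_events={c.branch_id: c.cna_events for c in clones},
        presence={m: frozenset(s) for m, s in presence.items()},
        truth_clonality=truth_clonality,
    )


def simulate_cohort(
    params_list: Sequence[SimulationParams],
    master_seed: int,
) -> tuple[list[SyntheticPatient], list[int]]:
    """Simulate independent patients with per-patient seeds derived from
    the master seed.  The returned seeds allow any single patient to be
    re-simulated identically."""
    if not params_list:
        raise ValueError("params_list must be non-empty")
    rng = np.random.default_rng(master_seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=len(params_list))]
    patients = [simulate_patient(p, s) for p, s in zip(params_list, seeds)]
    return patients, seeds
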