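"""Copy-number burden: ploidy, percent genome altered, arm-level calls
and cohort comparisons.

Alteration states are called against an absolute diploid-heterozygous
baseline: gain when total copy number exceeds 2, loss below 2, and
copy-neutral LOH when the total is 2 with no minor allele.  A
ploidy-relative mode (baseline = rounded sample ploidy) is available
behind a flag for sensitivity analyses.  Sex chromosomes are excluded
throughout; only autosomal coverage enters denominators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import CNSegment, GenomeLayout
from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "CNProfile",
    "PloidySummary",
    "BurdenResult",
    "ploidy_summary",
    "pga",
    "arm_calls",
    "compare_arm_frequencies",
    "burden_by_grade",
]

ARM_COVERAGE_MIN = 0.10  # arms with less coverage are excluded from cohort tables


@dataclass
class CNProfile:
    """All copy-number segments of one sample."""

    sample_id: str
    segments: list[CNSegment]
    dialect: str = "allele_specific"  # or "lowpass"

    def __post_init__(self) -> None:
        if self.dialect not in ("allele_specific", "lowpass"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        for s in self.segments:
            if s.sample_id != self.sample_id:
                raise ValueError(f"segment sample {s.sample_id} != profile {self.sample_id}")
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))


@dataclass(frozen=True)
class PloidySummary:
    psi: float  # length-weighted mean total copy number
    ploidy_class: str  # near_diploid | near_triploid | near_tetraploid | other


@dataclass(frozen=True)
class BurdenResult:
    pga_full: float  # gain + loss + cnLOH
    pga_gl: float  # gains + losses only
    frac_gain: float
    frac_loss: float
    frac_cnloh: float
    covered_bp: int
    cnloh_resolvable: bool


def _autosome_segments(profile: CNProfile, layout: GenomeLayout) -> list[CNSegment]:
    out = []
    for s in profile.segments:
        if s.chrom in layout and layout[s.chrom].is_autosome:
            end = min(s.end, layout[s.chrom].length)
            if end > s.start:
                out.append(CNSegment(s.sample_id, s.chrom, s.start, end,
                                     s.cn_total, s.cn_minor))
    return out


def ploidy_summary(profile: CNProfile, layout: GenomeLayout) -> PloidySummary:
    """Length-weighted mean total copy number over covered autosomes,
    binned into ploidy classes: [1.6, 2.4) near-diploid, [2.6, 3.4]
    near-triploid, [3.6, 4.4] near-tetraploid, else other."""
    segs = _autosome_segments(profile, layout)
    total_len = sum(s.length for s in segs)
    if total_len == 0:
        raise ValueError(f"{profile.sample_id}: no autosomal coverage")
    psi = sum(s.length * s.cn_total for s in segs) / total_len
    if 1.6 <= psi < 2.4:
        cls = "near_diploid"
    elif 2.6 <= psi <= 3.4:
        cls = "near_triploid"
    elif 3.6 <= psi <= 4.4:
        cls = "near_tetraploid"
    else:
        cls = "other"
    return PloidySummary(psi, cls)


def _segment_state(seg: CNSegment, baseline: int) -> str:
    if seg.cn_total > baseline:
        return "gain"
    if seg.cn_total < baseline:
        return "loss"
    if seg.cn_minor == 0 and seg.cn_total > 0:
        return "cnLOH"
    return "neutral"


def pga(
    profile: CNProfile,
    layout: GenomeLayout,
    ploidy_relative: bool = False,
) -> BurdenResult:
    """Percent genome altered over covered autosomes.

    ``pga_full`` counts gain + loss + cnLOH; ``pga_gl`` gains and losses
    only.  Low-pass profiles cannot resolve cnLOH, so pga_full == pga_gl
    there, with ``cnloh_resolvable=False``.
    """
    segs = _autosome_segments(profile, layout)
    covered = sum(s.length for s in segs)
    if covered == 0:
        return BurdenResult(0.0, 0.0, 0.0, 0.0, 0.0, 0, profile.dialect == "allele_specific")
    baseline = 2
    if ploidy_relative:
        baseline = max(1, round(ploidy_summary(profile, layout).psi))
    by_state = {"gain": 0, "loss": 0, "cnLOH": 0}
    resolvable = profile.dialect == "allele_specific"
    for s in segs:
        state = _segment_state(s, baseline)
        if state == "cnLOH" and not resolvable:
            state = "neutral"
        if state in by_state:
            by_state[state] += s.length
    frac = {k: v / covered for k, v in by_state.items()}
    pga_gl = frac["gain"] + frac["loss"]
    return BurdenResult(
        pga_full=pga_gl + frac["cnLOH"],
        pga_gl=pga_gl,
        frac_gain=frac["gain"],
        frac_loss=frac["loss"],
        frac_cnloh=frac["cnLOH"],
        covered_bp=covered,
        cnloh_resolvable=resolvable,
    )


def arm_calls(
    profile: CNProfile,
    layout: GenomeLayout,
    arm_fraction_threshold: float = 0.5,
    ploidy_relative: bool = False,
) -> pd.DataFrame:
    """Per-arm call (gain / loss / cnLOH / neutral) with the fraction of
    the arm supporting it.  An arm is called altered when at least
    ``arm_fraction_threshold`` of its length is in one altered state;
    gain/loss take precedence over cnLOH.  Uncovered arms are neutral
    with a warning; the coverage fraction is reported for filtering.
    """
    segs = _autosome_segments(profile, layout)
    baseline = 2
    if ploidy_relative and segs:
        baseline = max(1, round(ploidy_summary(profile, layout).psi))
    resolvable = profile.dialect == "allele_specific"
    rows = []
    for arm in layout.arms():
        lens = {"gain": 0, "loss": 0, "cnLOH": 0}
        covered = 0
        for s in segs:
            if s.chrom != arm.chrom:
                continue
            ov = min(s.end, arm.end) - max(s.start, arm.start)
            if ov <= 0:
                continue
            covered += ov
            state = _segment_state(s, baseline)
            if state == "cnLOH" and not resolvable:
                state = "neutral"
            if state in lens:
                lens[state] += ov
        if covered == 0:
            warnings.warn(f"{profile.sample_id}: arm {arm.name} has no coverage")
            rows.append({"sample_id": profile.sample_id, "arm": arm.name,
                         "call": "neutral", "fraction": 0.0, "coverage": 0.0})
            continue
        fracs = {k: v / arm.length for k, v in lens.items()}
        call, frac = "neutral", 0.0
        gl = {"gain": fracs["gain"], "loss": fracs["loss"]}
        best_gl = max(gl, key=gl.get)
        if gl[best_gl] >= arm_fraction_threshold:
            call, frac = best_gl, gl[best_gl]
        elif fracs["cnLOH"] >= arm_fraction_threshold:
            call, frac = "cnLOH", fracs["cnLOH"]
        rows.append({"sample_id": profile.sample_id, "arm": arm.name,
                     "call": call, "fraction": frac,
                     "coverage": covered / arm.length})
    return pd.DataFrame(rows)


def compare_arm_frequencies(
    cohort_a: Sequence[pd.DataFrame],
    cohort_b: Sequence[pd.DataFrame],
    coverage_min: float = ARM_COVERAGE_MIN,
) -> pd.DataFrame:
    """Fisher exact comparison of arm-level gain and loss frequencies
    between two cohorts of per-sample arm-call tables, BH-adjusted
    across all arm x direction tests.  Samples whose arm coverage is
    below ``coverage_min`` are excluded for that arm."""
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must contain at least one sample")

    def counts(cohort: Sequence[pd.DataFrame]) -> pd.DataFrame:
        cat = pd.concat(cohort, ignore_index=True)
        cat = cat[cat["coverage"] >= coverage_min]
        return cat

    ca, cb = counts(cohort_a), counts(cohort_b)
    arms = sorted(set(ca["arm"]) & set(cb["arm"]), key=_arm_sort_key)
    rows = []
    for arm in arms:
        sa = ca[ca["arm"] == arm]
        sb = cb[cb["arm"] == arm]
        if sa.empty or sb.empty:
            continue
        for direction in ("gain", "loss"):
            ka = int((sa["call"] == direction).sum())
            kb = int((sb["call"] == direction).sum())
            na, nb = len(sa), len(sb)
            res = _stats.fisher_exact_2x2(ka, na - ka, kb, nb - kb)
            rows.append({"arm": arm, "direction": direction,
                         "count_a": ka, "n_a": na, "count_b": kb, "n_b": nb,
                         "odds_ratio": res.statistic, "p": res.p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = _stats.bh_adjust(df["p"].to_numpy())
        df["significant"] = df["q"] < 0.05
    return df


def _arm_sort_key(arm: str) -> tuple:
    chrom = arm.rstrip("pq")
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (int(digits) if digits else 99, chrom, arm[-1])


def burden_by_grade(groups: Mapping[str, Sequence[float]]) -> dict:
    """Kruskal-Wallis across lesion grades plus BH-adjusted pairwise
    Mann-Whitney comparisons of per-sample genome-altered fractions."""
    names = list(groups)
    if len(names) < 2 or any(len(groups[g]) == 0 for g in names):
        raise ValueError("need >= 2 non-empty grade groups")
    kw = _stats.kruskal_wallis([groups[g] for g in names])
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = _stats.mann_whitney_u(groups[a], groups[b])
            pair_rows.append({"group_a": a, "group_b": b,
                              "U": res.statistic, "p": res.p, "exact": res.exact})
    pairs = pd.DataFrame(pair_rows)
    if not pairs.empty:
        pairs["q"] = _stats.bh_adjust(pairs["p"].to_numpy())
    medians = {g: float(np.median(groups[g])) for g in names}
    return {"kruskal_wallis": kw, "pairwise": pairs, "medians": medians}
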