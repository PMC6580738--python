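"""Clonality classification, field sharing, mutation burden and CCF.

A mutation observed in at least one carcinoma region of a patient is
exactly one of truncal (all carcinoma regions), shared subclonal (more
than one but not all) or private (exactly one); independently it may
also be present in the surrounding non-dysplastic mucosa (a field
mutation).  Mutations seen only in mucosa are flagged ``mucosa_only``
and carry no cancer pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import Effect, MutationCall, TissueClass
from .phylogeny import BinaryCharacterMatrix
from . import stats as _stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClonalityRecord",
    "BurdenSummary",
    "CCFEstimate",
    "classify_clonality",
    "field_overlap_fraction",
    "mutation_burden",
    "estimate_ccf",
    "convergent_genes",
    "tp53_domain_class",
    "gene_frequency_table",
    "pool_frequencies",
    "compare_gene_frequencies",
]

# Default exome footprint (Mb) used to convert mutation counts to SNAs/Mb.
DEFAULT_FOOTPRINT_MB = 34.7
# Burden threshold (SNAs/Mb) above which a sample is flagged as
# hypermutated / microsatellite-instability-like.
DEFAULT_MSI_THRESHOLD = 10.0
# TP53 DNA-binding domain codon range (inclusive).
TP53_DBD_RANGE = (102, 292)


@dataclass(frozen=True)
class ClonalityRecord:
    mutation_id: str
    cancer_pattern: Optional[str]  # "truncal" | "shared_subclonal" | "private" | None
    in_mucosa: bool
    mucosa_only: bool

    def __post_init__(self) -> None:
        if self.mucosa_only and self.cancer_pattern is not None:
            raise ValueError("mucosa_only mutations carry no cancer pattern")


@dataclass(frozen=True)
class BurdenSummary:
    sample_id: str
    n_nonsynonymous: int
    snas_per_mb: float
    msi_flag: bool


@dataclass(frozen=True)
class CCFEstimate:
    mutation_id: str
    multiplicity: int
    ccf: float  # capped at 1.0 for reporting
    ccf_raw: float


def classify_clonality(
    matrix: BinaryCharacterMatrix,
    sample_roles: Mapping[str, TissueClass],
) -> list[ClonalityRecord]:
    """Classify every matrix column by its presence pattern across the
    carcinoma regions and the mucosa."""
    non_outgroup = matrix.sample_ids[1:]
    missing = [s for s in non_outgroup if s not in sample_roles]
    if missing:
        raise ValueError(f"tissue role missing for samples: {missing}")
    carcinoma = [i + 1 for i, s in enumerate(non_outgroup)
                 if sample_roles[s] == TissueClass.CARCINOMA]
    mucosa = [i + 1 for i, s in enumerate(non_outgroup)
              if sample_roles[s] == TissueClass.NORMAL_MUCOSA]
    if not carcinoma:
        raise ValueError("need at least one carcinoma sample")

    records: list[ClonalityRecord] = []
    for j, mid in enumerate(matrix.mutation_ids):
        col = matrix.values[:, j]
        n_carc = int(col[carcinoma].sum())
        in_mucosa = bool(col[mucosa].sum() > 0) if mucosa else False
        if n_carc == 0:
            records.append(ClonalityRecord(mid, None, in_mucosa, mucosa_only=in_mucosa))
            continue
        if n_carc == len(carcinoma):
            pattern = "truncal"
        elif n_carc > 1:
            pattern = "shared_subclonal"
        else:
            pattern = "private"
        records.append(ClonalityRecord(mid, pattern, in_mucosa, mucosa_only=False))
    return records


def field_overlap_fraction(records: Sequence[ClonalityRecord]) -> float:
    """Fraction of truncal mutations also present in the surrounding
    mucosa (the mutational field).  NaN when there is no truncal
    mutation."""
    truncal = [r for r in records if r.cancer_pattern == "truncal"]
    if not truncal:
        logger.warning("field_overlap_fraction: no truncal mutations; undefined")
        return float("nan")
    return sum(r.in_mucosa for r in truncal) / len(truncal)


def mutation_burden(
    calls: Sequence[MutationCall],
    sample_id: str,
    footprint_mb: float = DEFAULT_FOOTPRINT_MB,
    msi_threshold: float = DEFAULT_MSI_THRESHOLD,
) -> BurdenSummary:
    """Non-synonymous mutation count and SNAs/Mb for one sample, with a
    burden-based hypermutation (MSI-like) flag."""
    if footprint_mb <= 0:
        raise ValueError("footprint_mb must be positive")
    n = sum(1 for c in calls
            if c.sample_id == sample_id and c.effect != Effect.SYNONYMOUS)
    per_mb = n / footprint_mb
    return BurdenSummary(sample_id, n, per_mb, per_mb >= msi_threshold)


def estimate_ccf(
    call: MutationCall,
    purity: float,
    cn_total: int,
    cn_major: int,
) -> CCFEstimate:
    """Cancer cell fraction from VAF, purity and local copy number.

    multiplicity = clamp(round(vaf * (purity*cn_total + 2(1-purity)) / purity),
                         1, max(cn_major, 1))
    ccf = vaf * (purity*cn_total + 2(1-purity)) / (purity * multiplicity)
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if cn_total < 1:
        raise ValueError("cn_total must be >= 1")
    denom = purity * cn_total + 2.0 * (1.0 - purity)
    raw_mult = call.vaf * denom / purity
    mult = int(min(max(round(raw_mult), 1), max(cn_major, 1)))
    ccf_raw = call.vaf * denom / (purity * mult)
    return CCFEstimate(call.mutation_id, mult, min(ccf_raw, 1.0), ccf_raw)


def convergent_genes(
    calls: Sequence[MutationCall],
    ccf_by_mutation: Mapping[str, float],
    ccf_threshold: float = 0.8,
) -> dict[str, int]:
    """Genes carrying >= 2 distinct near-clonal non-synonymous mutations
    (convergent multi-hit pattern).  Returns gene -> count of distinct
    qualifying mutations."""
    per_gene: dict[str, set[str]] = {}
    for c in calls:
        if not c.gene or c.effect == Effect.SYNONYMOUS:
            continue
        ccf = ccf_by_mutation.get(c.mutation_id)
        if ccf is None or ccf < ccf_threshold:
            continue
        per_gene.setdefault(c.gene, set()).add(c.mutation_id)
    return {g: len(muts) for g, muts in per_gene.items() if len(muts) >= 2}


def tp53_domain_class(protein_pos: int) -> str:
    """'DNA_binding' for codons within the p53 DNA-binding domain
    (102-292 inclusive), else 'other'."""
    lo, hi = TP53_DBD_RANGE
    return "DNA_binding" if lo <= protein_pos <= hi else "other"


def gene_frequency_table(
    cohort_calls: Mapping[str, Sequence[MutationCall]],
    n_cases: Mapping[str, int],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Per-gene mutated-case fractions for each cohort.

    A case counts as mutated in a gene when it has >= 1 non-synonymous
    call in that gene; cases are identified by the sample_id prefix up
    to the first '_' (or the whole sample_id), i.e. the patient.
    """
    rows = []
    for cohort, calls in cohort_calls.items():
        n = n_cases[cohort]
        if n <= 0:
            raise ValueError(f"cohort {cohort!r} has no cases")
        mutated: dict[str, set[str]] = {g: set() for g in genes}
        for c in calls:
            if c.gene in mutated and c.effect != Effect.SYNONYMOUS:
                case = c.sample_id.split("_")[0]
                mutated[c.gene].add(case)
        for g in genes:
            k = len(mutated[g])
            rows.append({"cohort": cohort, "gene": g, "n_mutated": k,
                         "n_cases": n, "fraction": k / n})
    return pd.DataFrame(rows)


def pool_frequencies(tables: Sequence[pd.DataFrame], label: str = "pooled") -> pd.DataFrame:
    """Meta-analysis pooling: sum numerators and denominators per gene
    across cohort tables."""
    cat = pd.concat(tables, ignore_index=True)
    grouped = cat.groupby("gene", sort=False).agg(
        n_mutated=("n_mutated", "sum"), n_cases=("n_cases", "sum")
    ).reset_index()
    grouped["cohort"] = label
    grouped["fraction"] = grouped["n_mutated"] / grouped["n_cases"]
    return grouped[["cohort", "gene", "n_mutated", "n_cases", "fraction"]]


def compare_gene_frequencies(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene Fisher exact comparison of mutated-case fractions
    between two cohort tables, with Benjamini-Hochberg q-values."""
    a = table_a.set_index("gene")
    b = table_b.set_index("gene")
    genes = [g for g in a.index if g in b.index]
    rows = []
    for g in genes:
        ka, na = int(a.loc[g, "n_mutated"]), int(a.loc[g, "n_cases"])
        kb, nb = int(b.loc[g, "n_mutated"]), int(b.loc[g, "n_cases"])
        res = _stats.fisher_exact_2x2(ka, na - ka, kb, nb - kb)
        rows.append({"gene": g, "frac_a": ka / na, "frac_b": kb / nb,
                     "odds_ratio": res.statistic, "p": res.p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q"] = _stats.bh_adjust(df["p"].to_numpy())
    return df
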