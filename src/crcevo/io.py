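"""Readers and writers for the tabular and tree formats of the pipeline.

All on-disk genomic coordinates are 1-based inclusive (SEG convention);
conversion to the internal half-open zero-based representation happens
here and nowhere else.  Parse failures raise :class:`ParseError` with
the 1-based line number of the offending row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    CHANNELS_96,
    Chromosome,
    CNSegment,
    Effect,
    GenomeLayout,
    InvariantError,
    MutationCall,
    RegionSample,
    SignatureMatrix,
    TissueClass,
)
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_mutation_table",
    "write_mutation_table",
    "read_segments",
    "write_segments",
    "read_genome_layout",
    "write_genome_layout",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_newick",
    "write_newick",
]

PathLike = Union[str, Path]

MUTATION_COLUMNS = [
    "sample_id", "patient_id", "tissue_class", "chrom", "pos", "ref", "alt",
    "gene", "effect", "protein_pos", "vaf", "context",
]

_NA = {"", ".", "na", "nan", "none", "unknown"}


class ParseError(ValueError):
    """A malformed input row; carries the 1-based file line number."""

    def __init__(self, message: str, line: Optional[int] = None) -> None:
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _read_tsv(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}", line=1)
    return df

def _opt(value: str) -> Optional[str]:
    return None if value.strip().lower() in _NA else value.strip()


# ---------------------------------------------------------------------------
# Mutation tables
# ---------------------------------------------------------------------------


def read_mutation_table(path: PathLike) -> tuple[list[MutationCall], list[RegionSample]]:
    """Read a per-patient (or cohort) mutation table.

    Returns the validated calls and the deduplicated sample metadata.
    Duplicate (sample, chrom, pos, alt) rows are rejected.
    """
    df = _read_tsv(path, MUTATION_COLUMNS)
    calls: list[MutationCall] = []
    samples: dict[str, RegionSample] = {}
    seen: set[tuple[str, str, int, str]] = set()
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        try:
            pos = int(row.pos)
            protein_pos = _opt(row.protein_pos)
            vaf = float(row.vaf)
            call = MutationCall(
                sample_id=row.sample_id,
                chrom=row.chrom,
                pos=pos,
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                effect=Effect.parse(row.effect),
                protein_pos=int(protein_pos) if protein_pos is not None else None,
                vaf=vaf,
                context=_opt(row.context),
            )
            sample = RegionSample(
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                tissue_class=TissueClass.parse(row.tissue_class),
            )
        except (ValueError, InvariantError) as exc:
            raise ParseError(str(exc), line=line) from exc
        key = (call.sample_id, call.chrom, call.pos, call.alt)
        if key in seen:
            raise ParseError(f"duplicate call {key}", line=line)
        seen.add(key)
        prev = samples.get(sample.sample_id)
        if prev is not None and prev != sample:
            raise ParseError(
                f"sample {sample.sample_id} has inconsistent metadata", line=line
            )
        samples[sample.sample_id] = sample
        calls.append(call)
    return calls, list(samples.values())


def write_mutation_table(
    calls: Sequence[MutationCall],
    samples: Sequence[RegionSample],
    path: PathLike,
) -> None:
    meta = {s.sample_id: s for s in samples}
    rows = []
    for c in calls:
        s = meta[c.sample_id]
        rows.append({
            "sample_id": c.sample_id,
            "patient_id": s.patient_id,
            "tissue_class": s.tissue_class.value,
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "gene": c.gene,
            "effect": c.effect.value,
            "protein_pos": "" if c.protein_pos is None else c.protein_pos,
            "vaf": repr(c.vaf),
            "context": "" if c.context is None else c.context,
        })
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number segments (SEG-like)
# ---------------------------------------------------------------------------

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_total"]


def read_segments(path: PathLike, dialect: str = "allele_specific") -> list[CNSegment]:
    """Read SEG-like segments (1-based inclusive on disk) into half-open
    zero-based :class:`CNSegment` records.

    ``dialect='lowpass'`` marks minor copy number unknown even when a
    ``cn_minor`` column is present.  Overlapping segments within one
    sample are rejected.
    """
    if dialect not in ("allele_specific", "lowpass"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_tsv(path, SEG_COLUMNS)
    has_minor = "cn_minor" in df.columns and dialect == "allele_specific"
    segs: list[CNSegment] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2
        try:
            start1, end1 = int(row.start), int(row.end)
            if start1 < 1 or end1 < start1:
                raise InvariantError(
                    f"bad 1-based inclusive interval {start1}-{end1}"
                )
            minor: Optional[int] = None
            if has_minor:
                raw = _opt(str(row.cn_minor))
                minor = int(raw) if raw is not None else None
            segs.append(CNSegment(
                sample_id=row.sample_id,
                chrom=row.chrom,
                start=start1 - 1,
                end=end1,
                cn_total=int(row.cn_total),
                cn_minor=minor,
            ))
        except (ValueError, InvariantError) as exc:
            raise ParseError(str(exc), line=line) from exc

    by_key: dict[tuple[str, str], list[CNSegment]] = {}
    for s in segs:
        by_key.setdefault((s.sample_id, s.chrom), []).append(s)
    for (sid, chrom), group in by_key.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ParseError(
                    f"overlapping segments for {sid} on {chrom}: "
                    f"{a.start + 1}-{a.end} and {b.start + 1}-{b.end}"
                )
    return segs


def write_segments(segments: Sequence[CNSegment], path: PathLike) -> None:
    rows = [{
        "sample_id": s.sample_id,
        "chrom": s.chrom,
        "start": s.start + 1,
        "end": s.end,
        "cn_total": s.cn_total,
        "cn_minor": "" if s.cn_minor is None else s.cn_minor,
    } for s in segments]
    pd.DataFrame(rows, columns=SEG_COLUMNS + ["cn_minor"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = ["chrom", "length", "centromere", "is_autosome"]


def read_genome_layout(path: PathLike) -> GenomeLayout:
    df = _read_tsv(path, LAYOUT_COLUMNS)
    chroms = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            chroms.append(Chromosome(
                name=row.chrom,
                length=int(row.length),
                centromere=int(row.centromere),
                is_autosome=str(row.is_autosome).strip().lower() in ("1", "true", "yes"),
            ))
        except (ValueError, InvariantError) as exc:
            raise ParseError(str(exc), line=idx + 2) from exc
    try:
        return GenomeLayout(chroms)
    except InvariantError as exc:
        raise ParseError(str(exc)) from exc


def write_genome_layout(layout: GenomeLayout, path: PathLike) -> None:
    rows = [{
        "chrom": c.name,
        "length": c.length,
        "centromere": c.centromere,
        "is_autosome": "1" if c.is_autosome else "0",
    } for c in layout.chromosomes]
    pd.DataFrame(rows, columns=LAYOUT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Signature matrices
# ---------------------------------------------------------------------------


def read_signature_matrix(path: PathLike) -> SignatureMatrix:
    """Read a 96-row signature matrix; channel labels must appear in the
    fixed pyrimidine-centred order and each column must sum to 1 within
    1e-6 (validated to 1e-9 after normalisation bookkeeping)."""
    df = _read_tsv(path, ["channel"])
    if len(df) != 96:
        raise ParseError(f"expected 96 channel rows, found {len(df)}")
    labels = list(df["channel"])
    if labels != list(CHANNELS_96):
        bad = next(i for i, (a, b) in enumerate(zip(labels, CHANNELS_96)) if a != b)
        raise ParseError(
            f"channel order mismatch: found {labels[bad]!r}, expected {CHANNELS_96[bad]!r}",
            line=bad + 2,
        )
    names = [c for c in df.columns if c != "channel"]
    if not names:
        raise ParseError("no signature columns present", line=1)
    try:
        probs = df[names].astype(float).to_numpy()
    except ValueError as exc:
        raise ParseError(f"non-numeric signature entry: {exc}") from exc
    if (probs < 0).any():
        i, j = np.argwhere(probs < 0)[0]
        raise ParseError(f"negative entry in signature {names[j]!r}", line=int(i) + 2)
    sums = probs.sum(axis=0)
    off = np.abs(sums - 1.0)
    if (off > 1e-6).any():
        j = int(np.argmax(off))
        raise ParseError(f"signature column {names[j]!r} sums to {sums[j]:.6g}, not 1")
    return SignatureMatrix(names, probs)


def write_signature_matrix(matrix: SignatureMatrix, path: PathLike) -> None:
    df = pd.DataFrame(matrix.probs, columns=matrix.names)
    df.insert(0, "channel", list(CHANNELS_96))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def write_newick(tree: PhyloTree, path: PathLike, with_support: bool = True) -> None:
    """Write a rooted tree with branch lengths; clade support appears as
    internal-node labels.  Unnamed leaves are rejected."""
    for leaf in tree.leaves():
        if not leaf.name:
            raise ValueError("cannot serialise a tree with unnamed leaves")
    Path(path).write_text(tree.to_newick(with_support=with_support) + "\n")


def read_newick(path: PathLike) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())
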