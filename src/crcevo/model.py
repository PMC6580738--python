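"""Core domain types shared across the pipeline.

The package analyses multiregion tumour samples: per-region somatic
mutation calls (SNAs and small indels), allele-specific copy-number
segments, and the genome layout that defines chromosome arms.  All
genomic intervals are half-open and zero-based internally; the on-disk
formats are 1-based inclusive (SEG convention) and converted at the I/O
boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TissueClass",
    "Effect",
    "Chromosome",
    "GenomeLayout",
    "Arm",
    "RegionSample",
    "MutationCall",
    "CNSegment",
    "SignatureMatrix",
    "CHANNELS_96",
    "InvariantError",
]


class InvariantError(ValueError):
    """A domain object violated one of its declared invariants."""


class TissueClass(str, enum.Enum):
    """Biopsy role within a patient."""

    BLOOD = "blood"
    NORMAL_MUCOSA = "normal_mucosa"
    LGD = "LGD"
    HGD = "HGD"
    CARCINOMA = "carcinoma"

    @classmethod
    def parse(cls, s: str) -> "TissueClass":
        for m in cls:
            if m.value.lower() == s.strip().lower():
                return m
        raise InvariantError(f"unknown tissue class: {s!r}")


class Effect(str, enum.Enum):
    """Coding consequence of a mutation call."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    OTHER = "other"

    @classmethod
    def parse(cls, s: str) -> "Effect":
        for m in cls:
            if m.value.lower() == s.strip().lower():
                return m
        raise InvariantError(f"unknown effect class: {s!r}")


# ---------------------------------------------------------------------------
# 96-channel substitution catalogue order (pyrimidine-centred convention):
# six substitution types C>A, C>G, C>T, T>A, T>C, T>G, each over the 16
# combinations of 5' and 3' flanking bases in A, C, G, T order.
# ---------------------------------------------------------------------------

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int
    is_autosome: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvariantError(f"{self.name}: length must be > 0")
        if not 0 < self.centromere < self.length:
            raise InvariantError(
                f"{self.name}: centromere must lie strictly inside the chromosome"
            )


@dataclass(frozen=True)
class Arm:
    """One chromosome arm, as a half-open zero-based interval."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Ordered chromosomes with centromere positions defining p/q arms."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise InvariantError("chromosome names must be unique")
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_autosome]

    @property
    def autosome_length(self) -> int:
        return sum(c.length for c in self.autosomes())

    def arms(self, autosomes_only: bool = True) -> list[Arm]:
        chroms = self.autosomes() if autosomes_only else self.chromosomes
        out: list[Arm] = []
        for c in chroms:
            out.append(Arm(c.name, "p", 0, c.centromere))
            out.append(Arm(c.name, "q", c.centromere, c.length))
        return out


@dataclass(frozen=True)
class RegionSample:
    """One sequenced biopsy region of one patient."""

    sample_id: str
    patient_id: str
    tissue_class: TissueClass
    purity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.purity is not None and not 0.0 <= self.purity <= 1.0:
            raise InvariantError(
                f"{self.sample_id}: purity {self.purity} outside [0, 1]"
            )


@dataclass(frozen=True)
class MutationCall:
    """One somatic SNA/indel observation in one sample.

    ``context`` is the reference trinucleotide with the mutated base in
    the middle; it is ``None`` for indels and for calls whose context is
    unknown.  ``vaf`` is the raw variant allele fraction.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    effect: Effect = Effect.OTHER
    protein_pos: Optional[int] = None
    vaf: float = 0.0
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise InvariantError(f"vaf {self.vaf} outside [0, 1]")
        if self.ref == self.alt:
            raise InvariantError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise InvariantError(f"position {self.pos} is not 1-based")
        if self.context is not None:
            if len(self.context) != 3:
                raise InvariantError(f"context {self.context!r} is not a trinucleotide")
            if self.is_snv and self.context[1] != self.ref:
                raise InvariantError(
                    f"context {self.context!r} middle base does not match ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def mutation_id(self) -> str:
        """Sample-independent identity of the genomic change."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CNSegment:
    """Allele-specific copy-number segment (internal half-open 0-based).

    ``cn_minor`` is ``None`` in the low-pass dialect, where total copy
    number is resolvable but allelic phase is not (so copy-neutral LOH
    cannot be seen).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    cn_total: int
    cn_minor: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InvariantError(
                f"{self.sample_id} {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )
        if self.cn_total < 0:
            raise InvariantError("cn_total must be >= 0")
        if self.cn_minor is not None:
            if self.cn_minor < 0:
                raise InvariantError("cn_minor must be >= 0")
            if 2 * self.cn_minor > self.cn_total:
                raise InvariantError(
                    f"cn_minor {self.cn_minor} exceeds half of cn_total {self.cn_total}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SignatureMatrix:
    """Reference mutational signatures: 96 channels x K processes.

    Each column is a probability distribution over the fixed channel
    order ``CHANNELS_96`` and must sum to 1 within 1e-9 (validated at
    load; construction tolerates 1e-6 and renormalises nothing).
    """

    names: list[str]
    probs: np.ndarray  # shape (96, K)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.names)):
            raise InvariantError(
                f"signature matrix shape {self.probs.shape} != (96, {len(self.names)})"
            )
        if (self.probs < 0).any():
            raise InvariantError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            culprit = self.names[int(np.argmax(bad))]
            raise InvariantError(
                f"signature column {culprit!r} sums to {sums[bad][0]:.6f}, expected 1"
            )

    @property
    def k(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.probs[:, idx])
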