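"""96-channel mutation catalogues and non-negative signature fitting.

Substitutions are tallied in the pyrimidine-centred trinucleotide
convention (purine-centred calls are reverse-complemented), and
exposures are obtained by non-negative least squares against a
reference signature matrix: e = argmin_{e >= 0} ||c - S e||^2, solved
with an active-set method whose pivoting is deterministic, so fits are
reproducible bit-for-bit.  Fit quality is summarised as
R^2 = 1 - SS_res / SS_tot; SS_tot is mean-centred by default (the
uncentred variant is available via ``centered=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import nnls

from .model import CHANNEL_INDEX, MutationCall, SignatureMatrix, revcomp

logger = logging.getLogger(__name__)

__all__ = ["MutationCatalogue", "SignatureFit", "tally_96", "fit_exposures", "fit_by_epoch"]

_PURINES = set("AG")


@dataclass
class MutationCatalogue:
    """Counts over the 96 fixed substitution channels."""

    counts: np.ndarray
    label: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("catalogue must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalogue counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class SignatureFit:
    """Non-negative exposures (absolute, in mutation units) with fit R^2."""

    signature_names: list[str]
    exposures: np.ndarray
    r_squared: float
    residual: np.ndarray
    label: str = ""

    @property
    def relative(self) -> np.ndarray:
        total = self.exposures.sum()
        if total <= 0:
            return np.zeros_like(self.exposures)
        return self.exposures / total

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_names, map(float, self.exposures)))


def channel_of(call: MutationCall) -> Optional[str]:
    """Normalised 96-channel label of a substitution call, or ``None``
    for indels / unknown context.  Raises when the context is
    inconsistent with the reference base after strand normalisation."""
    if not call.is_snv or call.context is None:
        return None
    ref, alt, ctx = call.ref, call.alt, call.context
    if ref in _PURINES:
        ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
    if ctx[1] != ref:
        raise ValueError(
            f"context {call.context!r} inconsistent with ref {call.ref!r} at "
            f"{call.chrom}:{call.pos}"
        )
    return f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"


def tally_96(calls: Sequence[MutationCall], label: str = "") -> MutationCatalogue:
    """Tally distinct substitutions into the 96-channel catalogue.

    The same genomic mutation observed in several samples counts once.
    Indels and unknown-context calls are skipped and counted in
    ``n_skipped``.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    seen: set[str] = set()
    for call in calls:
        mid = call.mutation_id
        if mid in seen:
            continue
        seen.add(mid)
        ch = channel_of(call)
        if ch is None:
            skipped += 1
            continue
        counts[CHANNEL_INDEX[ch]] += 1
    if skipped:
        logger.info("tally_96(%s): skipped %d indel/unknown-context mutations", label, skipped)
    return MutationCatalogue(counts, label=label, n_skipped=skipped)


def fit_exposures(
    catalogue,
    signatures: SignatureMatrix,
    subset: Optional[Sequence[str]] = None,
    centered: bool = True,
) -> SignatureFit:
    """Non-negative least-squares exposures of ``catalogue`` over the
    chosen signature columns.  ``catalogue`` may be a
    :class:`MutationCatalogue` or a raw length-96 non-negative vector
    (e.g. an exact mixture).  An all-zero catalogue has undefined R^2
    (NaN) and zero exposures."""
    sigs = signatures if subset is None else signatures.subset(list(subset))
    if isinstance(catalogue, MutationCatalogue):
        c = catalogue.counts.astype(float)
        label = catalogue.label
    else:
        c = np.asarray(catalogue, dtype=float)
        if c.shape != (96,) or (c < 0).any():
            raise ValueError("catalogue vector must be length 96 and non-negative")
        label = ""
        catalogue = None
    if c.sum() == 0:
        logger.warning("fit_exposures(%s): empty catalogue", label)
        return SignatureFit(list(sigs.names), np.zeros(sigs.k), float("nan"), c.copy(),
                            label=label)
    e, _ = nnls(sigs.probs, c)
    resid = c - sigs.probs @ e
    ss_res = float(resid @ resid)
    ref = c - c.mean() if centered else c
    ss_tot = float(ref @ ref)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return SignatureFit(list(sigs.names), e, r2, resid, label=label)


def fit_by_epoch(
    calls: Sequence[MutationCall],
    clonality_records,
    signatures: SignatureMatrix,
    subset: Optional[Sequence[str]] = None,
) -> dict[str, SignatureFit]:
    """Fit exposures separately for the precancer (mucosa-shared field),
    truncal (clonal in the carcinoma, not in mucosa) and branch
    (subclonal + private) mutation catalogues.  Empty epochs are
    skipped with a log line."""
    epoch_of: dict[str, str] = {}
    for rec in clonality_records:
        if rec.in_mucosa:
            epoch_of[rec.mutation_id] = "precancer"
        elif rec.cancer_pattern == "truncal":
            epoch_of[rec.mutation_id] = "truncal"
        elif rec.cancer_pattern is not None:
            epoch_of[rec.mutation_id] = "branch"
    buckets: dict[str, list[MutationCall]] = {"precancer": [], "truncal": [], "branch": []}
    for call in calls:
        epoch = epoch_of.get(call.mutation_id)
        if epoch is not None:
            buckets[epoch].append(call)
    fits: dict[str, SignatureFit] = {}
    for epoch, bucket in buckets.items():
        catalogue = tally_96(bucket, label=epoch)
        if catalogue.total == 0:
            logger.info("fit_by_epoch: epoch %s has no substitutions, skipped", epoch)
            continue
        fits[epoch] = fit_exposures(catalogue, signatures, subset=subset)
    return fits
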