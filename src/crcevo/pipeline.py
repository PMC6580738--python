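"""End-to-end per-patient and cohort analysis from a single config.

``run_patient`` ties the stages together for one patient: SNA
parsimony tree with bootstrap and homoplasy index, clonality and field
statistics, per-epoch signature fits, copy-number burden, the binned
CNA tree, and the punctuation profile.  ``run_cohort`` adds the
cohort-level tables: gene-frequency comparisons, arm-level Fisher/BH
comparisons and burden-by-grade statistics.  All randomness is seeded
from the config, every stage that lacks its inputs is skipped with a
log line, and a JSON manifest records parameters, seeds and warnings
for provenance.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import clonality as clon
from . import cna as cnamod
from . import cnaphylo
from . import phylogeny as phylo
from . import signatures as sigmod
from .model import GenomeLayout, MutationCall, RegionSample, SignatureMatrix, TissueClass
from .tree import support_band

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_patient", "run_cohort"]


@dataclass
class RunConfig:
    """Paths and parameters for a pipeline run."""

    mutations: Optional[str] = None
    segments: Optional[str] = None
    segments_dialect: str = "allele_specific"
    layout: Optional[str] = None
    signatures: Optional[str] = None
    out_dir: str = "crcevo_out"
    detection_threshold: float = 0.05
    footprint_mb: float = clon.DEFAULT_FOOTPRINT_MB
    msi_threshold: float = clon.DEFAULT_MSI_THRESHOLD
    signature_subset: Optional[list[str]] = None
    bin_size: int = 500_000
    bootstrap: int = 100
    arm_fraction_threshold: float = 0.5
    seed: int = 0
    driver_genes: list[str] = field(default_factory=lambda: [
        "TP53", "KRAS", "APC", "PIK3CA", "FBXW7", "ARID1A",
    ])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def _load_inputs(config: RunConfig):
    calls, samples = ([], [])
    if config.mutations:
        calls, samples = cio.read_mutation_table(config.mutations)
    segments = cio.read_segments(config.segments, config.segments_dialect) \
        if config.segments else []
    layout = cio.read_genome_layout(config.layout) if config.layout else None
    signatures = cio.read_signature_matrix(config.signatures) \
        if config.signatures else None
    return calls, samples, segments, layout, signatures


def run_patient(
    config: RunConfig,
    patient_id: str,
    calls: Optional[Sequence[MutationCall]] = None,
    samples: Optional[Sequence[RegionSample]] = None,
    segments=None,
    layout: Optional[GenomeLayout] = None,
    signatures: Optional[SignatureMatrix] = None,
) -> dict:
    """Run all per-patient stages; returns the report bundle and writes
    it under ``out_dir/patient_id``.  Stages whose inputs are missing
    are skipped and recorded in the manifest."""
    if calls is None and samples is None:
        calls, samples, segments, layout, signatures = _load_inputs(config)
    calls = [c for c in calls or []]
    samples = [s for s in (samples or []) if s.patient_id == patient_id]
    sample_ids = {s.sample_id for s in samples}
    calls = [c for c in calls if c.sample_id in sample_ids]
    segments = [s for s in (segments or []) if s.sample_id in sample_ids]
    if not samples:
        raise ValueError(f"patient {patient_id} not present in inputs")

    out = Path(config.out_dir) / patient_id
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "patient_id": patient_id,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    report: dict = {"patient_id": patient_id, "manifest": manifest}
    roles = {s.sample_id: s.tissue_class for s in samples}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
            manifest["stages"][name] = {"status": "ok",
                                        "seconds": round(time.perf_counter() - t0, 3)}
            return result
        except (ValueError, KeyError) as exc:
            logger.warning("stage %s skipped for %s: %s", name, patient_id, exc)
            manifest["stages"][name] = {"status": "skipped", "reason": str(exc)}
            manifest["warnings"].append(f"{name}: {exc}")
            return None

    # --- SNA phylogeny ----------------------------------------------------
    def _sna_tree():
        matrix = phylo.build_character_matrix(calls, samples, config.detection_threshold)
        tree, stats = phylo.search_mp_tree(matrix, seed=config.seed)
        supports = phylo.bootstrap_support(matrix, b=config.bootstrap, seed=config.seed)
        phylo.apply_support(tree, supports)
        phylo.annotate_branches(tree, matrix, config.driver_genes)
        cio.write_newick(tree, out / "snv_tree.nwk")
        pd.DataFrame({
            "mutation_id": matrix.mutation_ids,
            "observed_changes": stats.per_char_changes,
            "min_changes": stats.per_char_min,
        }).to_csv(out / "snv_tree_characters.tsv", sep="\t", index=False)
        summary = {
            "score": stats.score,
            "consistency_index": stats.consistency_index,
            "homoplasy_index": stats.homoplasy_index,
            "supports": {",".join(sorted(k)): v for k, v in supports.items()},
            "bands": {",".join(sorted(k)): support_band(v) for k, v in supports.items()},
        }
        (out / "snv_tree_stats.json").write_text(json.dumps(summary, indent=2))
        return {"matrix": matrix, "tree": tree, "stats": stats, "supports": supports}

    sna = stage("snv_tree", _sna_tree)
    report["snv"] = sna

    # --- clonality --------------------------------------------------------
    def _clonality():
        matrix = sna["matrix"] if sna else phylo.build_character_matrix(
            calls, samples, config.detection_threshold)
        records = clon.classify_clonality(matrix, roles)
        overlap = clon.field_overlap_fraction(records)
        burdens = [clon.mutation_burden(calls, s.sample_id, config.footprint_mb,
                                        config.msi_threshold)
                   for s in samples if s.tissue_class == TissueClass.CARCINOMA]
        pd.DataFrame([{
            "mutation_id": r.mutation_id,
            "cancer_pattern": r.cancer_pattern or "",
            "in_mucosa": int(r.in_mucosa),
            "mucosa_only": int(r.mucosa_only),
        } for r in records]).to_csv(out / "clonality.tsv", sep="\t", index=False)
        pd.DataFrame([{
            "sample_id": b.sample_id,
            "n_nonsynonymous": b.n_nonsynonymous,
            "snas_per_mb": b.snas_per_mb,
            "msi_flag": int(b.msi_flag),
        } for b in burdens]).to_csv(out / "burden.tsv", sep="\t", index=False)
        return {"records": records, "field_overlap": overlap, "burdens": burdens}

    clonal = stage("clonality", _clonality)
    report["clonality"] = clonal

    # --- signatures -------------------------------------------------------
    def _signatures():
        if signatures is None:
            raise ValueError("no signature matrix provided")
        if not clonal:
            raise ValueError("clonality stage unavailable")
        fits = sigmod.fit_by_epoch(calls, clonal["records"], signatures,
                                   subset=config.signature_subset)
        rows = []
        for epoch, fit in fits.items():
            for name, exp, rel in zip(fit.signature_names, fit.exposures, fit.relative):
                rows.append({"epoch": epoch, "signature": name,
                             "exposure": exp, "relative": rel, "r_squared": fit.r_squared})
        pd.DataFrame(rows).to_csv(out / "signatures_by_epoch.tsv", sep="\t", index=False)
        return fits

    report["signatures"] = stage("signatures", _signatures)

    # --- copy-number burden ----------------------------------------------
    profiles = []
    if segments:
        by_sample: dict[str, list] = {}
        for s in segments:
            by_sample.setdefault(s.sample_id, []).append(s)
        dialect = config.segments_dialect
        profiles = [cnamod.CNProfile(sid, segs, dialect)
                    for sid, segs in by_sample.items()]

    def _cna_burden():
        if not profiles or layout is None:
            raise ValueError("no segments/layout available")
        rows = []
        arm_tables = []
        for profile in profiles:
            ploidy = cnamod.ploidy_summary(profile, layout)
            burden = cnamod.pga(profile, layout)
            arm_tables.append(cnamod.arm_calls(profile, layout,
                                               config.arm_fraction_threshold))
            rows.append({
                "sample_id": profile.sample_id,
                "psi": ploidy.psi, "ploidy_class": ploidy.ploidy_class,
                "pga_full": burden.pga_full, "pga_gl": burden.pga_gl,
                "frac_gain": burden.frac_gain, "frac_loss": burden.frac_loss,
                "frac_cnloh": burden.frac_cnloh,
            })
        df = pd.DataFrame(rows)
        df.to_csv(out / "cna_burden.tsv", sep="\t", index=False)
        pd.concat(arm_tables, ignore_index=True).to_csv(
            out / "arm_calls.tsv", sep="\t", index=False)
        return {"table": df, "arm_tables": arm_tables}

    report["cna_burden"] = stage("cna_burden", _cna_burden)

    # --- CNA phylogeny + punctuation -------------------------------------
    def _cna_tree():
        if not profiles or layout is None:
            raise ValueError("no segments/layout available")
        binned = cnaphylo.bin_profiles(profiles, layout, config.bin_size)
        tree, stats = cnaphylo.cna_tree(binned, seed=config.seed)
        supports = cnaphylo.cna_bootstrap(binned, b=config.bootstrap, seed=config.seed)
        phylo.apply_support(tree, supports)
        cio.write_newick(tree, out / "cna_tree.nwk")
        result = {"binned": binned, "tree": tree, "stats": stats, "supports": supports}
        try:
            profile = cnaphylo.punctuation_profile(tree, roles)
            (out / "punctuation.json").write_text(json.dumps({
                "trunk_changes": profile.trunk_changes,
                "mean_clade_changes": profile.mean_clade_changes,
                "punctuation_ratio": profile.punctuation_ratio,
                "n_clade_samples": profile.n_clade_samples,
                "low_confidence": profile.low_confidence,
            }, indent=2))
            result["punctuation"] = profile
        except ValueError as exc:
            manifest["warnings"].append(f"punctuation: {exc}")
        return result

    report["cna"] = stage("cna_tree", _cna_tree)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def run_cohort(
    config: RunConfig,
    cohort_labels: dict[str, str],
    calls: Optional[Sequence[MutationCall]] = None,
    samples: Optional[Sequence[RegionSample]] = None,
    segments=None,
    layout: Optional[GenomeLayout] = None,
    signatures: Optional[SignatureMatrix] = None,
) -> dict:
    """Cohort-level comparisons between the (exactly two) cohort labels
    in ``cohort_labels`` (patient id -> label): per-gene mutation
    frequency with Fisher/BH, arm-level frequency comparison, and
    burden-by-grade statistics over all samples."""
    if calls is None and samples is None:
        calls, samples, segments, layout, signatures = _load_inputs(config)
    calls = list(calls or [])
    samples = list(samples or [])
    segments = list(segments or [])
    patients = sorted({s.patient_id for s in samples})
    if len(patients) < 2:
        raise ValueError("cohort analysis needs >= 2 patients")
    labels = sorted(set(cohort_labels.values()))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"patients": patients}

    sample_patient = {s.sample_id: s.patient_id for s in samples}
    roles = {s.sample_id: s.tissue_class for s in samples}

    # --- gene frequencies -------------------------------------------------
    genes = sorted({c.gene for c in calls if c.gene})
    if genes:
        cohort_calls = {
            lab: [c for c in calls
                  if cohort_labels.get(sample_patient.get(c.sample_id)) == lab]
            for lab in labels
        }
        n_cases = {lab: len([p for p in patients if cohort_labels.get(p) == lab])
                   for lab in labels}
        freq = clon.gene_frequency_table(cohort_calls, n_cases, genes)
        freq.to_csv(out / "gene_frequencies.tsv", sep="\t", index=False)
        report["gene_frequencies"] = freq
        if len(labels) == 2 and all(n_cases[l] > 0 for l in labels):
            cmp = clon.compare_gene_frequencies(
                freq[freq.cohort == labels[0]], freq[freq.cohort == labels[1]])
            cmp.to_csv(out / "gene_comparison.tsv", sep="\t", index=False)
            report["gene_comparison"] = cmp
        else:
            logger.info("gene comparison skipped: need exactly two cohorts")

    # --- arm-level comparison and burden by grade -------------------------
    if segments and layout is not None:
        by_sample: dict[str, list] = {}
        for s in segments:
            by_sample.setdefault(s.sample_id, []).append(s)
        profiles = {sid: cnamod.CNProfile(sid, segs, config.segments_dialect)
                    for sid, segs in by_sample.items()}
        arm_tables = {sid: cnamod.arm_calls(p, layout, config.arm_fraction_threshold)
                      for sid, p in profiles.items()}
        if len(labels) == 2:
            grp = {lab: [arm_tables[sid] for sid in arm_tables
                         if cohort_labels.get(sample_patient.get(sid)) == lab]
                   for lab in labels}
            if all(grp[l] for l in labels):
                arm_cmp = cnamod.compare_arm_frequencies(grp[labels[0]], grp[labels[1]])
                arm_cmp.to_csv(out / "arm_comparison.tsv", sep="\t", index=False)
                report["arm_comparison"] = arm_cmp

        grade_groups: dict[str, list[float]] = {}
        for sid, profile in profiles.items():
            grade = roles.get(sid)
            if grade is None:
                continue
            burden = cnamod.pga(profile, layout)
            grade_groups.setdefault(grade.value, []).append(burden.pga_gl)
        if len(grade_groups) >= 2:
            report["burden_by_grade"] = cnamod.burden_by_grade(grade_groups)
            summary = {
                g: {"n": len(v), "median": float(np.median(v)),
                    "range": [float(min(v)), float(max(v))]}
                for g, v in grade_groups.items()
            }
            (out / "burden_by_grade.json").write_text(json.dumps({
                "groups": summary,
                "kruskal_wallis": {
                    "H": report["burden_by_grade"]["kruskal_wallis"].statistic,
                    "p": report["burden_by_grade"]["kruskal_wallis"].p,
                },
            }, indent=2))

    (out / "cohort_manifest.json").write_text(json.dumps({
        "config": config.to_dict(),
        "patients": patients,
        "cohorts": {lab: [p for p in patients if cohort_labels.get(p) == lab]
                    for lab in labels},
    }, indent=2, sort_keys=True))
    return report
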