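"""Clonality classification, field overlap, burden, CCF and gene tables."""

import math

import numpy as np
import pytest

from crcevo.clonality import (
    ClonalityRecord,
    classify_clonality,
    compare_gene_frequencies,
    convergent_genes,
    estimate_ccf,
    field_overlap_fraction,
    gene_frequency_table,
    mutation_burden,
    pool_frequencies,
    tp53_domain_class,
)
from crcevo.model import Effect, MutationCall, RegionSample, TissueClass
from crcevo.phylogeny import BinaryCharacterMatrix, build_character_matrix


def _matrix(rows, sample_ids):
    rows = np.asarray(rows, dtype=np.int8)
    mids = [f"m{j}" for j in range(rows.shape[1])]
    return BinaryCharacterMatrix(sample_ids, mids, rows)


ROLES = {
    "M": TissueClass.NORMAL_MUCOSA,
    "C1": TissueClass.CARCINOMA, "C2": TissueClass.CARCINOMA, "C3": TissueClass.CARCINOMA,
}
IDS = ["germline", "M", "C1", "C2", "C3"]


class TestClassify:
    def test_truncal_shared_private_mucosa_patterns(self):
        rows = [
            [0, 0, 0, 0],  # germline
            [0, 1, 0, 1],  # M
            [1, 1, 1, 0],  # C1
            [1, 0, 1, 0],  # C2
            [1, 0, 0, 0],  # C3
        ]
        recs = {r.mutation_id: r for r in classify_clonality(_matrix(rows, IDS), ROLES)}
        assert recs["m0"].cancer_pattern == "truncal" and not recs["m0"].in_mucosa
        assert recs["m1"].cancer_pattern == "private" and recs["m1"].in_mucosa
        assert recs["m2"].cancer_pattern == "shared_subclonal"
        assert recs["m3"].mucosa_only and recs["m3"].cancer_pattern is None

    def test_partition_property(self, clean_patient):
        """Every mutation in >=1 carcinoma is exactly one of
        truncal/shared/private."""
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        recs = classify_clonality(m, clean_patient.tissue_roles())
        carc = [i for i, s in enumerate(m.sample_ids)
                if clean_patient.tissue_roles().get(s) == TissueClass.CARCINOMA]
        for j, r in enumerate(recs):
            in_cancer = m.values[carc, j].any()
            assert (r.cancer_pattern is not None) == bool(in_cancer)

    def test_recovers_simulator_labels_noiselessly(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        recs = classify_clonality(m, clean_patient.tissue_roles())
        for r in recs:
            got = r.cancer_pattern or ("mucosa_only" if r.mucosa_only else "none")
            assert got == clean_patient.truth_clonality[r.mutation_id]

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError, match="role"):
            classify_clonality(_matrix([[0], [1], [1]], ["germline", "A", "B"]),
                               {"A": TissueClass.CARCINOMA})

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            ClonalityRecord("m", "truncal", True, mucosa_only=True)


class TestFieldOverlap:
    def test_quarter_overlap(self):
        recs = ([ClonalityRecord(f"t{i}", "truncal", i < 5, False) for i in range(20)])
        assert field_overlap_fraction(recs) == 0.25

    def test_zero_overlap(self):
        recs = [ClonalityRecord("t", "truncal", False, False)]
        assert field_overlap_fraction(recs) == 0.0

    def test_no_truncal_is_nan(self):
        assert math.isnan(field_overlap_fraction(
            [ClonalityRecord("p", "private", False, False)]))

    def test_simulator_overlap_matches_truth(self, clean_patient):
        m = build_character_matrix(clean_patient.calls, clean_patient.samples)
        recs = classify_clonality(m, clean_patient.tissue_roles())
        truth = clean_patient.truth_clonality
        truncal = [mid for mid, lab in truth.items() if lab == "truncal"]
        in_field = [mid for mid in truncal
                    if clean_patient.mutation_branch[mid] == "field"]
        assert field_overlap_fraction(recs) == pytest.approx(
            len(in_field) / len(truncal))


def _call(sid, pos, effect=Effect.MISSENSE, gene="", vaf=0.4, protein_pos=None):
    return MutationCall(sid, "chr1", pos, "C", "T", gene=gene, effect=effect,
                        vaf=vaf, protein_pos=protein_pos)


class TestBurden:
    def test_arithmetic(self):
        calls = [_call("S", i + 1) for i in range(50)] + \
                [_call("S", 100 + i, effect=Effect.SYNONYMOUS) for i in range(10)] + \
                [_call("S", 200 + i, effect=Effect.NONSENSE) for i in range(10)]
        b = mutation_burden(calls, "S", footprint_mb=30.0)
        assert b.n_nonsynonymous == 60
        assert b.snas_per_mb == pytest.approx(2.0)
        assert not b.msi_flag

    def test_hypermutated_flagged(self):
        # 33 SNAs/Mb-scale burden trips the MSI-like flag (threshold 10).
        calls = [_call("S", i + 1) for i in range(990)]
        b = mutation_burden(calls, "S", footprint_mb=30.0)
        assert b.snas_per_mb == pytest.approx(33.0)
        assert b.msi_flag

    def test_no_calls(self):
        b = mutation_burden([], "S", footprint_mb=30.0)
        assert b.snas_per_mb == 0.0

    def test_bad_footprint(self):
        with pytest.raises(ValueError):
            mutation_burden([], "S", footprint_mb=0.0)


class TestCCF:
    def test_half_purity_diploid_clonal(self):
        est = estimate_ccf(_call("S", 1, vaf=0.25), purity=0.5, cn_total=2, cn_major=1)
        assert est.multiplicity == 1
        assert est.ccf == pytest.approx(1.0)

    def test_pure_diploid_heterozygous(self):
        est = estimate_ccf(_call("S", 1, vaf=0.5), purity=1.0, cn_total=2, cn_major=1)
        assert est.ccf == pytest.approx(1.0)

    def test_subclonal_half(self):
        est = estimate_ccf(_call("S", 1, vaf=0.25), purity=1.0, cn_total=2, cn_major=1)
        assert est.ccf == pytest.approx(0.5)

    def test_clonal_heterozygous_closed_form_all_purities(self):
        """vaf = p/(2p + 2(1-p)) = p/2 gives CCF 1 for any purity."""
        for purity in np.linspace(0.05, 1.0, 20):
            vaf = purity / 2
            est = estimate_ccf(_call("S", 1, vaf=vaf), purity=float(purity),
                               cn_total=2, cn_major=1)
            assert est.ccf == pytest.approx(1.0, abs=1e-9)

    def test_multiplicity_capped_by_major(self):
        est = estimate_ccf(_call("S", 1, vaf=0.9), purity=1.0, cn_total=4, cn_major=3)
        assert 1 <= est.multiplicity <= 3

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(_call("S", 1, vaf=0.2), purity=0.0, cn_total=2, cn_major=1)


class TestConvergence:
    def test_triple_hit_gene_flagged(self):
        calls = [_call("S", p, gene="TP53") for p in (100, 200, 300)]
        ccfs = {c.mutation_id: 0.9 for c in calls}
        out = convergent_genes(calls, ccfs)
        assert out == {"TP53": 3}

    def test_subclonal_second_hit_not_flagged(self):
        calls = [_call("S", 100, gene="TP53"), _call("S", 200, gene="TP53")]
        ccfs = {calls[0].mutation_id: 0.9, calls[1].mutation_id: 0.3}
        assert convergent_genes(calls, ccfs) == {}

    def test_empty_input(self):
        assert convergent_genes([], {}) == {}


class TestTP53Domain:
    @pytest.mark.parametrize("codon,expected", [
        (245, "DNA_binding"),   # exon-7 hotspot
        (306, "other"),         # p.R306X lies outside the domain
        (102, "DNA_binding"),   # inclusive boundary
        (292, "DNA_binding"),
        (293, "other"),
    ])
    def test_domain_boundaries(self, codon, expected):
        assert tp53_domain_class(codon) == expected


class TestGeneFrequencies:
    def test_fraction_and_pooling(self):
        calls_a = [_call(f"P{i}_C1", 10 + i, gene="TP53") for i in range(8)]
        table_a = gene_frequency_table({"A": calls_a}, {"A": 10}, ["TP53"])
        assert table_a.iloc[0]["fraction"] == pytest.approx(0.8)
        table_b = gene_frequency_table(
            {"B": [_call(f"Q{i}_C1", 50 + i, gene="TP53") for i in range(16)]},
            {"B": 30}, ["TP53"])
        pooled = pool_frequencies([table_a, table_b])
        assert pooled.iloc[0]["n_mutated"] == 24
        assert pooled.iloc[0]["n_cases"] == 40
        assert pooled.iloc[0]["fraction"] == pytest.approx(0.6)

    def test_absent_gene_zero(self):
        table = gene_frequency_table({"A": []}, {"A": 5}, ["APC"])
        assert table.iloc[0]["fraction"] == 0.0

    def test_comparison_uses_fisher_and_bh(self):
        ta = gene_frequency_table(
            {"A": [_call(f"P{i}_C1", 10 + i, gene="TP53") for i in range(9)]},
            {"A": 10}, ["TP53", "APC"])
        tb = gene_frequency_table(
            {"B": [_call(f"Q{i}_C1", 50 + i, gene="TP53") for i in range(1)]},
            {"B": 10}, ["TP53", "APC"])
        cmp = compare_gene_frequencies(ta, tb)
        assert set(cmp["gene"]) == {"TP53", "APC"}
        row = cmp[cmp.gene == "TP53"].iloc[0]
        assert row["p"] < 0.01
        assert "q" in cmp.columns
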