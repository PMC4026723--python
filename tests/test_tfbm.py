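"""Consensus-index weighting, similarity scoring, scanning, and tiers."""

import io

import numpy as np
import pytest

import cpg_descent as cd
from cpg_descent.errors import DataError
from cpg_descent.tfbm import MotifHit, reverse_complement


def single_base_pwm(consensus: str, matrix_id="M1", family="F1"):
    counts = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 10
    return cd.PositionWeightMatrix(matrix_id, family, counts)


class TestConsensusIndex:
    def test_uniform_column_zero(self):
        assert cd.consensus_index(np.array([[0.25] * 4]))[0] == pytest.approx(0.0)

    def test_single_base_column_100(self):
        assert cd.consensus_index(np.array([[1.0, 0, 0, 0]]))[0] == pytest.approx(100.0)

    def test_intermediate_columns_strictly_between(self):
        ci = cd.consensus_index(np.array([[0.7, 0.1, 0.1, 0.1], [0.5, 0.5, 0, 0]]))
        assert np.all(ci > 0) and np.all(ci < 100)

    def test_core_is_max_ci_run(self):
        # conserved CGCG block in the middle, uniform elsewhere
        counts = np.full((8, 4), 5.0)
        for i, b in zip(range(2, 6), "CGCG"):
            counts[i] = 0
            counts[i, "ACGT".index(b)] = 20
        pwm = cd.PositionWeightMatrix("M", "F", counts)
        assert pwm.core_start == 2


class TestSimilarity:
    def test_consensus_scores_one(self):
        pwm = single_base_pwm("ACGTAC")
        assert cd.matrix_similarity(pwm, "ACGTAC") == pytest.approx(1.0)
        assert cd.core_similarity(pwm, "ACGTAC") == pytest.approx(1.0)

    def test_all_uniform_matrix_scores_zero(self):
        pwm = cd.PositionWeightMatrix("M", "F", np.full((4, 4), 5.0))
        assert cd.matrix_similarity(pwm, "ACGT") == 0.0

    def test_uniform_column_never_affects_score(self):
        counts = np.zeros((5, 4))
        for i, b in enumerate("ACGTA"):
            counts[i, "ACGT".index(b)] = 8
        counts[2] = [2, 2, 2, 2]  # uniform -> Ci = 0
        pwm = cd.PositionWeightMatrix("M", "F", counts)
        assert cd.matrix_similarity(pwm, "ACATA") == pytest.approx(
            cd.matrix_similarity(pwm, "ACCTA")
        )

    def test_mixed_column_example(self):
        # col1 all-A (Ci=100), cols 2-4 uniform (Ci=0): only col1 counts
        counts = np.array([[9.0, 0, 0, 0]] + [[1.0, 1, 1, 1]] * 3)
        pwm = cd.PositionWeightMatrix("M", "F", counts)
        assert cd.matrix_similarity(pwm, "CAAA") == pytest.approx(0.0)
        assert cd.matrix_similarity(pwm, "ACGT") == pytest.approx(1.0)

    def test_core_mismatch_zeroes_that_term(self):
        pwm = single_base_pwm("AAAA")
        # single mismatch in a 4-wide all-core matrix: 3 of 4 equal columns
        assert cd.core_similarity(pwm, "AATA") == pytest.approx(0.75)

    def test_mismatch_outside_core_leaves_core_sim_at_one(self):
        counts = np.full((6, 4), 2.0)
        for i, b in zip(range(1, 5), "CGCG"):
            counts[i] = 0
            counts[i, "ACGT".index(b)] = 20
        pwm = cd.PositionWeightMatrix("M", "F", counts)
        assert pwm.core_start == 1
        assert cd.core_similarity(pwm, "TCGCGT") == pytest.approx(1.0)

    def test_length_mismatch_and_bad_alphabet_rejected(self):
        pwm = single_base_pwm("ACGT")
        with pytest.raises(DataError):
            cd.matrix_similarity(pwm, "ACG")
        with pytest.raises(DataError):
            cd.matrix_similarity(pwm, "ACGN")


def make_window(insert: str, at: int) -> str:
    """122-bp A/T background with CG at 61-62 and ``insert`` at 1-based ``at``."""
    base = list("AT" * 61)
    base[60], base[61] = "C", "G"
    for i, b in enumerate(insert):
        base[at - 1 + i] = b
    return "".join(base)


class TestScanWindow:
    def test_cg_consensus_hit_overlaps_focal_cpg(self):
        pwm = single_base_pwm("ACGT")
        window = make_window("ACGT", 60)  # CG lands on columns 61-62
        hits = cd.scan_window(pwm, window, site_id="cg01")
        overlapping = [h for h in hits if h.overlaps_cpg]
        assert any(h.strand == "+" and h.start == 60 for h in overlapping)
        for h in hits:
            assert 0.0 <= h.mat_sim <= 1.0

    def test_wrong_window_length_rejected(self):
        with pytest.raises(DataError, match="window length"):
            cd.scan_window(single_base_pwm("ACGT"), "ACGT")

    def test_impossible_threshold_empty(self):
        pwm = single_base_pwm("ACGT")
        window = make_window("ACGT", 10)
        assert cd.scan_window(pwm, window, mat_threshold=1.1) == []

    def test_palindrome_deduplicated_keeping_plus_strand(self):
        pwm = single_base_pwm("CATG")  # reverse complement of itself
        window = make_window("CATG", 30)
        hits = [h for h in cd.scan_window(pwm, window) if h.start == 30]
        assert len(hits) == 1 and hits[0].strand == "+"

    def test_reverse_complement_symmetry(self):
        pwm = single_base_pwm("AACGTT")
        window = make_window("AACGTT", 20)
        hits_fwd = cd.scan_window(pwm, window)
        hits_rc = cd.scan_window(pwm.reverse_complement(), window)
        assert {(h.start, h.end) for h in hits_fwd} == {
            (h.start, h.end) for h in hits_rc
        }

    def test_minus_strand_coordinates_are_plus_strand(self):
        pwm = single_base_pwm("AAAC")
        # plant the reverse complement GTTT at 1-based 40..43
        window = make_window("GTTT", 40)
        minus = [h for h in cd.scan_window(pwm, window) if h.strand == "-"]
        assert any(h.start == 40 and h.end == 43 for h in minus)


class TestTiers:
    def hit(self, mat_sim, site="cg01", family="F1"):
        return MotifHit("M1", family, site, "+", 60, 63, mat_sim, 1.0, True)

    def test_tier_counts_monotone_non_increasing(self):
        rng = np.random.default_rng(2)
        hits = [self.hit(x) for x in rng.uniform(0.5, 1.0, size=50)] + [
            self.hit(1.0) for _ in range(3)
        ]
        summary = cd.tier_and_summarize(hits)
        values = [summary.tier_hits[t] for t in (">0.80", ">0.90", ">0.95", "=1")]
        assert values == sorted(values, reverse=True)
        for t in summary.tier_hits:
            assert summary.tier_sites[t] <= summary.tier_hits[t]

    def test_non_overlapping_hits_excluded(self):
        h = MotifHit("M1", "F1", "cg01", "+", 1, 4, 1.0, 1.0, False)
        summary = cd.tier_and_summarize([h])
        assert summary.tier_hits["=1"] == 0

    def test_tier1_grouped_by_branch_and_family(self):
        hits = [self.hit(1.0, "cg01", "famA"), self.hit(1.0, "cg02", "famB")]
        summary = cd.tier_and_summarize(hits, {"cg01": "ape", "cg02": "primate"})
        assert summary.tier1_by_family == {"famA": 1, "famB": 1}
        assert summary.tier1_by_branch == {"ape": 1, "primate": 1}


class TestTier1Fixture:
    def test_packaged_table_summary(self):
        df = cd.load_tier1_fixture()
        summary = cd.summarize_tier1_table(df)
        assert summary["n_records"] == 22
        assert summary["n_unique_sites"] == 21
        assert summary["n_families"] == 9
        assert summary["branch_counts"] == {
            "human_terminal": 2,
            "human_chimp": 5,
            "ape": 6,
            "primate": 5,
            "placental": 2,
            "theria": 2,
        }


class TestTransfacIO:
    TEXT = """\
ID M001
NA family one
P0 A C G T
01 10 0 0 0
02 0 10 0 0
03 0 0 10 0
04 0 0 0 10
//
ID M002
NA family two
01 1 1 1 1
02 8 0 0 0
03 0 8 0 0
04 0 0 8 0
05 0 0 0 8
//
"""

    def test_read_parses_ids_families_counts(self):
        pwms = cd.read_transfac(io.StringIO(self.TEXT))
        assert [p.matrix_id for p in pwms] == ["M001", "M002"]
        assert pwms[0].family == "family one"
        assert pwms[0].consensus == "ACGT"
        assert pwms[1].width == 5

    def test_round_trip(self, tmp_path):
        pwms = cd.read_transfac(io.StringIO(self.TEXT))
        path = tmp_path / "m.transfac"
        from cpg_descent.tfbm import write_transfac

        write_transfac(pwms, path)
        again = cd.read_transfac(path)
        assert [p.matrix_id for p in again] == [p.matrix_id for p in pwms]
        assert np.allclose(again[0].counts, pwms[0].counts)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            cd.read_transfac(io.StringIO(""))


def test_revcomp_helper():
    assert reverse_complement("ACGT") == "ACGT"
    assert reverse_complement("AACG") == "CGTT"


def test_appending_uniform_columns_preserves_mat_sim():
    pwm = single_base_pwm("ACGT")
    counts = np.vstack([pwm.counts, np.full((2, 4), 3.0)])
    extended = cd.PositionWeightMatrix("M2", "F", counts)
    assert cd.matrix_similarity(extended, "ACGTTT") == pytest.approx(
        cd.matrix_similarity(pwm, "ACGT")
    )
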