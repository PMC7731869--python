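import math

import numpy as np
import pandas as pd
import pytest

from exodys.exonscan import (
    SelectionConfig,
    exon_zscores,
    permutation_null,
    scale_within_transcript,
    scan,
    select_exons,
)
from exodys.samples import SampleSheet

from conftest import random_scan_instance
from oracle import oracle_select


def _one_transcript(counts_per_sample: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(counts_per_sample.values())))
    return pd.DataFrame(counts_per_sample, index=[f"e{i}" for i in range(n)])


class TestScaling:
    def test_population_sd_hand_example(self):
        counts = _one_transcript({"s1": [10, 20, 30]})
        scaled = scale_within_transcript(counts, {f"e{i}": "t1" for i in range(3)})
        # sigma = sqrt(200/3)
        expected = np.array([-1.2247449, 0.0, 1.2247449])
        assert np.allclose(scaled["s1"].to_numpy(), expected, atol=1e-6)
        assert scaled["s1"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_sample_sd_mode(self):
        counts = _one_transcript({"s1": [10, 20, 30]})
        scaled = scale_within_transcript(
            counts, {f"e{i}": "t1" for i in range(3)}, sd_mode="sample"
        )
        assert np.allclose(scaled["s1"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_zero_variance_transcript_excluded(self):
        counts = _one_transcript({"s1": [5, 5, 5], "s2": [1, 2, 3]})
        scaled = scale_within_transcript(counts, {f"e{i}": "t1" for i in range(3)})
        assert scaled["s1"].isna().all()
        assert scaled["s2"].notna().all()

    def test_single_exon_transcript_undefined(self):
        counts = pd.DataFrame({"s1": [7]}, index=["e0"])
        scaled = scale_within_transcript(counts, {"e0": "t1"})
        assert scaled["s1"].isna().all()


class TestZScores:
    def test_unit_reference(self, small_sheet):
        scaled = pd.DataFrame(
            [[-1.0, 0.0, 1.0, 4.2, 0.0, -1.0]],
            index=["e0"], columns=small_sheet.sample_ids,
        )
        z = exon_zscores(scaled, small_sheet)
        assert z.loc["e0", "p1"] == pytest.approx(4.2)
        assert z.loc["e0", "p2"] == pytest.approx(0.0)

    def test_zero_control_sd_excluded(self, small_sheet):
        scaled = pd.DataFrame(
            [[0.0, 0.0, 0.0, 1.0, 2.0, 3.0]],
            index=["e0"], columns=small_sheet.sample_ids,
        )
        z = exon_zscores(scaled, small_sheet)
        assert z.loc["e0"].isna().all()


class TestSelection:
    def _z(self, values):
        return pd.DataFrame([values], index=["e0"],
                            columns=[f"p{i}" for i in range(len(values))])

    def test_five_cases_above_threshold_selected_up(self):
        z = self._z([4.5, 5.0, 6.0, 4.1, 4.2, 0.3])
        result = select_exons(z, pd.Series({"e0": 60}), SelectionConfig())
        assert result.selected_up == ["e0"]

    def test_control_reads_filter_is_strict(self):
        z = self._z([10.0] * 6)
        result = select_exons(z, pd.Series({"e0": 50}), SelectionConfig())
        assert result.n_selected == 0
        assert "e0" in result.excluded["read_filter"]

    def test_four_cases_not_enough(self):
        z = self._z([4.5, 4.5, 4.5, 4.5, 0.0, 0.0])
        result = select_exons(z, pd.Series({"e0": 60}), SelectionConfig())
        assert result.n_selected == 0

    def test_both_directions_reported_ambiguous(self):
        z = self._z([5.0] * 5 + [-5.0] * 5)
        config = SelectionConfig(min_cases=5)
        result = select_exons(z, pd.Series({"e0": 60}), config)
        assert result.ambiguous == ["e0"]
        assert result.n_selected == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_thresholds(self, seed):
        rng = np.random.default_rng(seed)
        counts, transcript_of, sheet = random_scan_instance(rng)
        base = SelectionConfig(min_control_reads=5, z_threshold=0.8, min_cases=1)
        n_base = scan(counts, transcript_of, sheet, base).n_selected
        for config in (
            SelectionConfig(min_control_reads=5, z_threshold=1.5, min_cases=1),
            SelectionConfig(min_control_reads=5, z_threshold=0.8, min_cases=2),
            SelectionConfig(min_control_reads=9, z_threshold=0.8, min_cases=1),
        ):
            assert scan(counts, transcript_of, sheet, config).n_selected <= n_base


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(25))
    def test_scan_matches_bruteforce(self, seed):
        rng = np.random.default_rng(1000 + seed)
        counts, transcript_of, sheet = random_scan_instance(rng)
        config = SelectionConfig(min_control_reads=10, z_threshold=1.3, min_cases=2)
        result = scan(counts, transcript_of, sheet, config)
        counts_dict = {e: counts.loc[e].to_dict() for e in counts.index}
        up, down, ambiguous = oracle_select(
            counts_dict, transcript_of, sheet.controls, sheet.cases,
            min_control_reads=10, z_threshold=1.3, min_cases=2,
        )
        assert set(result.selected_up) == up
        assert set(result.selected_down) == down
        assert set(result.ambiguous) == ambiguous


class TestPermutationNull:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(42)
        sheet = SampleSheet(
            sample_ids=["c1", "c2", "c3", "p1", "p2", "p3"],
            conditions=["control"] * 3 + ["case"] * 3,
        )
        exons = [f"e{i}" for i in range(12)]
        transcript_of = {e: f"t{i // 4}" for i, e in enumerate(exons)}
        counts = pd.DataFrame(
            rng.integers(20, 120, size=(12, 6)), index=exons,
            columns=sheet.sample_ids,
        )
        return counts, transcript_of, sheet

    def test_exhaustive_enumerates_all_labelings(self, toy):
        counts, transcript_of, sheet = toy
        config = SelectionConfig(min_control_reads=10, z_threshold=1.0, min_cases=1)
        null = permutation_null(counts, transcript_of, sheet, config, exhaustive=True)
        assert null.n_permutations == math.comb(6, 3) == 20
        # identity labeling is the first enumerated assignment
        assert null.null_counts[0] == null.observed
        # plug-in p-value equals the count-based fraction
        expected_p = sum(c >= null.observed for c in null.null_counts) / 20
        assert null.p_value == pytest.approx(expected_p)

    def test_observed_zero_gives_p_one(self, toy):
        counts, transcript_of, sheet = toy
        config = SelectionConfig(min_control_reads=10**6, z_threshold=4.0, min_cases=3)
        null = permutation_null(counts, transcript_of, sheet, config,
                                n_permutations=30, seed=1)
        assert null.observed == 0
        assert null.p_value == 1.0

    def test_seeded_determinism(self, toy):
        counts, transcript_of, sheet = toy
        config = SelectionConfig(min_control_reads=10, z_threshold=1.0, min_cases=1)
        a = permutation_null(counts, transcript_of, sheet, config,
                             n_permutations=40, seed=9)
        b = permutation_null(counts, transcript_of, sheet, config,
                             n_permutations=40, seed=9)
        assert np.array_equal(a.null_counts, b.null_counts)
        assert a.p_value == b.p_value

    def test_add_one_convention(self, toy):
        counts, transcript_of, sheet = toy
        config = SelectionConfig(min_control_reads=10, z_threshold=1.0, min_cases=1)
        null = permutation_null(counts, transcript_of, sheet, config,
                                n_permutations=40, seed=9,
                                p_convention="add_one")
        r = int((null.null_counts >= null.observed).sum())
        assert null.p_value == pytest.approx((r + 1) / 41)


class TestScanReporting:
    def test_table_flags_and_summary_consistency(self, small_sheet):
        rng = np.random.default_rng(5)
        counts, transcript_of, sheet = random_scan_instance(rng)
        config = SelectionConfig(min_control_reads=5, z_threshold=1.0, min_cases=1)
        result = scan(counts, transcript_of, sheet, config)
        summary = result.summary()
        assert summary["n_selected"] == (
            summary["n_up"] + summary["n_down"] + summary["n_ambiguous"]
        )
        assert set(result.selected_up).isdisjoint(result.selected_down)
        table = result.table
        assert set(table.index) == set(counts.index)
        assert (table.loc[result.selected_up, "status"] == "up").all()
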