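"""Normalization, pairwise matrices, valid-value filtering, exclusivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings, strategies as st

from phoscale import preprocess as pp
from phoscale.errors import DesignError, NormalizationError
from phoscale.io import SampleDesign, default_design


def frame_from(values, samples):
    return pd.DataFrame(np.asarray(values, dtype=float), columns=samples)


class TestNormalize:
    def test_hand_computed_medians(self):
        # log2 values A {10,20,30}, B {12,22,32}; medians 20, 22; grand 21
        raw = frame_from([[2**10, 2**12], [2**20, 2**22], [2**30, 2**32]], ["A", "B"])
        out = pp.log2_median_normalize(raw)
        assert out["A"].tolist() == [11.0, 21.0, 31.0]
        assert out["B"].tolist() == [11.0, 21.0, 31.0]

    def test_fixed_point_when_medians_equal(self):
        raw = frame_from([[2**10, 2**11], [2**20, 2**20], [2**30, 2**29]], ["A", "B"])
        out = pp.log2_median_normalize(raw)
        np.testing.assert_allclose(out.to_numpy(), np.log2(raw.to_numpy()))

    def test_single_cell(self):
        out = pp.log2_median_normalize(frame_from([[2**7.5]], ["A"]))
        assert out.iloc[0, 0] == pytest.approx(7.5)

    def test_all_missing_sample_raises(self):
        raw = frame_from([[1024.0, np.nan]], ["A", "B"])
        with pytest.raises(NormalizationError, match="B"):
            pp.log2_median_normalize(raw)

    def test_median_equality_exact(self):
        rng = np.random.default_rng(3)
        raw = frame_from(2 ** rng.normal(20, 2, size=(51, 6)), list("ABCDEF"))
        raw.iloc[rng.random((51, 6)) < 0.2] = np.nan
        out = pp.log2_median_normalize(raw)
        meds = out.median(axis=0, skipna=True)
        assert np.allclose(meds, meds.iloc[0], atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_shift_equivariance(self, shift):
        """Multiplying one sample's raw values by 2^c changes the output at
        most by a common additive constant (when the grand median moves);
        fold changes are therefore invariant."""
        rng = np.random.default_rng(7)
        raw = frame_from(2 ** rng.normal(20, 2, size=(11, 3)), ["A", "B", "C"])
        shifted = raw.copy()
        shifted["B"] = shifted["B"] * (2.0**shift)
        diff = (
            pp.log2_median_normalize(shifted).to_numpy()
            - pp.log2_median_normalize(raw).to_numpy()
        )
        np.testing.assert_allclose(diff, diff.flat[0], atol=1e-9)


class TestBuildPairMatrix:
    def test_full_design_24_columns(self, full_design):
        frame = pd.DataFrame(
            np.ones((2, len(full_design))), columns=[d.sample_id for d in full_design]
        )
        m = pp.build_pair_matrix(frame, full_design, ("bic", "5min"))
        assert m.frame.shape == (2, 24)
        # ordered lexicographically by (arm, bio_rep, tech_rep): control first
        assert list(m.columns["arm"][:12]) == ["control"] * 12
        assert list(m.columns["bio_rep"][:6]) == [1, 1, 1, 2, 2, 2]

    def test_missing_tech_rep_23_columns(self, full_design):
        design = [d for d in full_design if not (d.sample_id == "bic_5min_b1_t3")]
        frame = pd.DataFrame(np.ones((1, len(design))), columns=[d.sample_id for d in design])
        m = pp.build_pair_matrix(frame, design, ("bic", "5min"))
        assert m.frame.shape[1] == 23

    def test_condition_partition(self, full_design):
        frame = pd.DataFrame(
            np.ones((1, len(full_design))), columns=[d.sample_id for d in full_design]
        )
        m = pp.build_pair_matrix(frame, full_design, ("bic", "5min"))
        assert not any(s.startswith("ttx") for s in m.frame.columns)
        assert all(("5min" in s) for s in m.frame.columns)

    def test_no_controls_raises(self, full_design):
        design = [d for d in full_design if d.treatment != "control"]
        frame = pd.DataFrame(np.ones((1, len(design))), columns=[d.sample_id for d in design])
        with pytest.raises(DesignError):
            pp.build_pair_matrix(frame, design, ("bic", "5min"))


def _pattern_matrix(patterns, pair_design):
    """events x 24 matrix from boolean observation patterns (column order
    (arm, bio, tech) as build_pair_matrix produces)."""
    frame = pd.DataFrame(
        np.where(np.asarray(patterns, dtype=bool), 20.0, np.nan),
        columns=[d.sample_id for d in pair_design],
    )
    return pp.build_pair_matrix(frame, pair_design, ("bic", "5min"))


def _clause_a(pattern):
    """Independent truth-table evaluation of the bio-coverage clause."""
    pattern = np.asarray(pattern, dtype=bool)
    for arm in (0, 1):  # control cols 0-11, treated cols 12-23
        for b in range(4):
            if not pattern[arm * 12 + b * 3 : arm * 12 + b * 3 + 3].any():
                return False
    return True


class TestValidValueFilter:
    def test_kept_event(self, pair_design):
        pattern = [True] * 12 + [True, False, False] * 4  # 14/24 present, all bio covered
        m = _pattern_matrix([pattern], pair_design)
        out, report = pp.valid_value_filter(m)
        assert len(out.frame) == 1 and report.n_out == 1

    def test_three_of_four_bio_reps_dropped(self, pair_design):
        pattern = [True] * 12 + [True] * 9 + [False] * 3  # treated bio rep 4 empty
        m = _pattern_matrix([pattern], pair_design)
        out, report = pp.valid_value_filter(m)
        assert len(out.frame) == 0
        assert report.n_fail_bio_coverage == 1

    def test_minimal_coverage_fails_half_rule(self, pair_design):
        # clause (a) satisfied with 1 tech rep per (arm, bio): 8 cells; add 3
        # more -> 11/24 = 46% < 50% -> dropped by (b) alone
        pattern = np.zeros(24, dtype=bool)
        pattern[[0, 3, 6, 9, 12, 15, 18, 21]] = True  # minimal (a) pattern
        pattern[[1, 4, 7]] = True
        m = _pattern_matrix([pattern], pair_design)
        out, report = pp.valid_value_filter(m)
        assert len(out.frame) == 0
        assert report.n_fail_half_valid == 1 and report.n_fail_bio_coverage == 0

    def test_against_truth_table_on_enumerated_patterns(self, pair_design):
        """200 seeded random patterns vs an independent clause evaluation."""
        rng = np.random.default_rng(202)
        patterns = rng.random((200, 24)) < rng.uniform(0.2, 0.95, (200, 1))
        m = _pattern_matrix(patterns, pair_design)
        out, _ = pp.valid_value_filter(m)
        kept = set(out.frame.index)
        for i, pattern in enumerate(patterns):
            expect = _clause_a(pattern) and pattern.sum() >= 12
            assert (i in kept) == bool(expect), f"pattern {i}"

    @settings(
        max_examples=60, deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture]
    )
    @given(data=st.data())
    def test_monotone_in_observations(self, pair_design, data):
        """Adding an observed cell can never turn kept into dropped."""
        pattern = np.array(data.draw(st.lists(st.booleans(), min_size=24, max_size=24)))
        add = data.draw(st.integers(0, 23))
        grown = pattern.copy()
        grown[add] = True
        m1 = _pattern_matrix([pattern], pair_design)
        m2 = _pattern_matrix([grown], pair_design)
        kept1 = len(pp.valid_value_filter(m1)[0].frame)
        kept2 = len(pp.valid_value_filter(m2)[0].frame)
        assert kept2 >= kept1


class TestDetectExclusive:
    def _frame(self, observed_groups, design, reliable=True):
        """Event observed in all 4 bio reps of each group in observed_groups
        (one tech rep), and in 3 bio reps of groups given as (group, 3)."""
        cols = [d.sample_id for d in design]
        row = {c: np.nan for c in cols}
        for entry in observed_groups:
            group, n_bio = entry if isinstance(entry[0], tuple) else (entry, 4)
            for d in design:
                if (d.treatment, d.timepoint) == group and d.tech_rep == 1 and d.bio_rep <= n_bio:
                    row[d.sample_id] = 20.0
        return pd.DataFrame([row], columns=cols)

    def test_exclusive_in_one_condition(self, full_design):
        frame = self._frame(
            [("bic", "24h"), (("control", "24h"), 3), (("ttx", "24h"), 2)], full_design
        )
        out = pp.detect_exclusive(frame, full_design)
        assert out == [(0, ("bic", "24h"))]

    def test_reliable_in_two_conditions_not_exclusive(self, full_design):
        frame = self._frame([("bic", "24h"), ("ttx", "24h")], full_design)
        assert pp.detect_exclusive(frame, full_design) == []

    def test_nowhere_reliable_not_exclusive(self, full_design):
        frame = self._frame([(("bic", "24h"), 3)], full_design)
        assert pp.detect_exclusive(frame, full_design) == []

    def test_strict_mode_requires_zero_detection_elsewhere(self, full_design):
        frame = self._frame([("bic", "24h"), (("ttx", "24h"), 1)], full_design)
        assert pp.detect_exclusive(frame, full_design) == [(0, ("bic", "24h"))]
        assert pp.detect_exclusive(frame, full_design, strict=True) == []

    def test_exclusive_disjoint_from_tested(self, full_design):
        """An exclusive event can never pass the valid-value filter for any
        condition (its controls are unreliable by construction)."""
        frame = self._frame([("bic", "24h")], full_design)
        assert pp.detect_exclusive(frame, full_design) == [(0, ("bic", "24h"))]
        for c in pp.CONDITIONS:
            m = pp.build_pair_matrix(frame, full_design, c)
            out, _ = pp.valid_value_filter(m)
            assert len(out.frame) == 0
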