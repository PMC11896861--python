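"""Delphi statistics: authority coefficient, Kendall's W, screening, report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from access5a.delphi import (
    ExpertProfile,
    ExpertRatingRound,
    authority_coefficient,
    consultation_report,
    kendalls_w,
    screen_indicators,
)
from oracles import kendalls_w_bruteforce


def make_round(matrix, round_number=1, prefix="I"):
    arr = np.asarray(matrix)
    return ExpertRatingRound(
        round_number=round_number,
        ratings=pd.DataFrame(
            arr,
            index=[f"e{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        ),
    )


class TestAuthorityCoefficient:
    @pytest.mark.parametrize(
        "ca, cs, expected",
        [(0.91, 0.85, 0.88), (0.96, 0.90, 0.93), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0)],
    )
    def test_published_and_boundary_values(self, ca, cs, expected):
        assert authority_coefficient(ca, cs) == pytest.approx(expected)

    @pytest.mark.parametrize("ca, cs", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, ca, cs):
        with pytest.raises(ValueError):
            authority_coefficient(ca, cs)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        ca=st.floats(0, 1, allow_nan=False),
        cs=st.floats(0, 1, allow_nan=False),
        bump=st.floats(0.001, 0.5),
    )
    def test_symmetric_and_monotone(self, ca, cs, bump):
        assert authority_coefficient(ca, cs) == authority_coefficient(cs, ca)
        higher = min(1.0, ca + bump)
        assert authority_coefficient(higher, cs) >= authority_coefficient(ca, cs)

    def test_profile_exposes_cr(self):
        assert ExpertProfile("e1", 0.91, 0.85).cr == pytest.approx(0.88)


class TestKendallsW:
    def test_identical_rankings_give_unity(self):
        rnd = make_round([[1, 2, 3, 4, 5]] * 3)
        assert kendalls_w(rnd).W == pytest.approx(1.0)

    def test_matches_bruteforce_on_seeded_matrices(self):
        rng = np.random.default_rng(2024)
        for m, n in [(4, 4), (20, 10), (7, 6)]:
            matrix = rng.integers(1, 6, size=(m, n))
            rnd = make_round(matrix)
            for tie_correction in (True, False):
                if not tie_correction and (matrix.std(axis=1) == 0).any():
                    continue
                res = kendalls_w(rnd, tie_correction=tie_correction)
                assert res.W == pytest.approx(
                    kendalls_w_bruteforce(matrix, tie_correction), abs=1e-9
                )

    def test_chi2_identity_without_tie_correction(self):
        rng = np.random.default_rng(5)
        # permutation rows: tie-free rankings
        matrix = np.vstack([rng.permutation(5) + 1 for _ in range(6)])
        res = kendalls_w(make_round(matrix), tie_correction=False)
        assert res.chi2 / (res.m * (res.n - 1)) == pytest.approx(res.W, abs=1e-6)
        assert res.df == res.n - 1

    def test_invariant_under_expert_and_item_relabeling(self):
        rng = np.random.default_rng(9)
        matrix = rng.integers(1, 6, size=(8, 7))
        base = kendalls_w(make_round(matrix)).W
        assert kendalls_w(make_round(matrix[rng.permutation(8)])).W == pytest.approx(base)
        assert kendalls_w(make_round(matrix[:, rng.permutation(7)])).W == pytest.approx(base)

    def test_reversing_one_ranking_does_not_increase_w(self):
        # Panels built around a shared truth, so expert 0 agrees with the
        # consensus and reversing their ratings must lower agreement.
        truth = np.tile(np.arange(1, 6), 2)[:8]
        for seed in range(5):
            rng = np.random.default_rng(seed)
            matrix = np.clip(np.round(truth + 0.6 * rng.standard_normal((6, 8))), 1, 5)
            base = kendalls_w(make_round(matrix)).W
            flipped = matrix.copy()
            flipped[0] = 6 - flipped[0]
            assert kendalls_w(make_round(flipped)).W <= base + 1e-12

    def test_constant_row_without_tie_correction_rejected(self):
        matrix = [[3, 3, 3, 3], [1, 2, 3, 4]]
        with pytest.raises(ValueError, match="undefined ranking"):
            kendalls_w(make_round(matrix), tie_correction=False)
        # with correction the constant row simply carries no information
        assert 0.0 <= kendalls_w(make_round(matrix)).W <= 1.0

    def test_minimum_size_precondition(self):
        with pytest.raises(ValueError, match="at least 2"):
            kendalls_w(pd.DataFrame([[1, 2, 3]]))


class TestScreening:
    def test_bimodal_round_drops_low_importance_columns(self):
        # 39 candidate indicators; exactly 2 rate poorly, mirroring a
        # two-round consultation that trims 39 down to 37.
        rng = np.random.default_rng(7)
        high = np.clip(np.round(4.5 + 0.3 * rng.standard_normal((20, 37))), 1, 5)
        low = np.full((20, 2), 2.0)
        matrix = np.hstack([high, low]).astype(int)
        rnd = make_round(matrix)
        result = screen_indicators(rnd, mean_min=3.5, cv_max=0.25)
        assert len(result.retained) == 37
        assert result.dropped == ["I37", "I38"]
        # oracle: direct mean / CV recomputation
        means = matrix.mean(axis=0)
        cvs = matrix.std(axis=0, ddof=1) / means
        expected = {f"I{j}" for j in range(39) if means[j] >= 3.5 and cvs[j] <= 0.25}
        assert set(result.retained) == expected

    def test_constant_top_ratings_all_retained_with_zero_cv(self):
        result = screen_indicators(make_round(np.full((5, 6), 5)))
        assert result.dropped == []
        assert (result.stats["cv"] == 0).all()

    def test_impossible_threshold_drops_everything(self):
        result = screen_indicators(make_round(np.full((5, 6), 5)), mean_min=6.0)
        assert result.retained == []

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            screen_indicators(make_round(np.full((5, 6), 5)), mean_min=0)


class TestConsultationReport:
    def _panel(self, seed, round_number, ids):
        rng = np.random.default_rng(seed)
        ratings = pd.DataFrame(
            rng.integers(1, 6, size=(6, len(ids))),
            index=[f"e{i}" for i in range(6)],
            columns=ids,
        )
        profiles = [ExpertProfile(f"e{i}", 0.9, 0.8) for i in range(6)]
        return ExpertRatingRound(round_number=round_number, ratings=ratings), profiles

    def test_two_round_panel_report_shape(self):
        ids = (
            ["A", "B", "C"]
            + [f"{p}{i}" for p in "ABC" for i in (1, 2)]
            + [f"{p}{i}{j}" for p in "ABC" for i in (1, 2) for j in (1, 2)]
        )
        r1, p1 = self._panel(1, 1, ids)
        r2, p2 = self._panel(2, 2, ids)
        report = consultation_report([r1, r2], {1: p1, 2: p2})
        assert len(report.authority) == 2
        # overall + levels 1..3, per round
        assert len(report.concordance) == 8
        np.testing.assert_allclose(report.authority["cr"].to_numpy(), 0.85)
        assert "## Expert authority" in report.to_markdown()

    def test_unit_profiles_give_unit_cr(self):
        r1, _ = self._panel(3, 1, ["A", "B", "C"])
        profiles = [ExpertProfile(f"e{i}", 1.0, 1.0) for i in range(6)]
        report = consultation_report([r1], {1: profiles})
        assert report.authority["cr"].iloc[0] == pytest.approx(1.0)

    def test_single_expert_rejected(self):
        ratings = pd.DataFrame([[1, 2, 3]], index=["e0"], columns=["A", "B", "C"])
        rnd = ExpertRatingRound(round_number=1, ratings=ratings)
        with pytest.raises(ValueError, match="at least 2"):
            consultation_report([rnd], {1: [ExpertProfile("e0", 0.9, 0.9)]})
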