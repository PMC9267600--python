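import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tmshet.heterogeneity import (
    MAX_SDI,
    CohortHeterogeneity,
    IntensityProfile,
    audit_reference_table,
    call_sample_heterogeneity,
    consensus_profile,
    h_score,
    heterogeneity_table,
    intensity_fractions,
    round_half_away,
    score_cohort,
    sdi_model_table,
    score_sample,
    shannon_diversity,
    summarize_marker,
    SampleScore,
)


def profile(fracs, sample="s1", marker="p-S6", **kw):
    return IntensityProfile(sample, marker, np.asarray(fracs, float), **kw)


# fraction strategies: 4 nonnegative weights with positive sum
fractions_st = (
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=4, max_size=4)
    .map(np.array)
    .filter(lambda p: p.sum() > 1e-6)
    .map(lambda p: p / p.sum())
)


class TestIntensityFractions:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((10, 0, 0, 0), (1, 0, 0, 0)),
            ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
            ((50, 30, 15, 5), (0.50, 0.30, 0.15, 0.05)),
        ],
    )
    def test_counts_to_fractions(self, counts, expected):
        np.testing.assert_allclose(intensity_fractions(counts), expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intensity_fractions((0, 0, 0, 0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            intensity_fractions((1, 2, 3))


class TestHScore:
    @pytest.mark.parametrize(
        "fracs, expected",
        [
            ((0, 0, 0, 1), 300.0),
            ((1, 0, 0, 0), 0.0),
            ((0.10, 0.20, 0.30, 0.40), 200.0),  # 0 + 20 + 60 + 120
        ],
    )
    def test_known_values(self, fracs, expected):
        assert h_score(profile(fracs)) == pytest.approx(expected)

    @given(p=fractions_st, q=fractions_st, alpha=st.floats(0.0, 1.0))
    def test_linearity_under_mixing(self, p, q, alpha):
        mix = alpha * p + (1 - alpha) * q
        expected = alpha * h_score(p) + (1 - alpha) * h_score(q)
        assert h_score(mix) == pytest.approx(expected, abs=1e-9)

    @given(p=fractions_st)
    def test_bounds(self, p):
        assert 0.0 <= h_score(p) <= 300.0


class TestShannonDiversity:
    @pytest.mark.parametrize(
        "fracs, expected",
        [
            ((1, 0, 0, 0), 0.0),
            ((0.25, 0.25, 0.25, 0.25), math.log(4)),
            ((0.5, 0.3, 0.15, 0.05), 1.1421200429883351),
        ],
    )
    def test_known_values(self, fracs, expected):
        assert shannon_diversity(profile(fracs)) == pytest.approx(expected, abs=1e-12)

    @given(p=fractions_st)
    def test_permutation_invariance(self, p):
        sdi = shannon_diversity(p)
        for perm in ((1, 0, 2, 3), (3, 2, 1, 0), (2, 3, 0, 1)):
            assert shannon_diversity(p[list(perm)]) == pytest.approx(sdi, abs=1e-12)

    @given(p=fractions_st)
    def test_bounds_and_extremes(self, p):
        sdi = shannon_diversity(p)
        assert -1e-12 <= sdi <= MAX_SDI + 1e-12
        concentrated = np.count_nonzero(p == 1.0) == 1
        if concentrated:
            assert sdi == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_oracle_on_random_profiles(self, rng):
        """The entropy must equal a direct -sum p ln p summation to 1e-12."""
        for _ in range(1000):
            p = rng.dirichlet(np.full(4, rng.uniform(0.2, 5.0)))
            oracle = -sum(pi * math.log(pi) for pi in p if pi > 0)
            assert abs(shannon_diversity(p) - oracle) < 1e-12


class TestConsensusProfile:
    def test_single_profile_is_identity(self):
        p = profile((0.6, 0.4, 0, 0))
        c = consensus_profile([p])
        np.testing.assert_allclose(c.fractions, p.fractions)
        assert c.observer == "consensus"

    def test_symmetric_pair(self):
        c = consensus_profile([profile((1, 0, 0, 0)), profile((0, 1, 0, 0))])
        np.testing.assert_allclose(c.fractions, (0.5, 0.5, 0, 0))

    def test_mean_of_observers(self):
        c = consensus_profile(
            [profile((0.6, 0.4, 0, 0)), profile((0.4, 0.4, 0.2, 0))]
        )
        np.testing.assert_allclose(c.fractions, (0.5, 0.4, 0.1, 0))

    def test_mismatched_sample_rejected(self):
        with pytest.raises(ValueError, match="sample/marker"):
            consensus_profile([profile((1, 0, 0, 0)), profile((1, 0, 0, 0), sample="other")])


class TestSampleHeterogeneityCall:
    @pytest.mark.parametrize(
        "fracs, expected",
        [
            ((1, 0, 0, 0), False),
            ((0.5, 0.5, 0, 0), True),
            ((0.95, 0.05, 0, 0), False),  # second bin below the 0.10 default
        ],
    )
    def test_default_threshold(self, fracs, expected):
        assert call_sample_heterogeneity(profile(fracs)) is expected

    @pytest.mark.parametrize("bad", [0.0, -0.1, 0.6, 1.0])
    def test_threshold_outside_range_rejected(self, bad):
        with pytest.raises(ValueError):
            call_sample_heterogeneity(profile((0.5, 0.5, 0, 0)), bad)

    def test_sdi_zero_iff_concentrated(self):
        score = score_sample(profile((0, 1, 0, 0)))
        assert score.sdi == pytest.approx(0.0, abs=1e-12)
        assert not score.heterogeneous


class TestSummarizeMarker:
    def test_pooled_boundary_case(self):
        """32/37 pools to 86.49% which rounds to 86, not the printed 87."""
        calls = {
            "LumA": [True] * 8 + [False],
            "LumB": [True] * 8 + [False] * 2,
            "HER2+": [True] * 8,
            "TNBC": [True] * 8 + [False] * 2,
        }
        summary = summarize_marker(calls, "p-S6")
        assert summary.pooled_counts == (32, 37)
        assert summary.pooled_percent == 86
        assert summary.is_heterogeneous_marker

    @pytest.mark.parametrize(
        "counts, expected_percent, expected_flag",
        [
            ({"LumA": (8, 10), "LumB": (10, 10), "HER2+": (8, 8), "TNBC": (9, 10)}, 92, True),
            ({"LumA": (1, 7), "LumB": (2, 9), "HER2+": (3, 7), "TNBC": (4, 8)}, 32, False),
        ],
    )
    def test_reference_rows(self, counts, expected_percent, expected_flag):
        calls = {
            subtype: [True] * k + [False] * (n - k) for subtype, (k, n) in counts.items()
        }
        summary = summarize_marker(calls, "m")
        assert summary.pooled_percent == expected_percent
        assert summary.is_heterogeneous_marker is expected_flag

    def test_empty_subtypes_excluded_from_pooling(self):
        summary = summarize_marker({"LumA": [True, False], "LumB": []}, "m")
        assert summary.per_subtype == {"LumA": (1, 2)}
        assert summary.pooled_percent == 50

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_marker({}, "m")

    def test_flag_is_strict_inequality_at_40(self):
        calls = {"LumA": [True] * 2 + [False] * 3}  # exactly 40%
        assert not summarize_marker(calls, "m").is_heterogeneous_marker


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected", [(86.49, 86), (86.5, 87), (0.5, 1), (-0.5, -1), (59.375, 59)]
    )
    def test_half_away_from_zero(self, x, expected):
        assert round_half_away(x) == expected


class TestReferenceAudit:
    def test_ten_markers_reproduce_printed_percent(self):
        audit = audit_reference_table()
        consistent = set(audit.loc[audit["consistent"], "marker"])
        assert consistent == {
            "GLUT1", "LDHA", "HK2", "PFKP", "ASCT2",
            "GLS", "CPT1A", "ACC", "ACSS2", "ATPb",
        }

    def test_discrepant_rows_flagged_not_forced(self):
        audit = audit_reference_table().set_index("marker")
        for marker in ("Rictor", "p-mTOR", "FASN", "p-S6"):
            row = audit.loc[marker]
            assert not row["consistent"]
            assert row["recomputed_percent"] != row["printed_percent"]


class TestSdiModelTable:
    def test_single_score_per_cell_is_identity(self):
        scores = [SampleScore("a", "GLS", 100.0, 0.33, False, group="Xeno")]
        table = sdi_model_table(scores)
        assert table.loc["GLS", "Xeno"] == pytest.approx(0.33)

    def test_midpoint_of_two_scores(self):
        scores = [
            SampleScore("a", "p-S6", 0.0, 0.0, False, group="Xeno"),
            SampleScore("b", "p-S6", 0.0, math.log(4), True, group="Xeno"),
        ]
        table = sdi_model_table(scores)
        assert table.loc["p-S6", "Xeno"] == pytest.approx(math.log(4) / 2)

    def test_missing_cells_are_absent_and_diff_computed(self):
        scores = [
            SampleScore("a", "p-S6", 0.0, 1.03, True, group="Xeno"),
            SampleScore("b", "p-S6", 0.0, 1.17, True, group="3D-TMS"),
            SampleScore("c", "GLS", 0.0, 0.33, False, group="Xeno"),
        ]
        table = sdi_model_table(scores, compare=("Xeno", "3D-TMS"))
        assert np.isnan(table.loc["GLS", "3D-TMS"])
        assert table.loc["p-S6", "abs_diff"] == pytest.approx(0.14)


class TestScoreCohort:
    def test_consensus_then_scoring_round_trip(self):
        rows = []
        for obs, fracs in (("obs1", (0.6, 0.4, 0, 0)), ("obs2", (0.4, 0.4, 0.2, 0))):
            rows.append(
                dict(sample_id="s1", marker="HK2", subtype="LumA", observer=obs,
                     p0=fracs[0], p1=fracs[1], p2=fracs[2], p3=fracs[3], n_cells=100)
            )
        rows.append(
            dict(sample_id="s2", marker="HK2", subtype="LumA", observer="obs1",
                 p0=1.0, p1=0.0, p2=0.0, p3=0.0, n_cells=100)
        )
        scores, summaries = score_cohort(pd.DataFrame(rows))
        s1 = scores.set_index("sample_id").loc["s1"]
        assert s1["h_score"] == pytest.approx(100 * (0.4 + 2 * 0.1))
        assert s1["heterogeneous"]
        (summary,) = summaries
        assert summary.per_subtype == {"LumA": (1, 2)}
        assert summary.pooled_percent == 50

    def test_table_layout(self):
        summaries = [
            CohortHeterogeneity("HK2", {"LumA": (6, 9), "LumB": (9, 10)}, 75, True)
        ]
        table = heterogeneity_table(summaries)
        assert table.loc[0, "LumA"] == "6/9"
        assert bool(table.loc[0, "heterogeneous_marker"])
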