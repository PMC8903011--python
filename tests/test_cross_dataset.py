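from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalsplice.cross_dataset import (
    classify_direction,
    direction_tally,
    intersect_high_confidence,
    overlap_enrichment,
)
from fetalsplice.differential import detect_events
from fetalsplice.psi import build_psi_matrix
from fetalsplice.simulate import CohortConfig, simulate_study


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "dev,dm1,expected",
        [
            (0.4, 0.3, "toward_prenatal"),
            (0.4, -0.3, "toward_postnatal"),
            (-0.4, -0.3, "toward_prenatal"),
            (0.4, None, "unknown"),
            (None, 0.3, "unknown"),
            (0.0, 0.3, "unknown"),
            (0.4, float("nan"), "unknown"),
        ],
    )
    def test_examples(self, dev, dm1, expected):
        assert classify_direction(dev, dm1) == expected

    def test_both_missing_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(None, float("nan"))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        dev=st.floats(-1, 1).filter(lambda v: abs(v) > 1e-9),
        dm1=st.floats(-1, 1).filter(lambda v: abs(v) > 1e-9),
    )
    def test_antisymmetry(self, dev, dm1):
        both = classify_direction(dev, dm1)
        assert classify_direction(-dev, -dm1) == both
        flipped = classify_direction(-dev, dm1)
        assert flipped != both


def _brute_force_overlap_p(universe, na, nb, k):
    total = comb(universe, nb)
    return sum(
        comb(na, j) * comb(universe - na, nb - j)
        for j in range(k, min(na, nb) + 1)
    ) / total


class TestOverlapEnrichment:
    def test_direct_sum_example(self):
        assert overlap_enrichment(100, 10, 10, 5) == pytest.approx(
            _brute_force_overlap_p(100, 10, 10, 5), abs=1e-12
        )

    def test_zero_overlap_of_empty_set_is_one(self):
        assert overlap_enrichment(100, 0, 10, 0) == 1.0

    def test_complete_overlap_is_tiny(self):
        assert overlap_enrichment(1000, 8, 8, 8) < 1e-6

    @pytest.mark.parametrize("universe", [5, 10, 25])
    def test_matches_enumeration_for_small_universes(self, universe):
        rng = np.random.default_rng(universe)
        for _ in range(10):
            na = int(rng.integers(0, universe + 1))
            nb = int(rng.integers(0, universe + 1))
            lo = max(0, na + nb - universe)
            k = int(rng.integers(lo, min(na, nb) + 1))
            a, b = sorted((na, nb))
            assert overlap_enrichment(universe, a, b, k) == pytest.approx(
                _brute_force_overlap_p(universe, a, b, k), abs=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_enrichment(10, 5, 5, 6)
        with pytest.raises(ValueError):
            overlap_enrichment(10, 12, 5, 2)


def _result_frame(rows):
    df = pd.DataFrame(
        rows, columns=["event_id", "mean_a", "mean_b", "delta_psi", "p",
                       "significant", "direction"]
    )
    return df.set_index("event_id")


class TestIntersection:
    def test_empty_dm1_yields_no_high_confidence(self):
        dev = _result_frame([("e1", 0.8, 0.4, 0.4, 0.001, True, 1)])
        dm1 = _result_frame([("e1", 0.5, 0.5, 0.01, 0.9, False, 1)])
        res = intersect_high_confidence(dev, dm1)
        assert not res["high_confidence"].any()

    def test_all_significant_same_sign_all_high_confidence(self):
        dev = _result_frame(
            [("e1", 0.8, 0.4, 0.4, 0.001, True, 1), ("e2", 0.2, 0.6, -0.4, 0.002, True, -1)]
        )
        dm1 = _result_frame(
            [("e1", 0.7, 0.4, 0.3, 0.003, True, 1), ("e2", 0.3, 0.6, -0.3, 0.004, True, -1)]
        )
        res = intersect_high_confidence(dev, dm1)
        assert res["high_confidence"].all()
        assert (res["direction"] == "toward_prenatal").all()

    def test_disjoint_universes_rejected(self):
        dev = _result_frame([("e1", 0.8, 0.4, 0.4, 0.001, True, 1)])
        dm1 = _result_frame([("e2", 0.7, 0.4, 0.3, 0.003, True, 1)])
        with pytest.raises(ValueError, match="share no event ids"):
            intersect_high_confidence(dev, dm1)

    def test_event_missing_in_one_dataset_is_unknown(self):
        dev = _result_frame(
            [("e1", 0.8, 0.4, 0.4, 0.001, True, 1), ("e2", 0.2, 0.6, -0.4, 0.002, True, -1)]
        )
        dm1 = _result_frame([("e1", 0.7, 0.4, 0.3, 0.003, True, 1)])
        res = intersect_high_confidence(dev, dm1)
        assert res.loc["e2", "direction"] == "unknown"
        assert not res.loc["e2", "high_confidence"]


class TestDirectionTally:
    def test_all_toward_prenatal(self):
        dev = _result_frame(
            [(f"e{i}", 0.8, 0.4, 0.4, 0.001, True, 1) for i in range(5)]
        )
        dm1 = _result_frame(
            [(f"e{i}", 0.7, 0.4, 0.3, 0.003, True, 1) for i in range(5)]
        )
        tally = direction_tally(intersect_high_confidence(dev, dm1), "both_p")
        assert tally["toward_prenatal"] == 5
        assert tally["toward_postnatal"] == 0

    def test_both_p_is_subset_of_either(self, small_study):
        res = _detect_pair(small_study)
        both = direction_tally(res, "both_p").sum()
        either = direction_tally(res, "either").sum()
        assert both <= either

    def test_unknown_criterion_rejected(self):
        dev = _result_frame([("e1", 0.8, 0.4, 0.4, 0.001, True, 1)])
        with pytest.raises(ValueError):
            direction_tally(intersect_high_confidence(dev, dev), "sometimes")


def _detect_pair(study):
    out = {}
    for kind, (ga, gb) in {
        "development": ("prenatal", "postnatal"),
        "dm1": ("dm1", "unaffected"),
    }.items():
        c = study[kind]
        pm = build_psi_matrix(c.inclusion, c.exclusion)
        out[kind] = detect_events(pm.psi, c.metadata, ga, gb)
    return intersect_high_confidence(out["development"], out["dm1"])


class TestRecovery:
    def test_shared_true_events_recovered_as_high_confidence(self):
        """A cohort pair with 40 shared regulated events recovers at least
        32 of them as high-confidence under the default thresholds."""
        cfg = CohortConfig(n_events=400, frac_true_fetal_shift=0.10, seed=3)
        study = simulate_study(cfg)
        res = _detect_pair(study)
        truth = study["development"].truth
        assert truth["regulated"].sum() == 40
        recovered = res.loc[truth.index[truth["regulated"]], "high_confidence"]
        assert recovered.sum() >= 32
        false_hits = res.loc[truth.index[~truth["regulated"]], "high_confidence"]
        assert false_hits.sum() <= 2

    def test_direction_mixture_tracks_truth(self, small_study):
        """Tallied directions: regulated events revert toward the prenatal
        pattern; the toward-postnatal bin stays near zero."""
        res = _detect_pair(small_study)
        tally = direction_tally(res, "both_p")
        assert tally["toward_prenatal"] > 10
        assert tally["toward_postnatal"] <= tally["toward_prenatal"] // 5
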