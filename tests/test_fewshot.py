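"""Anchors, within-n prediction, F1, and the ten-cycle protocol.

The protocol tests use an oracle extractor/head pair: features encode
the true days-to-anthesis in their first component and the head applies
the comparator's tie rule exactly, so protocol-level behaviour can be
checked independently of any trained network.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import feature_iwc
from spikecast.errors import ValidationError
from spikecast.fewshot import (
    Anchor,
    build_anchor,
    f1_score,
    predict_within_n,
    run_protocol,
)


def oracle_extractor(iwcs):
    feats = np.zeros((len(iwcs), 256))
    feats[:, 0] = [iwc.days_to_anthesis for iwc in iwcs]
    return feats


def oracle_head(v1, v2):
    """Positive (class 1) iff first flowers strictly sooner (d1 < d2)."""
    d1, d2 = np.atleast_2d(v1)[:, 0], np.atleast_2d(v2)[:, 0]
    scores = np.zeros((len(d1), 2))
    scores[:, 1] = (d1 < d2).astype(float)
    scores[:, 0] = 1.0 - scores[:, 1]
    return scores


def oracle_pool(n_plants=12, days=range(2, 20)):
    return [
        feature_iwc(f"p{p:02d}", d)
        for p in range(n_plants)
        for d in days
    ]


class TestF1:
    @pytest.mark.parametrize(
        "tp,fp,fn,expected", [(5, 0, 0, 1.0), (0, 3, 2, 0.0), (2, 1, 1, 0.6667)]
    )
    def test_examples(self, tp, fp, fn, expected):
        assert f1_score(tp, fp, fn) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_counts_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert f1_score(0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            f1_score(-1, 0, 0)

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500), fn=st.integers(0, 500))
    @settings(max_examples=1000, deadline=None)
    def test_equals_harmonic_mean_of_precision_and_recall(self, tp, fp, fn):
        if 2 * tp + fp + fn == 0 or tp == 0:
            return
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert f1_score(tp, fp, fn) == pytest.approx(
            2 * precision * recall / (precision + recall)
        )


class TestAnchor:
    def test_mean_identity_for_identical_supports(self):
        support = [feature_iwc("p0", 8) for _ in range(4)]
        anchor = build_anchor(support, oracle_extractor, 8)
        assert np.allclose(anchor.vector, oracle_extractor(support[:1])[0])

    def test_permutation_invariance(self):
        support = [feature_iwc(f"p{i}", 8) for i in range(5)]
        a = build_anchor(support, oracle_extractor, 8)
        b = build_anchor(support[::-1], oracle_extractor, 8)
        assert np.allclose(a.vector, b.vector)

    def test_two_vector_mean_matches_hand_arithmetic(self):
        def extractor(iwcs):
            return np.array([[1.0, 3.0], [5.0, 7.0]])[: len(iwcs)]

        support = [feature_iwc("a", 8), feature_iwc("b", 8)]
        anchor = build_anchor(support, extractor, 8)
        assert np.allclose(anchor.vector, [3.0, 5.0])

    def test_linearity_over_concatenated_supports(self):
        s1 = [feature_iwc(f"a{i}", 8) for i in range(2)]
        s2 = [feature_iwc(f"b{i}", 8) for i in range(3)]
        a1 = build_anchor(s1, oracle_extractor, 8)
        a2 = build_anchor(s2, oracle_extractor, 8)
        both = build_anchor(s1 + s2, oracle_extractor, 8)
        weighted = (2 * a1.vector + 3 * a2.vector) / 5
        assert np.allclose(both.vector, weighted)

    def test_empty_support_rejected(self):
        with pytest.raises(ValidationError):
            build_anchor([], oracle_extractor, 8)

    def test_mixed_critical_days_rejected(self):
        support = [feature_iwc("a", 8), feature_iwc("b", 9)]
        with pytest.raises(ValidationError):
            build_anchor(support, oracle_extractor, 8)


class TestPredictWithinN:
    def anchor(self, n=10):
        return build_anchor([feature_iwc("s", n)], oracle_extractor, n)

    def test_close_query_is_within(self):
        q = feature_iwc("q", 3)
        assert predict_within_n(q, self.anchor(10), oracle_extractor,
                                oracle_head) == "within"

    def test_distant_query_is_beyond(self):
        q = feature_iwc("q", 20)
        assert predict_within_n(q, self.anchor(8), oracle_extractor,
                                oracle_head) == "beyond"

    def test_boundary_query_falls_on_beyond_side(self):
        """Tie rule: equal day counts compare negative, so a query
        exactly at the critical day is classified 'beyond'."""
        q = feature_iwc("q", 10)
        assert predict_within_n(q, self.anchor(10), oracle_extractor,
                                oracle_head) == "beyond"

    def test_untrained_model_rejected(self):
        from spikecast.networks import SiameseComparator

        model = SiameseComparator(seed=0)  # no window stats -> untrained
        with pytest.raises(ValidationError, match="train"):
            predict_within_n(feature_iwc("q", 3), self.anchor(), model, model)


class TestProtocol:
    def test_oracle_head_scores_perfectly_with_strict_boundary(self):
        pool = oracle_pool()
        report = run_protocol(
            (oracle_extractor, oracle_head), pool, shots=5, cycles=1,
            seed=0, boundary="strict",
        )
        assert all(v == [1.0] for v in report.f1.values())

    def test_same_seed_reproduces_report_exactly(self):
        pool = oracle_pool()
        kwargs = dict(shots=5, cycles=3, seed=42)
        a = run_protocol((oracle_extractor, oracle_head), pool, **kwargs)
        b = run_protocol((oracle_extractor, oracle_head), pool, **kwargs)
        assert a.f1 == b.f1 and a.confusion == b.confusion

    def test_ten_cycles_per_critical_day(self):
        pool = oracle_pool()
        report = run_protocol((oracle_extractor, oracle_head), pool,
                              shots=1, cycles=10, seed=1)
        assert all(len(v) == 10 for v in report.f1.values())
        assert all(0.0 <= x <= 1.0 for v in report.f1.values() for x in v)

    def test_supports_never_leak_into_queries(self):
        n_plants, days = 12, range(2, 20)
        pool = oracle_pool(n_plants, days)
        report = run_protocol((oracle_extractor, oracle_head), pool,
                              shots=5, cycles=2, seed=3)
        # every (plant, day) group of the non-support plants is queried once
        expected = (n_plants - 5) * len(list(days))
        for n in report.critical_days:
            for conf in report.confusion[n]:
                assert sum(conf.values()) == expected

    def test_insufficient_support_plants_rejected(self):
        pool = oracle_pool(n_plants=3)
        with pytest.raises(ValidationError, match="support"):
            run_protocol((oracle_extractor, oracle_head), pool, shots=5,
                         cycles=1, seed=0)

    def test_anchor_transfer_uses_external_pool_without_exclusions(self):
        field_a = oracle_pool(8)
        field_b = [
            feature_iwc(f"q{p}", d) for p in range(6) for d in range(2, 20)
        ]
        report = run_protocol(
            (oracle_extractor, oracle_head), field_b, shots=5, cycles=2,
            seed=0, anchor_pool=field_a, boundary="strict",
        )
        # all field-B plants remain queries; oracle features transfer exactly
        expected = 6 * 18
        assert all(sum(c.values()) == expected
                   for n in report.critical_days for c in report.confusion[n])
        assert report.overall_mean_f1 == 1.0
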