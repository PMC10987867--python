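"""QRS segmentation, decile features, R/S measurements and transitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import decile_means_by_repetition, transition_scan
from conftest import make_segment, rs_segment
from otva import qrs
from otva.qrs import (
    LEADS,
    NO_TRANSITION,
    RS_RATIO_CAP,
    BeatAnnotation,
    EcgRecord,
    QrsSegment,
    combine_pvc_sinus_transition,
    decile_features,
    detect_transition,
    extract_pvc_and_preceding_sinus,
    rs_measurement,
    transition_agreement_stats,
    transition_vector,
    v3_amplitude,
)


def _record(n=1200, fs=500.0):
    return EcgRecord(np.zeros((n, 12)) + np.linspace(0, 0.1, n)[:, None], fs=fs)


class TestRecordAndSegment:
    def test_record_rejects_missing_or_duplicate_leads(self):
        with pytest.raises(ValueError):
            EcgRecord(np.zeros((100, 11)), fs=500)
        with pytest.raises(ValueError, match="NaN"):
            EcgRecord(np.full((100, 12), np.nan), fs=500)

    def test_record_reorders_leads_to_standard_order(self):
        sig = np.arange(12)[None, :].repeat(20, axis=0).astype(float)
        shuffled = list(LEADS[::-1])
        rec = EcgRecord(sig, fs=500, lead_names=shuffled)
        assert rec.lead("I")[0] == 11.0  # column that carried lead I

    def test_segment_baseline_starts_at_zero(self):
        rec = _record()
        beat = BeatAnnotation("pvc", 100, 130, 160)
        seg = QrsSegment.from_record(rec, beat)
        assert np.all(seg.signal[0] == 0.0)

    def test_segment_requires_min_samples(self):
        with pytest.raises(ValueError, match="10 samples"):
            QrsSegment(np.zeros((5, 12)), fs=500, beat_type="pvc")

    def test_bad_fiducial_order_rejected(self):
        with pytest.raises(ValueError):
            BeatAnnotation("pvc", 100, 90, 160)


class TestBeatSelection:
    def _annotated(self, *beats):
        return [BeatAnnotation(t, on, on + 20, on + 60) for t, on in beats]

    def test_selects_pvc_and_preceding_sinus(self):
        rec = _record()
        sinus, pvc = extract_pvc_and_preceding_sinus(
            rec, self._annotated(("sinus", 100), ("pvc", 600))
        )
        assert sinus.beat_type == "sinus" and pvc.beat_type == "pvc"

    def test_nearest_preceding_sinus_wins(self):
        rec = _record()
        ann = self._annotated(("sinus", 100), ("sinus", 500), ("pvc", 900))
        sinus, _ = extract_pvc_and_preceding_sinus(rec, ann)
        # nearest sinus starts at 500; its baseline value identifies it
        assert sinus.signal.shape[0] == 60
        expected = rec.signal[500:560] - rec.signal[500]
        np.testing.assert_allclose(sinus.signal, expected)

    def test_errors_without_pvc_or_preceding_sinus(self):
        rec = _record()
        with pytest.raises(ValueError, match="no PVC"):
            extract_pvc_and_preceding_sinus(rec, self._annotated(("sinus", 100)))
        with pytest.raises(ValueError, match="preceding sinus"):
            extract_pvc_and_preceding_sinus(
                rec, self._annotated(("pvc", 100), ("sinus", 600))
            )


class TestDecileFeatures:
    def test_constant_lead_gives_constant_features(self):
        # baseline correction pins the onset sample to 0, so the lead is
        # constant at 1 mV from the second sample on; every section that
        # excludes the onset sample must average exactly 1.0
        seg = make_segment(n=100, II=np.r_[0.0, np.ones(99)])
        feats = decile_features(seg).reshape(12, 10)
        assert np.allclose(feats[LEADS.index("II"), 1:], 1.0)
        assert feats[LEADS.index("II"), 0] == pytest.approx(0.9)

    def test_linear_ramp_matches_window_means(self):
        vals = np.arange(100) / 100.0
        seg = make_segment(n=100, V1=vals)
        feats = decile_features(seg).reshape(12, 10)
        np.testing.assert_allclose(feats[LEADS.index("V1")], np.arange(10) / 10 + 0.045)

    def test_all_zero_record_gives_120_zeros(self):
        seg = make_segment(n=50)
        assert decile_features(seg).shape == (120,)
        assert np.all(decile_features(seg) == 0)

    @pytest.mark.parametrize("n", [10, 13, 25, 99, 100, 137])
    def test_matches_repetition_oracle(self, n):
        rng = np.random.default_rng(n)
        vals = rng.normal(size=n)
        vals[0] = 0.0
        seg = make_segment(n=n, V3=vals)
        feats = decile_features(seg).reshape(12, 10)[LEADS.index("V3")]
        np.testing.assert_allclose(feats, decile_means_by_repetition(vals), atol=1e-12)

    @pytest.mark.parametrize("factor", [2, 3, 7])
    def test_invariant_under_integer_upsampling(self, factor):
        rng = np.random.default_rng(factor)
        vals = rng.normal(size=47)
        vals[0] = 0.0
        seg = make_segment(n=47, V2=vals)
        up = make_segment(n=47 * factor, V2=np.repeat(vals, factor))
        np.testing.assert_allclose(
            decile_features(seg), decile_features(up), atol=1e-6
        )


class TestRsMeasurement:
    def test_biphasic_wave(self):
        seg = rs_segment([0.8], [0.4])
        m = rs_measurement(seg, "V1")
        assert (m.r_amplitude, m.s_amplitude, m.ratio) == (0.8, 0.4, 2.0)

    def test_monophasic_positive_wave_hits_cap(self):
        seg = rs_segment([0.7], [0.0])
        m = rs_measurement(seg, "V1")
        assert m.s_amplitude == 0.0 and m.ratio == RS_RATIO_CAP

    def test_all_zero_lead(self):
        seg = make_segment(n=20)
        m = rs_measurement(seg, "V5")
        assert m.r_amplitude == m.s_amplitude == m.ratio == 0.0


class TestTransitionDetection:
    def test_first_crossing_rule(self):
        seg = rs_segment([0.2, 0.5, 1.5, 2.0, 3.0, 4.0], [1.0] * 6)
        assert detect_transition(seg).index == 3

    def test_all_dominant_gives_first_lead(self):
        seg = rs_segment([2.0] * 6, [1.0] * 6)
        assert detect_transition(seg).index == 1

    def test_none_dominant_gives_sentinel(self):
        seg = rs_segment([0.1] * 6, [1.0] * 6)
        assert detect_transition(seg).index == NO_TRANSITION

    def test_matches_brute_force_scan_on_random_tuples(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            r = np.where(rng.random(6) < 0.15, 0.0, rng.uniform(0, 2, 6))
            s = np.where(rng.random(6) < 0.15, 0.0, rng.uniform(0, 2, 6))
            seg = rs_segment(r, s)
            assert detect_transition(seg).index == transition_scan(r, s)


class TestTransitionEncodings:
    @pytest.mark.parametrize(
        "index,expected",
        [(4, [0, 0, 0, 1, 0, 0]), (1, [1, 0, 0, 0, 0, 0]), (7, [0] * 6)],
    )
    def test_one_hot_vectors(self, index, expected):
        np.testing.assert_array_equal(transition_vector(index), expected)

    @given(st.integers(1, 7))
    @settings(derandomize=True)
    def test_one_hot_sum_property(self, index):
        assert transition_vector(index).sum() == (0.0 if index == 7 else 1.0)

    @pytest.mark.parametrize(
        "pvc,sinus,scalar,vec",
        [
            (3, 4, -1, [0, 0, 1, -1, 0, 0]),
            (2, 2, 0, [0] * 6),
            (7, 3, 4, [0, 0, -1, 0, 0, 0]),
        ],
    )
    def test_combined_pvc_sinus_feature(self, pvc, sinus, scalar, vec):
        s, v = combine_pvc_sinus_transition(pvc, sinus)
        assert s == scalar
        np.testing.assert_array_equal(v, vec)

    @given(st.integers(1, 7), st.integers(1, 7))
    @settings(derandomize=True)
    def test_zero_scalar_iff_zero_vector(self, pvc, sinus):
        s, v = combine_pvc_sinus_transition(pvc, sinus)
        assert (s == 0) == np.all(v == 0)


class TestAgreementStats:
    def test_direct_arithmetic_case(self):
        stats = transition_agreement_stats([(3, 3), (4, 3), (2, 5)])
        assert stats["exact_agreement"] == pytest.approx(1 / 3)
        assert stats["mean_shift"] == pytest.approx(4 / 3)
        assert stats["median_shift"] == 1.0

    def test_identical_pairs(self):
        stats = transition_agreement_stats([(2, 2)] * 5)
        assert stats == {
            "exact_agreement": 1.0, "mean_shift": 0.0,
            "median_shift": 0.0, "iqr_shift": 0.0,
        }

    def test_maximal_shift_and_empty_error(self):
        assert transition_agreement_stats([(1, 7)])["mean_shift"] == 6.0
        with pytest.raises(ValueError):
            transition_agreement_stats([])


class TestV3Amplitude:
    @pytest.mark.parametrize("amp,binary", [(1.3, 1), (0.4, 0), (0.0, 0)])
    def test_amplitude_and_threshold(self, amp, binary):
        seg = make_segment(n=20, V3=np.r_[0, amp, np.zeros(18)])
        assert v3_amplitude(seg) == amp
        assert qrs.binarize_v3_amplitude(v3_amplitude(seg)) == binary
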