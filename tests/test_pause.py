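"""Normalization, EJES detection, window statistics and the t-test."""

import math

import numpy as np
import pandas as pd
import pytest

import uindel as u


def _call(read_class, jss=None, jes=None, u_obs=(0,)):
    return u.ReadCall("r", read_class, jss, jes, tuple(u_obs), None)


class TestNormalizeSample:
    def test_two_reads_split_weight(self):
        calls = [
            _call(u.ReadClass.PARTIALLY_EDITED, jss=2, jes=2, u_obs=(5,)),
            _call(u.ReadClass.PRE_EDITED, u_obs=(1,)),
        ]
        p = u.normalize_sample(calls, es_lo=1, es_hi=4)
        assert p.jes_hist == {2: 50_000.0}

    def test_all_fully_edited(self):
        calls = [_call(u.ReadClass.FULLY_EDITED, u_obs=(3,))] * 4
        p = u.normalize_sample(calls, es_lo=1, es_hi=4)
        assert p.class_counts[u.ReadClass.FULLY_EDITED] == 100_000.0
        assert p.jes_hist == {}

    def test_proportional_scaling(self):
        calls = (
            [_call(u.ReadClass.PARTIALLY_EDITED, 2, 2, (5,))] * 3
            + [_call(u.ReadClass.PARTIALLY_EDITED, 3, 3, (0, 9))]
        )
        p = u.normalize_sample(calls, es_lo=1, es_hi=4)
        assert p.jes_hist == {2: 75_000.0, 3: 25_000.0}

    def test_excluded_reads_unweighted_but_tallied(self):
        calls = [
            _call(u.ReadClass.PRE_EDITED, u_obs=(1,)),
            u.ReadCall("x", u.ReadClass.EXCLUDED, None, None, None,
                       u.ExclusionReason.BACKBONE_MISMATCH),
        ]
        p = u.normalize_sample(calls, es_lo=1, es_hi=4)
        assert p.n_excluded == 1
        assert p.exclusion_counts["backbone-mismatch"] == 1
        assert p.class_counts[u.ReadClass.PRE_EDITED] == 100_000.0

    def test_empty_sample(self):
        with pytest.raises(u.EmptySample):
            u.normalize_sample([], es_lo=1, es_hi=4)

    def test_conservation(self, synthetic):
        """Class totals and sequence-table totals both sum to 100,000."""
        s, w = synthetic
        rng = np.random.default_rng(17)
        reads, _ = u.simulate_sample(
            s, w, u.SimConfig(n_reads=1500, error_rate=0.002), rng)
        calls = u.process_reads(s, w, reads)
        p = u.normalize_sample(calls, es_lo=w.es_lo, es_hi=w.es_hi)
        assert math.isclose(sum(p.class_counts.values()), 100_000.0, abs_tol=1e-6)
        assert math.isclose(p.seq_table["count_norm"].sum(), 100_000.0, abs_tol=1e-6)
        assert sum(p.jes_hist.values()) <= 100_000.0 + 1e-9


class TestDetectEjes:
    def test_strong_pause_passes(self, make_profile):
        ind = [make_profile({121: 400.0}), make_profile({121: 440.0})]
        uni = [make_profile({121: 10.0}), make_profile({121: 12.0})]
        t = u.detect_ejes(ind, uni)
        row = t[t.es == 121].iloc[0]
        assert row.ejes
        assert row.fold_change == pytest.approx(420 / 11, rel=1e-12)
        assert round(row.fold_change, 1) == 38.2

    def test_replicate_floor(self, make_profile):
        ind = [make_profile({50: 120.0}), make_profile({50: 90.0})]
        uni = [make_profile({50: 1.0}), make_profile({50: 1.0})]
        t = u.detect_ejes(ind, uni, min_norm_reads=100, min_replicates=2)
        assert not t[t.es == 50].iloc[0].ejes  # only one replicate >= 100

    def test_identical_profiles_never_pass(self, make_profile):
        prof = {101: 500.0, 102: 900.0}
        t = u.detect_ejes([make_profile(prof)] * 2, [make_profile(prof)] * 2)
        assert not t.ejes.any()

    def test_zero_denominator_pseudocount(self, make_profile):
        ind = [make_profile({60: 200.0}), make_profile({60: 200.0})]
        uni = [make_profile({}), make_profile({})]
        t = u.detect_ejes(ind, uni)
        row = t[t.es == 60].iloc[0]
        assert row.fold_change == pytest.approx(201.0)  # (200+1)/(0+1)
        assert row.ejes

    def test_replicate_mismatch(self, make_profile):
        with pytest.raises(u.ReplicateMismatch):
            u.detect_ejes([make_profile({})], [make_profile({})] * 2)

    def test_monotonicity_in_thresholds(self, make_profile):
        """Raising fold_min or min_norm_reads never adds EJES."""
        rng = np.random.default_rng(23)
        ind = [make_profile({es: float(rng.integers(0, 500)) for es in range(1, 40)})
               for _ in range(2)]
        uni = [make_profile({es: float(rng.integers(0, 500)) for es in range(1, 40)})
               for _ in range(2)]
        counts = []
        for fold_min, floor in [(1.5, 50), (3, 50), (3, 150), (6, 150)]:
            t = u.detect_ejes(ind, uni, fold_min=fold_min, min_norm_reads=floor)
            counts.append(int(t.ejes.sum()))
        assert counts == sorted(counts, reverse=True)


class TestFilterWindowSequences:
    @staticmethod
    def _profile_with_seq(count, jes, u_vec="0,3,5,0"):
        import pandas as pd

        return u.SampleProfile(
            sample_id="s", condition="c", replicate=1, es_lo=1, es_hi=200,
            n_reads=0, n_excluded=0, exclusion_counts={}, class_counts={},
            jes_hist={}, seq_table=pd.DataFrame({
                "u_vector": [u_vec],
                "read_class": ["PARTIALLY_EDITED"],
                "jss": [jes], "jes": [jes],
                "count_norm": [float(count)],
            }),
        )

    def test_retained_with_fold(self):
        ind = [self._profile_with_seq(280, 123), self._profile_with_seq(320, 123)]
        uni = [self._profile_with_seq(40, 123), self._profile_with_seq(60, 123)]
        t = u.filter_window_sequences(ind, uni, (121, 126))
        assert len(t) == 1
        assert t.iloc[0].fold_change == pytest.approx(6.0)

    def test_dropped_below_fold(self):
        ind = [self._profile_with_seq(300, 123)] * 2
        uni = [self._profile_with_seq(150, 123)] * 2
        assert u.filter_window_sequences(ind, uni, (121, 126)).empty

    def test_dropped_outside_window(self):
        ind = [self._profile_with_seq(300, 110)] * 2
        uni = [self._profile_with_seq(10, 110)] * 2
        assert u.filter_window_sequences(ind, uni, (121, 126)).empty

    def test_empty_window(self):
        ind = [self._profile_with_seq(300, 123)] * 2
        with pytest.raises(u.EmptyWindow):
            u.filter_window_sequences(ind, ind, (500, 600))


class TestPercentJesInWindow:
    def test_arithmetic(self, make_profile):
        p = make_profile({121: 10_000.0, 124: 2_100.0})
        assert u.percent_jes_in_window(p, (121, 126)) == pytest.approx(12.1)

    def test_empty_hist(self, make_profile):
        assert u.percent_jes_in_window(make_profile({}), (121, 126)) == 0.0

    def test_all_reads_in_window(self, make_profile):
        p = make_profile({123: 100_000.0})
        assert u.percent_jes_in_window(p, (121, 126)) == 100.0

    def test_empty_window(self, make_profile):
        with pytest.raises(u.EmptyWindow):
            u.percent_jes_in_window(make_profile({}), (300, 400))


class TestCompareConditions:
    def test_identical_values(self):
        r = u.compare_conditions([12.0, 12.0], [12.0, 12.0])
        assert (r.t, r.p, r.degenerate) == (0.0, 1.0, False)

    def test_zero_variance_unequal_means_degenerate(self):
        r = u.compare_conditions([12.0, 12.0], [26.0, 26.0])
        assert r.degenerate
        assert math.isinf(r.t)

    def test_textbook_values(self):
        """{10,14} vs {24,28}: pooled s^2 = 8, t = -14/sqrt(8) on 2 df."""
        r = u.compare_conditions([10.0, 14.0], [24.0, 28.0])
        t_expected = -14.0 / math.sqrt(8.0)
        assert r.t == pytest.approx(t_expected, rel=1e-12)
        assert r.df == 2
        # closed-form Student cdf for df = 2: sf(t) = 1/2 - t / (2 sqrt(2 + t^2))
        p_expected = 2 * (0.5 - abs(t_expected) / (2 * math.sqrt(2 + t_expected**2)))
        assert r.p == pytest.approx(p_expected, rel=1e-9)

    def test_replicate_mismatch(self):
        with pytest.raises(u.ReplicateMismatch):
            u.compare_conditions([1.0], [2.0, 3.0])


def test_render_sequence_alignment(toy):
    s, w = toy
    out = u.render_sequence_alignment(s, w, (0, 3, 0, 0))
    lines = out.splitlines()
    assert len(lines) == 3
    assert len({len(ln) for ln in lines}) == 1  # columns aligned
    assert lines[0].startswith("PRE")
    assert lines[1].startswith("EDIT")
    # the read row shows 3 U's at ES2 and none elsewhere
    assert "ttt" in lines[2]
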