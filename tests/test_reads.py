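"""Read alignment, the exclusion filter, classification and junction calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uindel as u
from conftest import random_scaffold


class TestAlignRead:
    @pytest.mark.parametrize(
        "read,expected_u",
        [
            ("GACTTTGA", (0, 3, 0, 0)),
            ("GATTCGTA", (1, 0, 2, 0)),  # the pre-edited reference itself
            ("GTATTCTTTGA", (0, 3, 2, 1)),  # the fully edited reference
        ],
    )
    def test_u_extraction(self, toy, read, expected_u):
        s, w = toy
        a = u.align_read(s, w, read)
        assert not a.excluded
        assert a.u_obs == expected_u

    def test_non_t_snp_excluded(self, toy):
        s, w = toy
        a = u.align_read(s, w, "GACCGA")  # backbone GACGA vs observed GACCGA
        assert a.excluded
        assert a.exclusion is u.ExclusionReason.BACKBONE_MISMATCH

    def test_backbone_indel_excluded(self, toy):
        s, w = toy
        assert u.align_read(s, w, "GACGGA").exclusion is \
            u.ExclusionReason.BACKBONE_MISMATCH

    def test_missing_primer_excluded(self, toy):
        s, w = toy
        a = u.align_read(s, w, "CACTTTGA")  # fwd primer prefix broken
        assert a.exclusion is u.ExclusionReason.PRIMER_MISSING

    def test_too_short_excluded(self, toy):
        s, w = toy
        a = u.align_read(s, w, "GACGA", min_length=8)
        assert a.exclusion is u.ExclusionReason.TOO_SHORT

    def test_primer_mismatch_tolerance(self, synthetic):
        s, w = synthetic
        read = u.render_amplicon(s, w, s.window_u(s.can_u, w.es_lo, w.es_hi))
        broken = "A" + read[1:] if read[0] != "A" else "C" + read[1:]
        assert u.align_read(s, w, broken).excluded
        assert not u.align_read(s, w, broken, primer_mismatches=1).excluded


class TestClassify:
    @pytest.mark.parametrize(
        "u_vec,expected",
        [
            ((0, 3, 2, 1), u.ReadClass.FULLY_EDITED),
            ((1, 0, 2, 0), u.ReadClass.PRE_EDITED),
            ((0, 3, 0, 0), u.ReadClass.PARTIALLY_EDITED),
        ],
    )
    def test_examples(self, toy, u_vec, expected):
        s, w = toy
        a = u.AlignedRead("r", u_vec)
        assert u.classify_read(a, s, w) is expected

    def test_excluded_read_raises(self, toy):
        s, w = toy
        a = u.AlignedRead("r", None, u.ExclusionReason.BACKBONE_MISMATCH)
        with pytest.raises(u.ExcludedRead):
            u.classify_read(a, s, w)
        with pytest.raises(u.ExcludedRead):
            u.call_junction(a, s, w)


class TestCallJunction:
    @pytest.mark.parametrize(
        "u_vec,jss,jes",
        [
            # non-canonical 2-U deletion at ES3 (pre=can=2): single-site junction
            ((0, 3, 0, 0), 3, 3),
            # non-canonical 5 U at ES3
            ((0, 3, 5, 0), 3, 3),
            # pre-edited read: no editing action
            ((1, 0, 2, 0), None, None),
            # fully edited read: no junction
            ((0, 3, 2, 1), None, None),
        ],
    )
    def test_examples(self, toy, u_vec, jss, jes):
        s, w = toy
        call = u.call_junction(u.AlignedRead("r", u_vec), s, w)
        assert (call.jss, call.jes) == (jss, jes)

    def test_empty_junction_encoding(self):
        # canonical editing through ES3, pre-edited 5' of it: jes = jss - 1
        s = u.build_scaffold("GATAGA", "GTATTATTGA")
        assert (s.pre_u, s.can_u) == ((0, 0, 1, 0), (0, 2, 2, 1))
        w = u.full_window(s)
        call = u.call_junction(u.AlignedRead("r", (0, 2, 2, 0)), s, w)
        assert (call.jss, call.jes) == (4, 3)

    def test_sites_matching_both_references_never_junction_ends(self, toy):
        s, w = toy  # ES3 has pre_u == can_u == 2
        # canonical ES1-2, pre-edited (== canonical) ES3, pre-edited ES4:
        # ES3 matches both and is skipped by both scans
        call = u.call_junction(u.AlignedRead("r", (0, 3, 2, 0)), s, w)
        assert (call.jss, call.jes) == (4, 2)


class TestOracleAgreement:
    def test_sampled_vectors_match_oracle(self, oracle):
        """Random u vectors on random scaffolds agree with the definition scan."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            s = random_scaffold(rng, max_u=4)
            w = u.full_window(s)
            u_vec = tuple(int(x) for x in rng.integers(0, 5, size=s.n_es))
            a = u.AlignedRead("r", u_vec)
            cls = u.classify_read(a, s, w)
            call = u.call_junction(a, s, w)
            ocls, ojss, ojes = oracle(u_vec, s.pre_u, s.can_u, w.es_lo)
            assert str(cls) == ocls
            assert (call.jss, call.jes) == (ojss, ojes)

    def test_junction_none_iff_not_partial(self, toy, oracle):
        s, w = toy
        rng = np.random.default_rng(5)
        for _ in range(200):
            u_vec = tuple(int(x) for x in rng.integers(0, 4, size=4))
            a = u.AlignedRead("r", u_vec)
            cls = u.classify_read(a, s, w)
            call = u.call_junction(a, s, w)
            partial = cls is u.ReadClass.PARTIALLY_EDITED
            assert (call.jss is not None) == partial
            assert (call.jes is not None) == partial
            if partial:
                # any ES strictly between jes and jss matches both references
                for es in range(call.jes + 1, call.jss):
                    assert s.pre_u[es - 1] == s.can_u[es - 1]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(data=st.data())
def test_reconstructed_reads_round_trip(data):
    """Any rendered read is never excluded and returns its u vector exactly."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    s = random_scaffold(rng)
    w = u.full_window(s)
    u_vec = tuple(int(x) for x in rng.integers(0, 9, size=s.n_es))
    read = u.render_amplicon(s, w, u_vec)
    a = u.align_read(s, w, read)
    assert not a.excluded
    assert a.u_obs == u_vec


def test_class_partition_is_exhaustive(synthetic):
    """EXCLUDED + PRE + PARTIAL + FULLY counts equal the total read count."""
    s, w = synthetic
    rng = np.random.default_rng(3)
    reads, _ = u.simulate_sample(
        s, w, u.SimConfig(n_reads=500, error_rate=0.01), rng)
    # add some junk that must land in EXCLUDED, not vanish
    reads += [("junk1", "ACGT"), ("junk2", ""), ("junk3", "N" * 50)]
    calls = u.process_reads(s, w, reads)
    assert len(calls) == len(reads)
    counts = {}
    for c in calls:
        counts[c.read_class] = counts.get(c.read_class, 0) + 1
    assert sum(counts.values()) == len(reads)
    assert counts.get(u.ReadClass.EXCLUDED, 0) >= 3
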