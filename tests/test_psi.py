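"""PSI quantification: effective lengths, replicate PSI, group delta."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicemeta import (
    GenomicInterval,
    SpliceEvent,
    canonical_key,
    effective_lengths,
    group_delta,
    psi_from_counts,
    psi_table,
)
from splicemeta.psi import EventCounts, ReplicatePSI, _psi

KEY = canonical_key(
    SpliceEvent(
        "SE",
        "G",
        GenomicInterval("chr1", 300, 400, "+"),
        GenomicInterval("chr1", 100, 200, "+"),
        GenomicInterval("chr1", 500, 600, "+"),
    )
)


def _counts(inc, skip, li=2.0, ls=1.0, group="fat"):
    return EventCounts(KEY, "r1", group, inc, skip, li, ls)


class TestEffectiveLengths:
    @pytest.mark.parametrize(
        "read_len, exon_len, mode, expected",
        [
            (100, None, "JC", (198.0, 99.0)),
            (150, 120, "JCEC", (298.0, 149.0)),  # exon shorter than read: no body positions
            (150, 300, "JCEC", (449.0, 149.0)),  # 298 junction + 151 exon-body placements
        ],
    )
    def test_formula(self, read_len, exon_len, mode, expected):
        assert effective_lengths(exon_len, read_len, mode) == expected

    def test_short_reads_rejected(self):
        with pytest.raises(ValueError):
            effective_lengths(None, 1, "JC")


class TestReplicatePsi:
    def test_worked_example(self):
        assert psi_from_counts(_counts(15, 5, li=2.0, ls=1.0)).psi == pytest.approx(0.6)

    def test_boundaries_and_missing(self):
        assert psi_from_counts(_counts(0, 10)).psi == 0.0
        assert psi_from_counts(_counts(10, 0)).psi == 1.0
        assert psi_from_counts(_counts(0, 0)).psi is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _counts(-1, 5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        inc=st.integers(0, 10_000),
        skip=st.integers(0, 10_000),
        li=st.floats(1.0, 500.0),
        ls=st.floats(1.0, 500.0),
    )
    def test_range_and_equal_length_limit(self, inc, skip, li, ls):
        psi = _psi(inc, skip, li, ls)
        if inc + skip == 0:
            assert psi is None
        else:
            assert 0.0 <= psi <= 1.0
            assert _psi(inc, skip, li, li) == pytest.approx(
                inc / (inc + skip)
            )  # with lI = lS the normalisation cancels

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        inc=st.integers(0, 1000),
        skip=st.integers(1, 1000),
        li=st.floats(1.0, 500.0),
        ls=st.floats(1.0, 500.0),
        scale=st.integers(2, 50),
    )
    def test_monotone_in_inclusion_and_scale_invariant(self, inc, skip, li, ls, scale):
        base = _psi(inc, skip, li, ls)
        assert _psi(inc + 1, skip, li, ls) >= base
        assert _psi(inc, skip + 1, li, ls) <= base
        assert _psi(inc * scale, skip * scale, li, ls) == pytest.approx(base)


class TestGroupDelta:
    def _psis(self, fat, thin):
        return [
            ReplicatePSI(KEY, f"f{i}", "fat", v) for i, v in enumerate(fat)
        ] + [ReplicatePSI(KEY, f"t{i}", "thin", v) for i, v in enumerate(thin)]

    def test_sign_convention(self):
        # exon more skipped in the fat-tailed group -> negative delta
        delta = group_delta(self._psis([0.5, 0.5, 0.5], [0.75, 0.75, 0.75]))
        assert delta.delta_psi == pytest.approx(-0.25)

    def test_identical_groups_and_extremes(self):
        assert group_delta(self._psis([0.4], [0.4])).delta_psi == 0.0
        assert group_delta(self._psis([1.0], [0.0])).delta_psi == 1.0

    def test_missing_replicates_dropped_but_empty_group_fails(self):
        delta = group_delta(self._psis([0.2, None], [0.4]))
        assert delta.psi_fat == pytest.approx(0.2)
        with pytest.raises(ValueError, match="thin"):
            group_delta(self._psis([0.2], [None]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        fat=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
        thin=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5),
    )
    def test_delta_bounded(self, fat, thin):
        assert -1.0 <= group_delta(self._psis(fat, thin)).delta_psi <= 1.0


class TestPsiTable:
    def test_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        n = 300
        df = pd.DataFrame(
            {
                "event_id": [f"e{i}" for i in range(n)],
                "study_id": "s1",
                "replicate_id": "r1",
                "group": "fat",
                "inclusion_count": rng.integers(0, 200, n),
                "skipping_count": rng.integers(0, 200, n),
                "read_length": rng.choice([75, 101, 150], n),
            }
        )
        out = psi_table(df, mode="JC")
        for row in out.itertuples():
            expected = _psi(
                row.inclusion_count,
                row.skipping_count,
                2.0 * (row.read_length - 1),
                row.read_length - 1.0,
            )
            if expected is None:
                assert np.isnan(row.psi)
            else:
                assert row.psi == pytest.approx(expected)

    def test_jcec_requires_event_table(self):
        df = pd.DataFrame(
            {
                "event_id": ["e0"],
                "study_id": ["s1"],
                "replicate_id": ["r1"],
                "group": ["fat"],
                "inclusion_count": [5],
                "skipping_count": [5],
                "read_length": [100],
            }
        )
        with pytest.raises(ValueError, match="event table"):
            psi_table(df, mode="JCEC")
        events = pd.DataFrame(
            {"event_id": ["e0"], "target_start": [300], "target_end": [700]}
        )
        out = psi_table(df, events=events, mode="JCEC")
        # lI = 198 + (400 - 100 + 1), lS = 99
        assert out["eff_len_inclusion"].iloc[0] == pytest.approx(499.0)
        assert out["eff_len_skipping"].iloc[0] == pytest.approx(99.0)
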