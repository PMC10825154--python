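"""Event domain objects, skipped-exon enumeration and cross-arm matching."""

import random

import pytest

from splicemeta import (
    GenomicInterval,
    SpliceEvent,
    canonical_key,
    enumerate_se_events,
    event_id,
    key_from_event_id,
    match_events,
)
from splicemeta.events import GTFParseError

from conftest import write_gtf


def _se(chrom="chr1", strand="+", target=(300, 400), up=(100, 200), down=(500, 600)):
    return SpliceEvent(
        event_class="SE",
        gene_id="G",
        target=GenomicInterval(chrom, *target, strand),
        flank_upstream=GenomicInterval(chrom, *up, strand),
        flank_downstream=GenomicInterval(chrom, *down, strand),
    )


class TestDomainTypes:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10, "+")
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "*")

    def test_event_flank_ordering_enforced(self):
        with pytest.raises(ValueError):
            _se(target=(300, 550))  # overlaps downstream flank

    def test_key_deterministic_and_strand_sensitive(self):
        assert canonical_key(_se()) == canonical_key(_se())
        assert canonical_key(_se(strand="+")) != canonical_key(_se(strand="-"))

    def test_key_from_gtf_coordinates_normalised(self):
        # 1-based inclusive GTF exon 301..400 == internal [300, 400)
        gtf_based = _se(target=(301 - 1, 400))
        assert canonical_key(gtf_based).target_start == 300
        assert canonical_key(gtf_based).target_end == 400

    def test_event_id_round_trip(self):
        key = canonical_key(_se())
        assert key_from_event_id(event_id(key)) == key
        with pytest.raises(ValueError):
            key_from_event_id("not-an-event-id")


class TestEnumeration:
    def test_cassette_exon_found(self, tmp_path):
        # T1 has exons A, B, C; T2 skips B -> exactly one SE event on B
        gtf = write_gtf(
            tmp_path / "a.gtf",
            [
                ("G", "T1", "chr1", "+", [(101, 200), (301, 400), (501, 600)]),
                ("G", "T2", "chr1", "+", [(101, 200), (501, 600)]),
            ],
        )
        events = enumerate_se_events(gtf)
        assert len(events) == 1
        key = canonical_key(events[0])
        assert (key.target_start, key.target_end) == (300, 400)
        assert (key.upstream_end, key.downstream_start) == (200, 500)
        assert events[0].gene_id == "G"

    def test_single_transcript_yields_nothing(self, tmp_path):
        gtf = write_gtf(
            tmp_path / "b.gtf",
            [("G", "T1", "chr1", "+", [(101, 200), (301, 400), (501, 600)])],
        )
        assert enumerate_se_events(gtf) == []

    def test_opposite_strand_genes_give_distinct_keys(self, tmp_path):
        exons3 = [(101, 200), (301, 400), (501, 600)]
        exons2 = [(101, 200), (501, 600)]
        gtf = write_gtf(
            tmp_path / "c.gtf",
            [
                ("G1", "G1.T1", "chr1", "+", exons3),
                ("G1", "G1.T2", "chr1", "+", exons2),
                ("G2", "G2.T1", "chr1", "-", exons3),
                ("G2", "G2.T2", "chr1", "-", exons2),
            ],
        )
        events = enumerate_se_events(gtf)
        keys = {canonical_key(e) for e in events}
        assert len(events) == 2 and len(keys) == 2
        (a, b) = sorted(keys)
        assert a._replace(strand="") == b._replace(strand="")

    def test_line_order_invariance(self, toy, tmp_path):
        original = (tmp_path / "orig.gtf")
        original.write_text(toy.gtf_text)
        lines = [l for l in toy.gtf_text.splitlines() if l]
        random.Random(7).shuffle(lines)
        shuffled = tmp_path / "shuf.gtf"
        shuffled.write_text("\n".join(lines) + "\n")
        keys_a = [canonical_key(e) for e in enumerate_se_events(original)]
        keys_b = [canonical_key(e) for e in enumerate_se_events(shuffled)]
        assert keys_a == keys_b

    def test_toy_enumeration_matches_event_table_and_keys_injective(self, toy, tmp_path):
        gtf = tmp_path / "toy.gtf"
        gtf.write_text(toy.gtf_text)
        events = enumerate_se_events(gtf)
        ids = [event_id(e) for e in events]
        assert sorted(ids) == sorted(toy.events["event_id"])
        assert len(set(ids)) == len(ids)  # canonical_key injective on this set
        for ev in events:  # flanks never overlap the target
            assert not ev.flank_upstream.overlaps(ev.target)
            assert not ev.flank_downstream.overlaps(ev.target)

    def test_malformed_gtf_names_line(self, tmp_path):
        good = 'chr1\tx\texon\t10\t20\t.\t+\t.\tgene_id "G"; transcript_id "T";'
        bad = "chr1\tx\texon\t10\t20\t.\t+"
        path = tmp_path / "bad.gtf"
        path.write_text(good + "\n" + bad + "\n")
        with pytest.raises(GTFParseError, match="line 2"):
            enumerate_se_events(path)

    def test_inverted_coordinates_rejected(self, tmp_path):
        bad = 'chr1\tx\texon\t50\t20\t.\t+\t.\tgene_id "G"; transcript_id "T";'
        path = tmp_path / "bad2.gtf"
        path.write_text(bad + "\n")
        with pytest.raises(GTFParseError, match="line 1"):
            enumerate_se_events(path)


class TestMatchEvents:
    @staticmethod
    def _call(key, study, arm):
        return {"event_key": key, "study_id": study, "arm": arm}

    def test_join_counts(self):
        keys = [
            canonical_key(
                _se(
                    target=(300 + 1000 * i, 400 + 1000 * i),
                    up=(100 + 1000 * i, 200 + 1000 * i),
                    down=(500 + 1000 * i, 600 + 1000 * i),
                )
            )
            for i in range(6)
        ]
        calls_a = [self._call(k, "s1", "count") for k in keys[:5]]  # 3 shared + 2 a-only
        calls_b = [self._call(k, "s1", "graph") for k in keys[:3] + keys[5:]]
        matched = match_events(calls_a, calls_b)
        assert len(matched) == 6
        both = [m for m in matched if m[1] and m[2]]
        assert len(both) == 3
        a_only = [m for m in matched if m[1] and not m[2]]
        b_only = [m for m in matched if m[2] and not m[1]]
        assert len(a_only) == 2 and len(b_only) == 1

    def test_duplicate_call_rejected(self):
        key = canonical_key(_se())
        calls = [self._call(key, "s1", "count")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            match_events(calls, [])
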