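"""3'-end pileup, normalization factors and track I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polpause.signal import (
    DEFAULT_RRNA_INTERVAL,
    Alignment,
    SignalTrack,
    SpikeInAbsentError,
    read_bedgraph_pair,
    rrna_normalization_factor,
    scale_track,
    spike_normalization_factor,
    three_prime_pileup,
    write_bedgraph_pair,
    write_sam,
    iter_sam,
)


def naive_pileup(alignments, min_mapq=10, flip=False):
    """Independent per-read oracle for the streaming pileup."""
    counts = {}
    for a in alignments:
        if a.mapq < min_mapq or a.end <= a.start:
            continue
        strand = a.strand
        if flip:
            strand = "+" if strand == "-" else "-"
        pos = a.end - 1 if strand == "+" else a.start
        counts[(a.contig, strand, pos)] = counts.get((a.contig, strand, pos), 0) + 1
    return counts


def track_as_dict(track):
    out = {}
    for contig, strand in track.keys():
        for pos, v in track.positions(contig, strand).items():
            out[(contig, strand, pos)] = v
    return out


alignment_st = st.builds(
    Alignment,
    contig=st.sampled_from(["chr1", "chr2"]),
    start=st.integers(0, 500),
    end=st.integers(0, 530),
    strand=st.sampled_from("+-"),
    mapq=st.integers(0, 60),
)


class TestPileup:
    def test_plus_strand_last_base(self):
        t = three_prime_pileup([Alignment("chr1", 100, 130, "+", 60)])
        assert t.value("chr1", "+", 129) == 1
        assert t.total() == 1

    def test_minus_strand_last_base(self):
        t = three_prime_pileup([Alignment("chr1", 100, 130, "-", 60)])
        assert t.value("chr1", "-", 100) == 1

    def test_duplicate_alignments_accumulate(self):
        a = Alignment("chr1", 100, 130, "+", 60)
        t = three_prime_pileup([a, a])
        assert t.value("chr1", "+", 129) == 2
        assert t.total() == 2

    def test_empty_stream_is_empty_track(self):
        t = three_prime_pileup([])
        assert t.total() == 0
        assert t.n_accepted == 0

    def test_invalid_span_counted_and_skipped(self):
        t = three_prime_pileup([Alignment("chr1", 100, 100, "+", 60)])
        assert t.n_skipped == 1
        assert t.total() == 0

    def test_low_mapq_excluded(self):
        t = three_prime_pileup([Alignment("chr1", 100, 130, "+", 5)], min_mapq=10)
        assert t.total() == 0

    @given(st.lists(alignment_st, max_size=60))
    @settings(deadline=None, max_examples=60)
    def test_matches_naive_per_read_oracle(self, alignments):
        t = three_prime_pileup(alignments)
        assert track_as_dict(t) == naive_pileup(alignments)
        assert t.total() == t.n_accepted

    @given(st.lists(alignment_st, max_size=40))
    @settings(deadline=None, max_examples=40)
    def test_flip_strand_is_an_involution(self, alignments):
        """Flipping the library strand twice must equal no flip at all."""
        once = naive_pileup(alignments, flip=True)
        flipped_back = {
            (c, "+" if s == "-" else "-", p): v for (c, s, p), v in once.items()
        }
        # flipping moves the 3' end too, so compare through the oracle
        t = three_prime_pileup(
            [a._replace(strand="+" if a.strand == "-" else "-") for a in alignments],
            flip_strand=True,
        )
        assert track_as_dict(t) == naive_pileup(alignments)


class TestNormalization:
    def test_spike_coverage_arithmetic(self):
        reads = [Alignment("dm_chr", i, i + 50, "+", 60) for i in range(1000)]
        nf = spike_normalization_factor(reads, {"dm_chr"}, 100_000, 1.0)
        assert nf.evidence["spike_coverage"] == pytest.approx(0.5)
        assert nf.value == pytest.approx(2.0)

    def test_identical_samples_identical_factors(self):
        reads = [Alignment("dm_chr", 0, 40, "+", 60)] * 7
        a = spike_normalization_factor(reads, {"dm_chr"}, 1000)
        b = spike_normalization_factor(reads, {"dm_chr"}, 1000)
        assert a.value == b.value

    def test_doubled_spike_fraction_halves_factor(self):
        human = [Alignment("chr1", 0, 50, "+", 60)] * 100
        spike1 = [Alignment("dm_chr", 0, 50, "+", 60)] * 10
        f1 = spike_normalization_factor(human + spike1, {"dm_chr"}, 1000)
        f2 = spike_normalization_factor(human + spike1 * 2, {"dm_chr"}, 1000)
        assert f2.value == pytest.approx(f1.value / 2)

    def test_absent_spike_is_an_error(self):
        with pytest.raises(SpikeInAbsentError):
            spike_normalization_factor(
                [Alignment("chr1", 0, 50, "+", 60)], {"dm_chr"}, 1000
            )

    def test_rrna_interval_default_is_the_pol1_interval(self):
        assert DEFAULT_RRNA_INTERVAL == ("chrUn_GL000220v1", 105424, 118780)

    @pytest.mark.parametrize("count,expected", [(2_000_000, 0.5), (1_000_000, 1.0)])
    def test_rrna_per_million_factor(self, count, expected):
        track = SignalTrack()
        track.add("chrUn_GL000220v1", "+", 110_000, count)
        nf = rrna_normalization_factor(track)
        assert nf.value == pytest.approx(expected)
        assert nf.evidence["rrna_reads"] == count

    def test_rrna_counts_three_prime_ends_from_alignments(self):
        inside = Alignment("chrUn_GL000220v1", 105_400, 105_430, "+", 60)  # 3' end 105429
        outside = Alignment("chrUn_GL000220v1", 105_390, 105_420, "+", 60)  # 3' end 105419
        nf = rrna_normalization_factor([inside, outside])
        assert nf.evidence["rrna_reads"] == 1

    def test_empty_rrna_denominator_is_an_error(self):
        with pytest.raises(ValueError, match="denominator"):
            rrna_normalization_factor(SignalTrack())


class TestScaling:
    def make_track(self, rng):
        t = three_prime_pileup(
            [
                Alignment("chr1", int(s), int(s) + 30, "+", 60)
                for s in rng.integers(0, 300, size=50)
            ]
        )
        return t

    def test_identity_factor(self, rng):
        from polpause.signal import NormalizationFactor

        t = self.make_track(rng)
        scaled = scale_track(t, NormalizationFactor("none", 1.0))
        assert track_as_dict(scaled) == track_as_dict(t)

    def test_scaling_commutes_with_interval_sums(self, rng):
        from polpause.signal import NormalizationFactor

        t = self.make_track(rng)
        scaled = scale_track(t, NormalizationFactor("spike_coverage", 2.5))
        assert scaled.total() == pytest.approx(2.5 * t.total())
        for lo, hi in [(0, 50), (100, 250), (0, 400)]:
            assert scaled.interval_sum("chr1", lo, hi, "+") == pytest.approx(
                2.5 * t.interval_sum("chr1", lo, hi, "+")
            )

    def test_double_scaling_rejected(self, rng):
        from polpause.signal import NormalizationFactor

        t = self.make_track(rng)
        scaled = scale_track(t, NormalizationFactor("spike_coverage", 2.0))
        with pytest.raises(ValueError, match="already scaled"):
            scale_track(scaled, NormalizationFactor("rrna_million", 3.0))


class TestIO:
    def test_bedgraph_round_trip_is_exact(self, tmp_path, rng):
        track = SignalTrack(sample_id="s1")
        for _ in range(200):
            track.add(
                rng.choice(["chr1", "chr2"]),
                rng.choice(["+", "-"]),
                int(rng.integers(0, 500)),
                float(rng.random() * 7),
            )
        plus, minus = tmp_path / "p.bedgraph", tmp_path / "m.bedgraph"
        write_bedgraph_pair(track, plus, minus)
        back = read_bedgraph_pair(plus, minus, sample_id="s1")
        assert track_as_dict(back) == track_as_dict(track)

    def test_minus_strand_written_negative(self, tmp_path):
        track = SignalTrack()
        track.add("chr1", "-", 10, 3.0)
        plus, minus = tmp_path / "p.bedgraph", tmp_path / "m.bedgraph"
        write_bedgraph_pair(track, plus, minus)
        assert "-3.0" in (tmp_path / "m.bedgraph").read_text()

    def test_sam_round_trip(self, tmp_path):
        alns = [
            Alignment("chr1", 100, 130, "+", 60),
            Alignment("chr1", 50, 90, "-", 60),
            Alignment("chr2", 5, 45, "+", 60),
        ]
        path = tmp_path / "reads.sam"
        write_sam(alns, {"chr1": 1000, "chr2": 1000}, path)
        back = sorted(iter_sam(str(path)), key=lambda a: (a.contig, a.start))
        assert back == sorted(alns, key=lambda a: (a.contig, a.start))
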