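"""Strand-specific single-nucleotide 3'-end pileup tracks and normalization.

PRO-seq reads report the 3' end of the nascent RNA — the position of the
engaged polymerase — so the signal of interest is a pileup of the last aligned
base of each read in read orientation, at single-nucleotide resolution.
Cross-sample comparability comes from one of two normalizations: scaling by
the genomic coverage of an exogenous Drosophila spike-in, or (for
alpha-amanitin experiments, where Pol II output itself collapses) scaling per
million reads falling in a Pol-I rRNA interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "SignalTrack",
    "NormalizationFactor",
    "SpikeInAbsentError",
    "three_prime_pileup",
    "spike_normalization_factor",
    "rrna_normalization_factor",
    "scale_track",
    "iter_sam",
    "iter_bed6",
    "read_alignments",
    "write_bed6",
    "write_sam",
    "write_bedgraph_pair",
    "read_bedgraph_pair",
    "write_track_manifest",
    "DEFAULT_RRNA_INTERVAL",
]

#: Pol-I rRNA interval used as the alpha-amanitin-insensitive denominator.
DEFAULT_RRNA_INTERVAL: tuple[str, int, int] = ("chrUn_GL000220v1", 105424, 118780)


class Alignment(NamedTuple):
    """A minimal aligned-read record (0-based half-open reference span)."""

    contig: str
    start: int
    end: int
    strand: str
    mapq: int = 255


class SpikeInAbsentError(ValueError):
    """No alignments on any spike-in contig; spike normalization impossible."""


@dataclass
class SignalTrack:
    """Sparse strand-specific map (contig, strand, position) -> signal.

    Raw tracks hold integer counts whose total equals the number of accepted
    alignments; after :func:`scale_track` the values carry the normalization
    factor and ``library_units`` records which scheme was applied.
    """

    sample_id: str = ""
    scale_applied: float = 1.0
    library_units: str = "raw_reads"
    n_accepted: int = 0
    n_skipped: int = 0
    _data: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    _sorted: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    def add(self, contig: str, strand: str, pos: int, value: float = 1.0) -> None:
        d = self._data.setdefault((contig, strand), {})
        d[pos] = d.get(pos, 0.0) + value
        self._sorted.pop((contig, strand), None)

    def value(self, contig: str, strand: str, pos: int) -> float:
        return self._data.get((contig, strand), {}).get(pos, 0.0)

    def total(self) -> float:
        return sum(sum(d.values()) for d in self._data.values())

    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._data)

    def positions(self, contig: str, strand: str) -> dict[int, float]:
        return dict(self._data.get((contig, strand), {}))

    def _arrays(self, contig: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        key = (contig, strand)
        cached = self._sorted.get(key)
        if cached is None:
            d = self._data.get(key, {})
            pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
            order = np.argsort(pos, kind="stable")
            vals = np.fromiter(d.values(), dtype=np.float64, count=len(d))[order]
            cached = (pos[order], vals)
            self._sorted[key] = cached
        return cached

    def interval_sum(
        self, contig: str, start: int, end: int, strand: str | None = None
    ) -> float:
        """Sum of values at positions in ``[start, end)``.

        With ``strand=None`` both strands are summed (strand-agnostic window
        quantification); otherwise counting is restricted to one strand.
        """
        strands = ("+", "-") if strand is None else (strand,)
        total = 0.0
        for s in strands:
            pos, vals = self._arrays(contig, s)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            total += float(vals[lo:hi].sum())
        return total

    def scaled(self, factor: float, library_units: str) -> "SignalTrack":
        out = SignalTrack(
            sample_id=self.sample_id,
            scale_applied=self.scale_applied * factor,
            library_units=library_units,
            n_accepted=self.n_accepted,
            n_skipped=self.n_skipped,
        )
        for key, d in self._data.items():
            out._data[key] = {p: v * factor for p, v in d.items()}
        return out


@dataclass(frozen=True)
class NormalizationFactor:
    """A multiplicative track scale with the evidence it was derived from."""

    mode: str  # {"spike_coverage", "rrna_million", "none"}
    value: float
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"normalization factor must be > 0, got {self.value}")


# ---------------------------------------------------------------------------
# alignment input
# ---------------------------------------------------------------------------

def iter_sam(path: str | Path, mode: str | None = None) -> Iterator[Alignment]:
    """Yield alignments from SAM/BAM via pysam.

    Unmapped, secondary and supplementary records are excluded.
    """
    import pysam

    with pysam.AlignmentFile(str(path), mode) as fh:  # type: ignore[arg-type]
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            yield Alignment(
                contig=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                mapq=rec.mapping_quality,
            )


def iter_bed6(path: str | Path) -> Iterator[Alignment]:
    """Yield alignments from a BED6 file (score column read as MAPQ)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 alignment needs 6 columns"
                )
            chrom, start, end, _name, score, strand = fields[:6]
            yield Alignment(chrom, int(start), int(end), strand, int(float(score)))


def read_alignments(path: str | Path) -> Iterator[Alignment]:
    """Dispatch on extension: .sam/.bam via pysam, .bed via the BED6 reader."""
    suffix = Path(path).suffix.lower()
    if suffix in (".sam", ".bam", ".cram"):
        return iter_sam(path)
    if suffix in (".bed", ".bed6"):
        return iter_bed6(path)
    raise ValueError(f"unrecognized alignment format: {path}")


def write_bed6(alignments: Iterable[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, a in enumerate(alignments):
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\tread{i}\t{a.mapq}\t{a.strand}\n")


def write_sam(
    alignments: Sequence[Alignment],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write coordinate-sorted SAM (or BAM if the path ends in .bam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    ordered = sorted(alignments, key=lambda a: (tid[a.contig], a.start))
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for i, a in enumerate(ordered):
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = f"read{i}"
            rec.reference_id = tid[a.contig]
            rec.reference_start = a.start
            rec.mapping_quality = a.mapq
            rec.cigartuples = [(0, a.end - a.start)]
            rec.flag = 16 if a.strand == "-" else 0
            rec.query_sequence = "N" * (a.end - a.start)
            out.write(rec)


# ---------------------------------------------------------------------------
# pileup and normalization
# ---------------------------------------------------------------------------

def three_prime_pileup(
    alignments: Iterable[Alignment],
    min_mapq: int = 10,
    flip_strand: bool = False,
    sample_id: str = "",
) -> SignalTrack:
    """Pile up the last aligned base of each read in read orientation.

    A plus-strand alignment over ``[start, end)`` contributes +1 at
    ``end - 1``; a minus-strand alignment contributes +1 at ``start``. With
    ``flip_strand`` the recorded strand of each alignment is inverted before
    the last-base rule is applied, covering library dialects sequenced from
    the reverse complement. Records with ``end <= start`` are counted in
    ``n_skipped`` and dropped; an empty stream yields an empty track.
    """
    track = SignalTrack(sample_id=sample_id)
    for a in alignments:
        if a.mapq < min_mapq:
            continue
        if a.end <= a.start:
            track.n_skipped += 1
            continue
        strand = a.strand
        if flip_strand:
            strand = "-" if strand == "+" else "+"
        pos = a.end - 1 if strand == "+" else a.start
        track.add(a.contig, strand, pos)
        track.n_accepted += 1
    return track


def spike_normalization_factor(
    alignments: Iterable[Alignment],
    spike_contigs: Iterable[str],
    spike_genome_length: int,
    reference_coverage: float = 1.0,
) -> NormalizationFactor:
    """Scale factor from the genomic coverage of spike-in alignments.

    ``coverage`` is total aligned bases on the spike contigs divided by the
    spike genome length; the factor is ``reference_coverage / coverage`` so a
    sample with more spike-in signal (i.e. sequenced deeper) is scaled down.
    """
    if spike_genome_length <= 0:
        raise ValueError("spike_genome_length must be > 0")
    spike = set(spike_contigs)
    aligned_bases = 0
    n_alignments = 0
    for a in alignments:
        if a.contig in spike and a.end > a.start:
            aligned_bases += a.end - a.start
            n_alignments += 1
    if n_alignments == 0:
        raise SpikeInAbsentError("spike-in absent: no alignments on spike contigs")
    coverage = aligned_bases / spike_genome_length
    return NormalizationFactor(
        mode="spike_coverage",
        value=reference_coverage / coverage,
        evidence={
            "spike_coverage": coverage,
            "spike_aligned_bases": aligned_bases,
            "spike_alignments": n_alignments,
        },
    )


def rrna_normalization_factor(
    source: SignalTrack | Iterable[Alignment],
    rrna_interval: tuple[str, int, int] = DEFAULT_RRNA_INTERVAL,
) -> NormalizationFactor:
    """Per-million-rRNA-reads scale factor.

    Counts alignments whose 3' end falls inside ``rrna_interval`` (strand
    agnostic) and returns ``1e6 / count``. Accepts either a raw pileup track
    or an alignment stream.
    """
    contig, lo, hi = rrna_interval
    if hi <= lo:
        raise ValueError("invalid rRNA interval")
    if isinstance(source, SignalTrack):
        count = source.interval_sum(contig, lo, hi, strand=None)
    else:
        count = 0
        for a in source:
            if a.contig != contig or a.end <= a.start:
                continue
            pos = a.end - 1 if a.strand == "+" else a.start
            if lo <= pos < hi:
                count += 1
    if count <= 0:
        raise ValueError("rRNA denominator empty: no reads in the rRNA interval")
    return NormalizationFactor(
        mode="rrna_million",
        value=1e6 / count,
        evidence={"rrna_reads": count, "interval": rrna_interval},
    )


_UNITS_BY_MODE = {
    "spike_coverage": "spike_normalized",
    "rrna_million": "rrna_normalized",
    "none": "raw_reads",
}


def scale_track(track: SignalTrack, factor: NormalizationFactor) -> SignalTrack:
    """Apply a normalization factor; double scaling is an error."""
    if track.library_units != "raw_reads":
        raise ValueError(
            f"track already scaled ({track.library_units}); refusing to rescale"
        )
    return track.scaled(factor.value, _UNITS_BY_MODE[factor.mode])


# ---------------------------------------------------------------------------
# bedGraph export / import
# ---------------------------------------------------------------------------

def _runs(d: dict[int, float]) -> Iterator[tuple[int, int, float]]:
    """Merge consecutive equal-valued positions into bedGraph runs."""
    pos = sorted(d)
    i = 0
    while i < len(pos):
        j = i
        while (
            j + 1 < len(pos)
            and pos[j + 1] == pos[j] + 1
            and d[pos[j + 1]] == d[pos[i]]
        ):
            j += 1
        yield pos[i], pos[j] + 1, d[pos[i]]
        i = j + 1


def write_bedgraph_pair(
    track: SignalTrack, plus_path: str | Path, minus_path: str | Path
) -> None:
    """Write one bedGraph per strand; minus values are written negative.

    Values are serialized with ``repr`` so that re-reading reproduces the
    track exactly (shortest round-trip decimal representation).
    """
    for path, strand, sign in ((plus_path, "+", 1.0), (minus_path, "-", -1.0)):
        with open(path, "w") as fh:
            for contig in sorted({c for c, s in track.keys() if s == strand}):
                for lo, hi, val in _runs(track._data[(contig, strand)]):
                    fh.write(f"{contig}\t{lo}\t{hi}\t{repr(sign * val)}\n")


def read_bedgraph_pair(
    plus_path: str | Path,
    minus_path: str | Path,
    sample_id: str = "",
    library_units: str = "raw_reads",
) -> SignalTrack:
    """Read a plus/minus bedGraph pair written by :func:`write_bedgraph_pair`."""
    track = SignalTrack(sample_id=sample_id, library_units=library_units)
    for path, strand, sign in ((plus_path, "+", 1.0), (minus_path, "-", -1.0)):
        with open(path) as fh:
            for line in fh:
                if line.startswith(("#", "track")) or not line.strip():
                    continue
                contig, lo, hi, val = line.rstrip("\n").split("\t")
                v = sign * float(val)
                for p in range(int(lo), int(hi)):
                    track.add(contig, strand, p, v)
    return track


def write_track_manifest(rows: Iterable[dict], path: str | Path) -> None:
    """TSV manifest: sample_id, files, normalization mode, factor, evidence."""
    import pandas as pd

    pd.DataFrame(list(rows)).to_csv(path, sep="\t", index=False)
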