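"""Per-gene IP enrichment and fixed-window locus signal quantification.

Covers the quantification layer shared by ChIP-style and in situ
biotinylation-style experiments — counts-per-million normalization followed by
per-gene IP/input ratios or IP-input differences — and the locus-level sum of
a contact/coverage track over fixed genomic windows, with the two human
replication-dependent histone clusters shipped as named presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .signal import Alignment, SignalTrack

__all__ = [
    "EnrichmentRecord",
    "LocusSignal",
    "cpm_normalize",
    "per_gene_enrichment",
    "count_fragments_by_gene",
    "window_signal",
    "HISTONE_LOCUS_PRESETS",
    "locus_presets_to_bed",
]

#: The two human replication-dependent histone gene clusters (GRCh38),
#: 0-based half-open genomic windows.
HISTONE_LOCUS_PRESETS: Mapping[str, tuple[tuple[str, int, int], ...]] = {
    "histone_cluster_1": (
        ("chr6", 27130000, 27150000),
        ("chr6", 27801000, 27903000),
    ),
    "histone_cluster_2": (("chr1", 149780000, 149890000),),
}


@dataclass(frozen=True)
class EnrichmentRecord:
    """CPM-scale IP vs input comparison for one gene."""

    gene_id: str
    ip_cpm: float
    input_cpm: float
    ratio: float
    difference: float


@dataclass(frozen=True)
class LocusSignal:
    """Total track signal over one named set of genomic windows."""

    locus_name: str
    intervals: tuple[tuple[str, int, int], ...]
    total_signal: float


def cpm_normalize(
    counts: Mapping[str, float] | pd.Series, library_total: int
) -> pd.Series:
    """Counts per million: ``count * 1e6 / library_total``."""
    if library_total <= 0:
        raise ValueError("library_total must be > 0")
    s = pd.Series(counts, dtype=float)
    return s * 1e6 / library_total


def per_gene_enrichment(
    ip: Mapping[str, float] | pd.Series,
    input_: Mapping[str, float] | pd.Series,
    pseudocount: float = 1.0,
) -> list[EnrichmentRecord]:
    """IP/input ratio and IP-input difference per gene, on CPM inputs.

    The ratio uses a symmetric pseudocount, ``(ip + pc) / (input + pc)``
    (default 1 CPM), so unobserved genes get ratio 1 rather than a division
    error; the difference is plain ``ip - input`` and may be negative. The
    gene sets must overlap.
    """
    ip = pd.Series(ip, dtype=float)
    input_ = pd.Series(input_, dtype=float)
    shared = sorted(set(ip.index) & set(input_.index))
    if not shared:
        raise ValueError("disjoint gene sets between IP and input")
    return [
        EnrichmentRecord(
            gene_id=g,
            ip_cpm=float(ip[g]),
            input_cpm=float(input_[g]),
            ratio=(float(ip[g]) + pseudocount) / (float(input_[g]) + pseudocount),
            difference=float(ip[g]) - float(input_[g]),
        )
        for g in shared
    ]


def count_fragments_by_gene(
    alignments: Iterable[Alignment], genes: Sequence[GeneModel]
) -> pd.Series:
    """Assign fragments to genes by midpoint overlap with the gene span.

    A fragment whose midpoint falls inside several (overlapping) gene spans
    counts for each of them — per-gene counts are independent interval sums,
    which is the right behaviour inside dense histone clusters.
    """
    mids: dict[str, list[int]] = {}
    for a in alignments:
        mids.setdefault(a.contig, []).append((a.start + a.end) // 2)
    mid_arrays = {c: np.sort(np.array(v)) for c, v in mids.items()}
    counts = {}
    for g in genes:
        arr = mid_arrays.get(g.chrom)
        if arr is None:
            counts[g.gene_id] = 0
        else:
            counts[g.gene_id] = int(
                np.searchsorted(arr, g.end, side="left")
                - np.searchsorted(arr, g.start, side="left")
            )
    return pd.Series(counts, dtype=float)


def window_signal(
    track: SignalTrack,
    intervals: str | Sequence[tuple[str, int, int]],
    locus_name: str | None = None,
) -> LocusSignal:
    """Strand-agnostic total track signal over a list of genomic windows.

    ``intervals`` may be a preset name from :data:`HISTONE_LOCUS_PRESETS` or
    an explicit list of ``(contig, start, end)`` half-open windows. Additive
    over disjoint interval lists; an empty track yields 0.0.
    """
    if isinstance(intervals, str):
        locus_name = locus_name or intervals
        intervals = HISTONE_LOCUS_PRESETS[intervals]
    ivs = tuple(tuple(iv) for iv in intervals)
    total = 0.0
    for contig, lo, hi in ivs:
        if hi < lo:
            raise ValueError(f"invalid interval {contig}:{lo}-{hi}")
        total += track.interval_sum(contig, lo, hi, strand=None)
    return LocusSignal(
        locus_name=locus_name or "custom", intervals=ivs, total_signal=total
    )


def locus_presets_to_bed(path: str | Path) -> None:
    """Write the named locus presets as a BED file."""
    with open(path, "w") as fh:
        for name, ivs in HISTONE_LOCUS_PRESETS.items():
            for contig, lo, hi in ivs:
                fh.write(f"{contig}\t{lo}\t{hi}\t{name}\n")
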