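"""Per-gene Pol II pausing statistics and paired condition comparisons.

Two pausing indices are computed per gene as signal-density ratios:

* TPP (TES-proximal pausing) = density in the TES-proximal window (TESr)
  over density in the gene body (GB) — high at replication-dependent histone
  genes where Pol II pauses over the stem-loop just upstream of the TES;
* PPP (promoter-proximal pausing) = density in the TSS-proximal window (TSSr)
  over GB density.

A pseudocount on the denominator count keeps indices finite at sparse gene
bodies. The read-through ratio quantifies termination failure as signal in
TES+1..TES+200 over TSS..TSS+200 (or over the gene body, selectable), and an
expression filter keeps only genes whose spike-normalized TSS-proximal signal
exceeds a threshold. Paired per-class condition contrasts use the two-sided
Wilcoxon signed-rank test with exact sign-flip enumeration at small n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import GeneModel, RegionSet
from .signal import SignalTrack

__all__ = [
    "PausingRecord",
    "ClassComparison",
    "window_counts",
    "tpp_index",
    "ppp_index",
    "readthrough_ratio",
    "filter_expressed",
    "compute_pausing_records",
    "records_to_frame",
    "compare_conditions",
    "wilcoxon_signed_rank",
    "class_summary",
]


@dataclass
class PausingRecord:
    """Window counts and pausing statistics for one gene.

    ``tpp_index``/``ppp_index`` are ``None`` for ineligible genes (degenerate
    window geometry) and ``readthrough_ratio`` is ``None`` when its
    denominator window is empty; such genes are excluded from summaries
    rather than propagating NaN.
    """

    gene_id: str
    gene_class: str = "other_noncoding"
    tssr_count: float = 0.0
    gb_count: float = 0.0
    tesr_count: float = 0.0
    rt_count: float = 0.0
    tss200_count: float = 0.0
    tpp_index: float | None = None
    ppp_index: float | None = None
    readthrough_ratio: float | None = None
    passes_filter: bool = False
    eligible: bool = True


@dataclass(frozen=True)
class ClassComparison:
    """Paired two-condition contrast for one gene class."""

    gene_class: str
    n_pairs: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    test_name: str = "wilcoxon_signed_rank_two_sided"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def window_counts(
    track: SignalTrack, regions: RegionSet, gene_class: str = "other_noncoding"
) -> PausingRecord:
    """Sum strand-matched track values in each analysis window of one gene."""

    def wsum(iv: tuple[int, int]) -> float:
        return track.interval_sum(regions.chrom, iv[0], iv[1], strand=regions.strand)

    return PausingRecord(
        gene_id=regions.gene_id,
        gene_class=gene_class,
        tssr_count=wsum(regions.tssr),
        gb_count=wsum(regions.gb),
        tesr_count=wsum(regions.tesr),
        rt_count=wsum(regions.rt),
        tss200_count=wsum(regions.tss200),
        eligible=regions.eligible,
    )


def _length(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


def tpp_index(
    record: PausingRecord,
    regions: RegionSet,
    pseudocount: float = 1.0,
    density: bool = True,
) -> float | None:
    """TES-proximal pausing index.

    Density form (default): ``(tesr/len(tesr)) / ((gb + pseudocount)/len(gb))``
    so unequal window lengths are comparable; the pseudocount applies to the
    denominator count only. ``density=False`` gives the raw-sum variant
    ``tesr / (gb + pseudocount)``. Returns ``None`` for ineligible genes.
    """
    if not record.eligible:
        return None
    gb = record.gb_count + pseudocount
    if density:
        return (record.tesr_count / _length(regions.tesr)) / (gb / _length(regions.gb))
    return record.tesr_count / gb


def ppp_index(
    record: PausingRecord,
    regions: RegionSet,
    pseudocount: float = 1.0,
    density: bool = True,
) -> float | None:
    """Promoter-proximal pausing index; as :func:`tpp_index` with TSSr."""
    if not record.eligible:
        return None
    gb = record.gb_count + pseudocount
    if density:
        return (record.tssr_count / _length(regions.tssr)) / (gb / _length(regions.gb))
    return record.tssr_count / gb


def readthrough_ratio(record: PausingRecord, mode: str = "tss200") -> float | None:
    """Termination read-through: RT-window signal over a reference window.

    ``mode="tss200"`` (default) divides by the TSS..TSS+200 signal;
    ``mode="genebody"`` divides by the gene-body signal. A zero denominator
    yields ``None`` and the gene is dropped from ratio summaries.
    """
    if mode == "tss200":
        denom = record.tss200_count
    elif mode == "genebody":
        denom = record.gb_count
    else:
        raise ValueError(f"unknown read-through mode {mode!r}")
    if denom <= 0:
        return None
    return record.rt_count / denom


def filter_expressed(
    records: Iterable[PausingRecord], threshold: float = 10.0
) -> list[PausingRecord]:
    """Flag genes whose TSS-proximal (tss200) signal strictly exceeds threshold.

    Intended for spike-normalized counts; non-passing records are retained
    with ``passes_filter=False`` and excluded from ratio/box summaries.
    """
    return [
        replace(r, passes_filter=r.tss200_count > threshold) for r in records
    ]


def compute_pausing_records(
    track: SignalTrack,
    genes: Iterable[GeneModel],
    regions: Mapping[str, RegionSet],
    pseudocount: float = 1.0,
    density: bool = True,
    readthrough_mode: str = "tss200",
    filter_threshold: float = 10.0,
) -> list[PausingRecord]:
    """Full per-gene pausing table: counts, indices, ratio, filter flag."""
    out: list[PausingRecord] = []
    for g in genes:
        rs = regions[g.gene_id]
        rec = window_counts(track, rs, gene_class=g.gene_class)
        rec.tpp_index = tpp_index(rec, rs, pseudocount, density)
        rec.ppp_index = ppp_index(rec, rs, pseudocount, density)
        rec.readthrough_ratio = readthrough_ratio(rec, readthrough_mode)
        out.append(rec)
    return filter_expressed(out, filter_threshold)


def records_to_frame(records: Iterable[PausingRecord]) -> pd.DataFrame:
    """Per-gene TSV-ready table of counts, statistics and flags."""
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "gene_class": r.gene_class,
                "tssr_count": r.tssr_count,
                "gb_count": r.gb_count,
                "tesr_count": r.tesr_count,
                "rt_count": r.rt_count,
                "tss200_count": r.tss200_count,
                "tpp_index": r.tpp_index,
                "ppp_index": r.ppp_index,
                "readthrough_ratio": r.readthrough_ratio,
                "passes_filter": r.passes_filter,
                "eligible": r.eligible,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

#: Largest n for which the null is enumerated exactly (2^n sign flips).
EXACT_ENUMERATION_MAX_N = 15


def wilcoxon_signed_rank(differences: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention). For
    ``n <= EXACT_ENUMERATION_MAX_N`` the p-value comes from exhaustive
    enumeration of all 2^n sign assignments of the observed absolute ranks
    (tied ranks averaged); above that, a normal approximation with continuity
    and tie correction is used. Returns ``(W_plus, p)``; all differences zero
    gives ``p = 1.0`` with a warning.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1.0", stacklevel=2)
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_ENUMERATION_MAX_N:
        # Enumerate W+ over all 2^n sign assignments of the observed ranks.
        masks = np.arange(2**n, dtype=np.uint32)
        bits = (masks[:, None] >> np.arange(n, dtype=np.uint32)) & 1
        w_all = bits @ ranks
        eps = 1e-9
        n_le = int(np.count_nonzero(w_all <= w_plus + eps))
        n_ge = int(np.count_nonzero(w_all >= w_plus - eps))
        p = 2.0 * min(n_le, n_ge) / 2**n
        return w_plus, min(p, 1.0)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float((tie_counts**3 - tie_counts).sum()) / 48.0
    if var <= 0:
        return w_plus, 1.0
    # continuity correction toward the mean
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = float(2.0 * (1.0 - _norm_cdf(abs(z))))
    return w_plus, min(p, 1.0)


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def compare_conditions(
    values_a: Mapping[str, float],
    values_b: Mapping[str, float],
    gene_class: str = "all",
) -> ClassComparison:
    """Paired two-sided Wilcoxon signed-rank contrast of per-gene statistics.

    ``values_a``/``values_b`` map gene_id -> statistic in the two conditions;
    only genes present (and non-None) in both are paired. No overlapping
    genes is an error.
    """
    shared = sorted(
        g
        for g in values_a
        if g in values_b and values_a[g] is not None and values_b[g] is not None
    )
    if not shared:
        raise ValueError("no genes present in both conditions")
    a = np.array([values_a[g] for g in shared], dtype=float)
    b = np.array([values_b[g] for g in shared], dtype=float)
    stat, p = wilcoxon_signed_rank(a - b)
    return ClassComparison(
        gene_class=gene_class,
        n_pairs=len(shared),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=stat,
        p_value=p,
    )


def class_summary(
    records: Iterable[PausingRecord], statistic: str = "tpp_index"
) -> pd.DataFrame:
    """Boxplot-style per-class summary (median and quartiles).

    Computed only over eligible, filter-passing genes with a defined value of
    the requested statistic.
    """
    rows: dict[str, list[float]] = {}
    for r in records:
        if not (r.eligible and r.passes_filter):
            continue
        v = getattr(r, statistic)
        if v is None:
            continue
        rows.setdefault(r.gene_class, []).append(v)
    return pd.DataFrame(
        [
            {
                "gene_class": cls,
                "n": len(vals),
                "q1": float(np.percentile(vals, 25)),
                "median": float(np.median(vals)),
                "q3": float(np.percentile(vals, 75)),
            }
            for cls, vals in sorted(rows.items())
        ]
    )
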