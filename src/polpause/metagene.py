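"""Anchor-centered meta-gene matrices and mean profiles.

Rows are genes, columns are fixed-width bins of transcript-oriented offsets
around an anchor (TSS or TES). Minus-strand genes are flipped at construction
time, so offset ``+x`` always means downstream of the anchor in transcript
orientation and profiles from the two strands superimpose directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .signal import SignalTrack

__all__ = ["MetageneMatrix", "Profile", "anchor_matrix", "mean_profile"]


@dataclass
class MetageneMatrix:
    """Genes x bins matrix of strand-matched signal around an anchor.

    ``offsets`` holds the transcript-oriented start offset of each bin;
    bin ``j`` covers offsets ``[offsets[j], offsets[j] + binsize)``.
    """

    anchors: list[tuple[str, int, str]]  # (gene_id, anchor position, strand)
    offsets: np.ndarray
    values: np.ndarray
    binsize: int
    anchor: str
    per_gene_normalized: bool = False

    @property
    def gene_ids(self) -> list[str]:
        return [a[0] for a in self.anchors]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.offsets
        )


@dataclass
class Profile:
    """A mean meta-gene profile over bins."""

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int
    n_dropped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "signal": self.values})


def anchor_matrix(
    track: SignalTrack,
    genes: list[GeneModel],
    anchor: str = "TES",
    upstream: int = 500,
    downstream: int = 500,
    binsize: int = 10,
) -> MetageneMatrix:
    """Build the genes x bins matrix of 3'-end signal around TSS or TES.

    Counting is strand-matched to each gene. For a plus-strand gene, bin j
    covers genomic ``[a + lo, a + lo + binsize)``; for a minus-strand gene the
    mirrored genomic bin is used and stored at the same transcript-oriented
    offset, so rows never need post-hoc flipping. Window parts beyond contig
    edges simply contribute zero (sparse track).
    """
    if not genes:
        raise ValueError("no genes supplied for meta-gene analysis")
    if (upstream + downstream) % binsize != 0:
        raise ValueError("upstream + downstream must be divisible by binsize")
    if anchor not in ("TSS", "TES"):
        raise ValueError(f"anchor must be TSS or TES, got {anchor!r}")

    n_bins = (upstream + downstream) // binsize
    offsets = np.arange(n_bins) * binsize - upstream
    values = np.zeros((len(genes), n_bins))
    anchors: list[tuple[str, int, str]] = []
    for gi, g in enumerate(genes):
        a = g.tss if anchor == "TSS" else g.tes
        anchors.append((g.gene_id, a, g.strand))
        for j, lo in enumerate(offsets):
            hi = lo + binsize
            if g.strand == "+":
                glo, ghi = a + lo, a + hi
            else:
                # transcript offset x maps to genomic a - x
                glo, ghi = a - hi + 1, a - lo + 1
            values[gi, j] = track.interval_sum(g.chrom, glo, ghi, strand=g.strand)
    return MetageneMatrix(
        anchors=anchors,
        offsets=offsets,
        values=values,
        binsize=binsize,
        anchor=anchor,
    )


def mean_profile(matrix: MetageneMatrix, per_gene_norm: str = "none") -> Profile:
    """Average the matrix rows into one profile.

    ``per_gene_norm="row_sum"`` divides each row by its total before
    averaging (rows summing to zero are dropped, with the dropped count
    reported); ``"none"`` takes the plain column mean.
    """
    if matrix.values.size == 0:
        raise ValueError("empty meta-gene matrix")
    if per_gene_norm == "none":
        return Profile(
            offsets=matrix.offsets,
            values=matrix.values.mean(axis=0),
            n_genes=matrix.values.shape[0],
        )
    if per_gene_norm != "row_sum":
        raise ValueError(f"unknown per_gene_norm {per_gene_norm!r}")
    totals = matrix.values.sum(axis=1)
    keep = totals > 0
    if not keep.any():
        raise ValueError("all rows sum to zero; row_sum profile undefined")
    normed = matrix.values[keep] / totals[keep, None]
    return Profile(
        offsets=matrix.offsets,
        values=normed.mean(axis=0),
        n_genes=int(keep.sum()),
        n_dropped=int((~keep).sum()),
    )
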