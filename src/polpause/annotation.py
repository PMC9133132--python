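"""Gene models, transcript collapsing, and analysis windows.

A transcription unit is represented by a single :class:`GeneModel` with a
strand, a transcription start site (TSS) and a transcript end site (TES).
Internal coordinates are 0-based half-open throughout; the TES is the final
transcribed base (inclusive), so on the plus strand ``TES == end - 1`` and the
read-through window "TES to TES + 200 bp" is the half-open interval
``[end, end + 200)``.

Transcripts sharing a TSS or a TES on the same strand are collapsed into one
unit before any pausing statistics are computed, mirroring how annotation
redundancy is handled when refGene-style transcript sets feed a per-gene
analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

GENE_CLASSES = (
    "RDH",
    "snRNA",
    "snoRNA",
    "rRNA",
    "protein_coding",
    "other_noncoding",
)

#: Merge priority when collapsed transcripts disagree on class. RDH first so a
#: histone unit overlapping a host transcript keeps its focus class.
CLASS_PRIORITY: Mapping[str, int] = {c: i for i, c in enumerate(GENE_CLASSES)}

#: GTF ``gene_biotype`` values mapped onto the internal class labels. Anything
#: absent from this table becomes ``other_noncoding``.
BIOTYPE_MAP: Mapping[str, str] = {
    "protein_coding": "protein_coding",
    "snRNA": "snRNA",
    "snoRNA": "snoRNA",
    "rRNA": "rRNA",
    "rRNA_pseudogene": "rRNA",
    "Mt_rRNA": "rRNA",
}


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True)
class GeneModel:
    """One collapsed transcription unit.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``strand`` is
    ``"+"`` or ``"-"``; ``gene_class`` is one of :data:`GENE_CLASSES`.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    gene_class: str = "other_noncoding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id!r}: invalid strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id!r}: start {self.start} must be < end {self.end}"
            )
        if self.gene_class not in CLASS_PRIORITY:
            raise AnnotationError(
                f"gene {self.gene_id!r}: unknown gene_class {self.gene_class!r}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site (inclusive base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcript end site: the final transcribed base (inclusive)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowParams:
    """Lengths (nt) of the per-gene analysis windows.

    ``tssr_len`` and ``tesr_len`` set the promoter-proximal and TES-proximal
    pause windows feeding the PPP and TPP indices; ``tss200_len``/``rt_len``
    are the read-through ratio windows (TSS..TSS+200 over TES+1..TES+200 by
    default). The gene body (GB) is whatever lies between TSSr and TESr, and
    genes whose GB would be shorter than ``min_gb_length`` are flagged
    ineligible rather than silently shrunk.
    """

    tssr_len: int = 150
    tesr_len: int = 100
    tss200_len: int = 200
    rt_len: int = 200
    min_gene_length: int = 150
    min_gb_length: int = 50


Interval = tuple[int, int]


@dataclass(frozen=True)
class RegionSet:
    """Analysis windows for one gene, all 0-based half-open on the genome.

    On the plus strand ``tssr`` starts at the TSS and ``rt`` starts one base
    past the TES; minus-strand genes are mirrored. ``eligible`` is False when
    the gene is too short for a non-degenerate gene body, in which case the
    interior windows are unusable and ``reason`` says why. ``clipped`` marks
    windows truncated at contig bounds.
    """

    gene_id: str
    chrom: str
    strand: str
    tssr: Interval
    gb: Interval
    tesr: Interval
    rt: Interval
    tss200: Interval
    eligible: bool = True
    reason: str = ""
    clipped: bool = False

    def window(self, name: str) -> Interval:
        return getattr(self, name)


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _class_from_attrs(
    gene_id: str,
    attrs: Mapping[str, str],
    class_table: Mapping[str, str] | None,
) -> str:
    if class_table is not None and gene_id in class_table:
        return class_table[gene_id]
    if "gene_class" in attrs:
        return attrs["gene_class"]
    biotype = attrs.get("gene_biotype", attrs.get("gene_type", ""))
    return BIOTYPE_MAP.get(biotype, "other_noncoding")


def _load_gtf(
    path: Path, class_table: Mapping[str, str] | None
) -> list[GeneModel]:
    transcripts: list[GeneModel] = []
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr = fields
            if feature not in ("transcript", "gene"):
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            attrs = _parse_gtf_attributes(attr)
            gene_id = attrs.get("transcript_id") or attrs.get("gene_id")
            if not gene_id:
                raise AnnotationError(
                    f"{path}:{lineno}: record without transcript_id/gene_id"
                )
            try:
                model = GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start1 - 1,  # GTF is 1-based inclusive
                    end=end1,
                    strand=strand,
                    gene_class=_class_from_attrs(gene_id, attrs, class_table),
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            (transcripts if feature == "transcript" else genes).append(model)
    # Prefer transcript records; fall back to gene records for GTFs that
    # carry only gene lines.
    return transcripts if transcripts else genes


def _load_gene_bed(
    path: Path, class_table: Mapping[str, str] | None
) -> list[GeneModel]:
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise AnnotationError(
                    f"{path}:{lineno}: gene-bed needs 7 columns "
                    "(chrom start end gene_id score strand gene_class), "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, gene_id, _score, strand, gene_class = fields[:7]
            try:
                start = int(start_s)
                end = int(end_s)
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if class_table is not None and gene_id in class_table:
                gene_class = class_table[gene_id]
            try:
                models.append(
                    GeneModel(gene_id, chrom, start, end, strand, gene_class)
                )
            except AnnotationError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return models


def load_gene_models(
    path: str | Path,
    format: str = "gene-bed",
    class_table: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Load gene models from GTF or the 7-column gene-bed dialect.

    GTF coordinates (1-based inclusive) are shifted into the internal 0-based
    half-open convention. Gene classes come from a ``gene_class`` attribute /
    column, from a supplied ``class_table`` (gene_id -> class), or from the
    GTF ``gene_biotype``. Duplicate gene ids and unknown strand symbols are
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gtf":
        models = _load_gtf(path, class_table)
    elif format == "gene-bed":
        models = _load_gene_bed(path, class_table)
    else:
        raise ValueError(f"unrecognized annotation format {format!r}")
    seen: set[str] = set()
    for m in models:
        if m.gene_id in seen:
            raise AnnotationError(f"duplicate gene_id {m.gene_id!r} in {path}")
        seen.add(m.gene_id)
    return models


def collapse_shared_ends(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Merge transcripts on the same chrom/strand sharing a TSS or a TES.

    Sharing is transitive (union-find): if A shares a TSS with B and B shares
    a TES with C, all three become one unit spanning ``min(start)..max(end)``.
    The merged id is the lexicographically first member id and the class is
    taken by :data:`CLASS_PRIORITY`. Idempotent, and the empty input maps to
    the empty output.
    """
    models = sorted(models, key=lambda m: (m.chrom, m.start, m.end, m.gene_id))
    parent = list(range(len(models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_key: dict[tuple, int] = {}
    for i, m in enumerate(models):
        # On a given strand a shared TSS is a shared start or a shared end,
        # so grouping on both boundary coordinates covers TSS and TES.
        for key in ((m.chrom, m.strand, "s", m.start), (m.chrom, m.strand, "e", m.end)):
            if key in by_key:
                union(by_key[key], i)
            else:
                by_key[key] = i

    groups: dict[int, list[GeneModel]] = {}
    for i, m in enumerate(models):
        groups.setdefault(find(i), []).append(m)

    merged: list[GeneModel] = []
    for members in groups.values():
        if len(members) == 1:
            merged.append(members[0])
            continue
        merged.append(
            GeneModel(
                gene_id=min(m.gene_id for m in members),
                chrom=members[0].chrom,
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                strand=members[0].strand,
                gene_class=min(
                    (m.gene_class for m in members), key=CLASS_PRIORITY.__getitem__
                ),
            )
        )
    merged.sort(key=lambda m: (m.chrom, m.start, m.end, m.gene_id))
    return merged


def _clip(iv: Interval, contig_length: int | None) -> tuple[Interval, bool]:
    lo, hi = iv
    nlo = max(lo, 0)
    nhi = hi if contig_length is None else min(hi, contig_length)
    return (nlo, nhi), (nlo, nhi) != (lo, hi)


def define_regions(
    model: GeneModel,
    params: WindowParams = WindowParams(),
    contig_length: int | None = None,
) -> RegionSet:
    """Derive the TSSr / GB / TESr / RT / TSS200 windows for one gene.

    All windows are orientation-aware: on the minus strand TSSr ends at the
    gene's 3'-most genomic coordinate and RT extends leftwards past the TES.
    For eligible genes TSSr, GB and TESr tile [TSS, TES] in transcript
    orientation with no gap or overlap. Windows crossing a contig edge are
    clipped and flagged, never fatal.
    """
    L = model.length
    s, e = model.start, model.end
    if model.strand == "+":
        tssr = (s, s + params.tssr_len)
        tesr = (e - params.tesr_len, e)
        gb = (s + params.tssr_len, e - params.tesr_len)
        tss200 = (s, s + params.tss200_len)
        rt = (e, e + params.rt_len)
    else:
        tssr = (e - params.tssr_len, e)
        tesr = (s, s + params.tesr_len)
        gb = (s + params.tesr_len, e - params.tssr_len)
        tss200 = (e - params.tss200_len, e)
        rt = (s - params.rt_len, s)

    eligible = True
    reason = ""
    if L < params.min_gene_length:
        eligible = False
        reason = f"gene length {L} < min_gene_length {params.min_gene_length}"
    elif gb[1] - gb[0] < params.min_gb_length:
        eligible = False
        reason = (
            f"gene body length {gb[1] - gb[0]} < min_gb_length "
            f"{params.min_gb_length}"
        )

    clipped = False
    out: dict[str, Interval] = {}
    for name, iv in (("tssr", tssr), ("gb", gb), ("tesr", tesr), ("rt", rt), ("tss200", tss200)):
        civ, was_clipped = _clip(iv, contig_length)
        if was_clipped:
            clipped = True
        out[name] = civ
    if clipped:
        warnings.warn(
            f"gene {model.gene_id}: analysis windows clipped at contig bounds",
            stacklevel=2,
        )
    return RegionSet(
        gene_id=model.gene_id,
        chrom=model.chrom,
        strand=model.strand,
        tssr=out["tssr"],
        gb=out["gb"],
        tesr=out["tesr"],
        rt=out["rt"],
        tss200=out["tss200"],
        eligible=eligible,
        reason=reason,
        clipped=clipped,
    )


def define_regions_for(
    models: Iterable[GeneModel],
    params: WindowParams = WindowParams(),
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, RegionSet]:
    """Vector form of :func:`define_regions`, keyed by gene_id."""
    out = {}
    for m in models:
        clen = None if contig_lengths is None else contig_lengths.get(m.chrom)
        out[m.gene_id] = define_regions(m, params, contig_length=clen)
    return out


def regions_to_bed(
    regions: Iterable[RegionSet],
    path: str | Path,
    windows: Sequence[str] = ("tssr", "gb", "tesr", "rt", "tss200"),
) -> None:
    """Export windows as BED6, one record per window named ``gene:window``."""
    with open(path, "w") as fh:
        for rs in regions:
            for w in windows:
                lo, hi = rs.window(w)
                if hi <= lo:
                    continue
                fh.write(
                    f"{rs.chrom}\t{lo}\t{hi}\t{rs.gene_id}:{w}\t0\t{rs.strand}\n"
                )
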