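"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates, at desk scale, the data layout of a nascent-RNA
3'-end (PRO-seq-style) experiment in a human-like genome:

* a small genome with two host contigs each carrying a cluster of
  replication-dependent histone (RDH)-like genes plus dispersed snRNA,
  snoRNA and protein-coding genes, a Drosophila-like spike-in contig, and a
  Pol-I-like rRNA contig that ignores alpha-amanitin presets;
* per-gene 3'-end positions drawn from a four-component mixture — a
  promoter-proximal pause (uniform over the TSS-proximal window), a uniform
  gene-body component, a TES-proximal pause (discretized Gaussian centered a
  configurable offset upstream of the TES, inside the stem-loop-like
  window), and a geometric read-through tail past the TES;
* condition presets transforming the mixture the way the modeled
  perturbations do (NELF knockdown, EAF1 mutant, alpha-amanitin);
* IP/input per-gene count pairs with a controlled enrichment over the
  RDH-cluster genes;
* two-channel nuclear-body images with a controlled anchor-partner
  association fraction.

All randomness flows from one master seed through named substreams, so the
same seed and configuration always reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, WindowParams
from .signal import Alignment

__all__ = [
    "GenomeConfig",
    "Genome",
    "SimGeneParams",
    "ImageTruth",
    "SimTruth",
    "simulate_genome",
    "default_truth",
    "apply_condition",
    "params_for_tpp",
    "simulate_proseq",
    "simulate_enrichment_counts",
    "simulate_images",
    "write_fasta",
    "write_gene_bed",
    "write_frames_tiff",
    "CONDITIONS",
]

CONDITIONS = ("WT", "NELF_KD", "EAF1_mut", "alpha_amanitin")


def _rng(seed: int, *stream: str) -> np.random.Generator:
    """Named substream of the master seed (reproducibility contract)."""
    import zlib

    # crc32 gives a process-independent mapping of stream names to spawn keys
    return np.random.default_rng(
        np.random.SeedSequence(
            seed, spawn_key=tuple(zlib.crc32(s.encode()) for s in stream)
        )
    )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeConfig:
    """Layout of the synthetic genome.

    RDH-like genes are split between one cluster interval on each host
    contig, mirroring the two-cluster organization of the human RDH genes;
    other classes are dispersed outside the clusters. Length ranges keep
    every gene long enough for the default analysis windows (gene body of at
    least 50 nt after a 150 nt TSSr and 100 nt TESr).
    """

    n_rdh: int = 30
    n_snrna: int = 20
    n_snorna: int = 20
    n_coding: int = 30
    n_rrna: int = 1
    len_rdh: tuple[int, int] = (400, 800)
    len_snrna: tuple[int, int] = (300, 500)
    len_snorna: tuple[int, int] = (300, 500)
    len_coding: tuple[int, int] = (1000, 3000)
    host_length: int = 300_000
    cluster_interval: tuple[int, int] = (20_000, 100_000)
    spike_length: int = 50_000
    rrna_length: int = 20_000
    rrna_interval: tuple[int, int] = (2_000, 15_000)


@dataclass
class Genome:
    """Contigs, gene models and the designated feature intervals."""

    contig_lengths: dict[str, int]
    genes: list[GeneModel]
    cluster_intervals: dict[str, tuple[int, int]]  # contig -> (start, end)
    spike_contig: str = "spike_dm"
    rrna_contig: str = "chrRn"
    rrna_interval: tuple[str, int, int] = ("chrRn", 2_000, 15_000)

    def genes_of_class(self, gene_class: str) -> list[GeneModel]:
        return [g for g in self.genes if g.gene_class == gene_class]


def _place_genes(
    rng: np.random.Generator,
    region: tuple[int, int],
    lengths: Sequence[int],
) -> list[tuple[int, int]]:
    """Place non-overlapping genes with random gaps filling ``region``."""
    lo, hi = region
    total = int(sum(lengths))
    space = hi - lo - total
    if space < 0:
        raise ValueError("genes do not fit in the designated region")
    gaps = rng.random(len(lengths) + 1)
    gaps = np.floor(gaps / gaps.sum() * space).astype(int)
    spans = []
    cursor = lo
    for L, gap in zip(lengths, gaps):
        cursor += int(gap)
        spans.append((cursor, cursor + int(L)))
        cursor += int(L)
    return spans


def simulate_genome(
    config: GenomeConfig = GenomeConfig(), seed: int = 0
) -> Genome:
    """Build the synthetic genome layout deterministically from ``seed``."""
    rng = _rng(seed, "genome")
    contigs = {
        "chrA": config.host_length,
        "chrB": config.host_length,
        "spike_dm": config.spike_length,
        "chrRn": config.rrna_length,
    }
    genes: list[GeneModel] = []

    def lens(rangepair: tuple[int, int], n: int) -> np.ndarray:
        return rng.integers(rangepair[0], rangepair[1] + 1, size=n)

    # RDH genes split between the two host-contig clusters
    n_a = config.n_rdh // 2
    clusters = {"chrA": config.cluster_interval, "chrB": config.cluster_interval}
    for contig, n in (("chrA", n_a), ("chrB", config.n_rdh - n_a)):
        spans = _place_genes(rng, clusters[contig], lens(config.len_rdh, n))
        for start, end in spans:
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"rdh_{contig}_{start}", contig, start, end, strand, "RDH"
                )
            )

    # dispersed genes downstream of the cluster on each host contig
    dispersed = (
        [("snRNA", L) for L in lens(config.len_snrna, config.n_snrna)]
        + [("snoRNA", L) for L in lens(config.len_snorna, config.n_snorna)]
        + [("protein_coding", L) for L in lens(config.len_coding, config.n_coding)]
    )
    half = len(dispersed) // 2
    for contig, chunk in (("chrA", dispersed[:half]), ("chrB", dispersed[half:])):
        region = (config.cluster_interval[1] + 2_000, config.host_length - 2_000)
        spans = _place_genes(rng, region, [L for _, L in chunk])
        for (cls, _L), (start, end) in zip(chunk, spans):
            strand = "+" if rng.random() < 0.5 else "-"
            prefix = {"snRNA": "snrna", "snoRNA": "snorna", "protein_coding": "pc"}[cls]
            genes.append(
                GeneModel(f"{prefix}_{contig}_{start}", contig, start, end, strand, cls)
            )

    # one Pol-I-like rRNA unit spanning the designated interval
    r_lo, r_hi = config.rrna_interval
    if config.n_rrna:
        genes.append(GeneModel("rrna_unit", "chrRn", r_lo, r_hi, "+", "rRNA"))

    genes.sort(key=lambda g: (g.chrom, g.start))
    return Genome(
        contig_lengths=contigs,
        genes=genes,
        cluster_intervals=clusters,
        rrna_interval=("chrRn", r_lo, r_hi),
    )


def write_fasta(genome: Genome, path: str | Path, seed: int = 0) -> None:
    """Random repeat-free sequence for each contig (deterministic)."""
    rng = _rng(seed, "fasta")
    bases = np.array(list("ACGT"))
    with open(path, "w") as fh:
        for contig, length in genome.contig_lengths.items():
            fh.write(f">{contig}\n")
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            for i in range(0, length, 80):
                fh.write(seq[i : i + 80] + "\n")


def write_gene_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Annotation in the 7-column gene-bed dialect."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t{g.gene_class}\n"
            )


# ---------------------------------------------------------------------------
# PRO-seq read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGeneParams:
    """Mixture parameters governing one gene's 3'-end distribution.

    ``w5``: promoter-pause weight (uniform over the TSSr window);
    ``w3``: TES-pause weight (discretized Gaussian of standard deviation
    ``pause_width`` nt centered ``pause3_offset`` nt upstream of the TES,
    truncated to the transcript); ``rho``: read-through fraction (geometric
    tail past the TES with mean ``rt_decay`` nt); the gene-body weight is
    the remainder ``1 - w5 - w3 - rho`` (uniform over the gene body).
    """

    gene: GeneModel
    reads_expected: float
    w5: float
    w3: float
    rho: float
    pause3_offset: int = 35
    pause_width: float = 10.0
    rt_decay: float = 50.0

    @property
    def wgb(self) -> float:
        return 1.0 - self.w5 - self.w3 - self.rho

    def __post_init__(self) -> None:
        for name, w in (("w5", self.w5), ("w3", self.w3), ("rho", self.rho), ("wgb", self.wgb)):
            if w < -1e-9:
                raise ValueError(f"{self.gene.gene_id}: weight {name} negative ({w})")
        if abs(self.w5 + self.w3 + self.rho + self.wgb - 1.0) > 1e-9:
            raise ValueError(f"{self.gene.gene_id}: weights do not sum to 1")


@dataclass(frozen=True)
class ImageTruth:
    """Ground-truth parameters of the two-channel nuclear-body images."""

    association_fraction: float = 0.5
    n_anchors: int = 300
    n_free_partners: int = 50
    blob_sigma: float = 1.5
    amplitude: float = 1000.0
    background: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.association_fraction <= 1.0:
            raise ValueError("association_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Full ground truth of one simulated sample."""

    genes: dict[str, SimGeneParams]
    spike_reads_expected: float
    condition_name: str = "WT"
    seed: int = 0
    spike_fraction: float = 0.1
    image: ImageTruth = field(default_factory=ImageTruth)


#: Default WT mixture weights (w5, w3, rho) per gene class. RDH and snRNA
#: genes carry a strong TES-proximal pause; protein-coding genes are
#: dominated by promoter-proximal pausing with nearly no TES pause.
CLASS_WEIGHTS: Mapping[str, tuple[float, float, float]] = {
    "RDH": (0.25, 0.35, 0.05),
    "snRNA": (0.25, 0.30, 0.05),
    "snoRNA": (0.30, 0.20, 0.05),
    "protein_coding": (0.45, 0.03, 0.04),
    "rRNA": (0.05, 0.0, 0.0),
    "other_noncoding": (0.40, 0.05, 0.05),
}


def default_truth(
    genome: Genome,
    condition: str = "WT",
    reads_per_gene: float = 2000.0,
    spike_fraction: float = 0.1,
    seed: int = 0,
    image: ImageTruth | None = None,
) -> SimTruth:
    """Study-condition ground truth with per-class default pause weights.

    ``spike_fraction`` (default 0.1) sets the expected share of spike-contig
    reads at the WT genic depth — a fixed per-cell spike-in, so condition
    presets never rescale it.
    """
    params = {}
    for g in genome.genes:
        w5, w3, rho = CLASS_WEIGHTS[g.gene_class]
        params[g.gene_id] = SimGeneParams(
            gene=g, reads_expected=reads_per_gene, w5=w5, w3=w3, rho=rho
        )
    genic_total = reads_per_gene * len(genome.genes)
    truth = SimTruth(
        genes=params,
        spike_reads_expected=spike_fraction / (1.0 - spike_fraction) * genic_total,
        condition_name="WT",
        seed=seed,
        spike_fraction=spike_fraction,
        image=image or ImageTruth(),
    )
    return apply_condition(truth, condition)


def apply_condition(truth: SimTruth, condition: str) -> SimTruth:
    """Transform WT ground truth into one of the study-condition presets.

    ``NELF_KD`` halves the TES-pause weight of RDH genes and mildly reduces
    the snRNA TES pause; ``EAF1_mut`` collapses the RDH TES pause
    (``w3 -> 0.05 w3``) and doubles RDH read-through; ``alpha_amanitin``
    suppresses expected reads of every non-rRNA gene 10-fold and leaves the
    Pol-I rRNA unit and the spike-in untouched.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    genes: dict[str, SimGeneParams] = {}
    for gid, p in truth.genes.items():
        cls = p.gene.gene_class
        if condition == "NELF_KD":
            if cls == "RDH":
                p = replace(p, w3=0.5 * p.w3)
            elif cls == "snRNA":
                p = replace(p, w3=0.8 * p.w3)
        elif condition == "EAF1_mut":
            if cls == "RDH":
                p = replace(p, w3=0.05 * p.w3, rho=2.0 * p.rho)
        elif condition == "alpha_amanitin":
            if cls != "rRNA":
                p = replace(p, reads_expected=0.1 * p.reads_expected)
        genes[gid] = p
    return SimTruth(
        genes=genes,
        spike_reads_expected=truth.spike_reads_expected,
        condition_name=condition,
        seed=truth.seed,
        spike_fraction=truth.spike_fraction,
        image=truth.image,
    )


def params_for_tpp(
    gene: GeneModel,
    k: float,
    reads_expected: float,
    windows: WindowParams = WindowParams(),
) -> SimGeneParams:
    """Mixture weights making the TES-pause density exactly k-fold GB density.

    With no promoter pause and no read-through, the TESr window carries all
    the w3 mass at density ``w3 / tesr_len`` while the gene body carries
    ``wgb / gb_len``; solving the density ratio for k gives the weights used
    by index-recovery experiments.
    """
    gb_len = gene.length - windows.tssr_len - windows.tesr_len
    if gb_len <= 0:
        raise ValueError("gene too short for the requested windows")
    w3 = k * windows.tesr_len / (k * windows.tesr_len + gb_len)
    return SimGeneParams(
        gene=gene, reads_expected=reads_expected, w5=0.0, w3=w3, rho=0.0
    )


def _sample_gene_positions(
    rng: np.random.Generator,
    p: SimGeneParams,
    n: int,
    windows: WindowParams,
) -> np.ndarray:
    """Transcript-oriented 3'-end offsets t (t=0 at TSS, t=L-1 at TES)."""
    L = p.gene.length
    tssr_len = min(windows.tssr_len, L)
    gb_lo, gb_hi = windows.tssr_len, L - windows.tesr_len
    comp = rng.choice(4, size=n, p=[p.w5, p.wgb, p.w3, p.rho])
    t = np.empty(n, dtype=np.int64)
    m5 = comp == 0
    t[m5] = rng.integers(0, tssr_len, size=int(m5.sum()))
    mgb = comp == 1
    if gb_hi <= gb_lo:
        gb_lo, gb_hi = 0, L  # degenerate geometry: fall back to whole gene
    t[mgb] = rng.integers(gb_lo, gb_hi, size=int(mgb.sum()))
    m3 = comp == 2
    d = np.rint(
        rng.normal(p.pause3_offset, p.pause_width, size=int(m3.sum()))
    ).astype(np.int64)
    t[m3] = np.clip(L - 1 - d, 0, L - 1)  # truncate the pause to the transcript
    mrt = comp == 3
    t[mrt] = L - 1 + rng.geometric(1.0 / p.rt_decay, size=int(mrt.sum()))
    return t


def simulate_proseq(
    genome: Genome,
    truth: SimTruth,
    seed: int | None = None,
    n_reads: int | None = None,
    depth_factor: float = 1.0,
    windows: WindowParams = WindowParams(),
) -> list[Alignment]:
    """Draw coordinate-sorted PRO-seq-like alignments from the ground truth.

    Per-gene read counts are Poisson around ``reads_expected`` (rescaled so
    the genic total is ``n_reads`` when given); ``depth_factor`` scales
    everything including the spike-in, modelling sequencing depth. Each
    read's 3' end comes from the gene's mixture; the read length is uniform
    25-50 nt ending at the 3' end; spike reads land uniformly on the spike
    contig. Identical seed and truth give identical output.
    """
    if n_reads is not None and n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if seed is None:
        seed = truth.seed
    rng = _rng(seed, "reads", truth.condition_name)

    genic_total = sum(p.reads_expected for p in truth.genes.values())
    rescale = 1.0 if n_reads is None else n_reads / genic_total
    alignments: list[Alignment] = []
    read_lengths = lambda m: rng.integers(25, 51, size=m)

    for gid in sorted(truth.genes):
        p = truth.genes[gid]
        g = p.gene
        m = int(rng.poisson(p.reads_expected * rescale * depth_factor))
        if m == 0:
            continue
        t = _sample_gene_positions(rng, p, m, windows)
        clen = genome.contig_lengths[g.chrom]
        if g.strand == "+":
            pos = g.start + t
        else:
            pos = g.end - 1 - t
        pos = np.clip(pos, 0, clen - 1)
        lens = read_lengths(m)
        if g.strand == "+":
            starts = np.maximum(pos - lens + 1, 0)
            ends = pos + 1
        else:
            starts = pos
            ends = np.minimum(pos + lens, clen)
        for s, e in zip(starts, ends):
            alignments.append(Alignment(g.chrom, int(s), int(e), g.strand, 60))

    # fixed-per-cell spike-in: scales with depth only
    m_spike = int(rng.poisson(truth.spike_reads_expected * depth_factor))
    clen = genome.contig_lengths[genome.spike_contig]
    pos = rng.integers(0, clen, size=m_spike)
    strands = rng.random(m_spike) < 0.5
    lens = read_lengths(m_spike)
    for i in range(m_spike):
        if strands[i]:
            s = max(int(pos[i]) - int(lens[i]) + 1, 0)
            alignments.append(
                Alignment(genome.spike_contig, s, int(pos[i]) + 1, "+", 60)
            )
        else:
            e = min(int(pos[i]) + int(lens[i]), clen)
            alignments.append(
                Alignment(genome.spike_contig, int(pos[i]), e, "-", 60)
            )

    alignments.sort(key=lambda a: (a.contig, a.start, a.end, a.strand))
    return alignments


# ---------------------------------------------------------------------------
# IP/input enrichment simulation
# ---------------------------------------------------------------------------

def simulate_enrichment_counts(
    genome: Genome,
    seed: int = 0,
    baseline: float = 200.0,
    effect: float = 5.0,
    enriched_class: str = "RDH",
) -> tuple[pd.Series, pd.Series]:
    """Per-gene (ip, input) raw count pairs with a controlled enrichment.

    Input counts are Poisson around ``baseline`` for every gene; IP counts
    are Poisson around ``baseline * effect`` for genes of ``enriched_class``
    (the nuclear-body-associated cluster genes) and ``baseline`` otherwise.
    """
    rng = _rng(seed, "enrichment")
    gids = [g.gene_id for g in genome.genes]
    input_counts = pd.Series(
        rng.poisson(baseline, size=len(gids)).astype(float), index=gids
    )
    ip_mu = np.array(
        [
            baseline * effect if g.gene_class == enriched_class else baseline
            for g in genome.genes
        ]
    )
    ip_counts = pd.Series(rng.poisson(ip_mu).astype(float), index=gids)
    return ip_counts, input_counts


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

def _pack_points(
    rng: np.random.Generator,
    n: int,
    frame: int,
    margin: float,
    min_sep: float,
    avoid: np.ndarray | None = None,
    avoid_dist: float = 0.0,
    max_tries: int = 200_000,
) -> np.ndarray:
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"infeasible packing: placed {len(pts)} of {n} blobs "
                f"in a {frame}x{frame} frame"
            )
        cand = margin + rng.random(2) * (frame - 2 * margin)
        if pts:
            arr = np.array(pts)
            if np.min(np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1])) < min_sep:
                continue
        if avoid is not None and len(avoid):
            if np.min(np.hypot(avoid[:, 0] - cand[0], avoid[:, 1] - cand[1])) < avoid_dist:
                continue
        pts.append((float(cand[0]), float(cand[1])))
    return np.array(pts).reshape(n, 2)


def _render(
    frame: int, centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    img = np.zeros((frame, frame))
    r = max(int(np.ceil(5 * sigma)), 2)
    for cy, cx in centers:
        y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, frame)
        x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, frame)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)
        )
    return img


def simulate_images(
    truth: ImageTruth,
    n_frames: int = 1,
    frame_size: int = 1024,
    seed: int = 0,
    noise: bool = True,
) -> tuple[list[dict[str, np.ndarray]], pd.DataFrame]:
    """Two-channel frames with a controlled anchor-partner association.

    Each frame carries ``n_anchors`` anchor blobs (non-overlapping, with
    margin); exactly ``round(f * n_anchors)`` of them (a random subset)
    receive a partner blob displaced by a vector of length uniform in
    ``[0, 2*sigma]`` so the two masks overlap; ``n_free_partners`` more
    partner blobs land at least ``10*sigma`` from every anchor. Pixel values
    are Poisson draws around background plus blob signal (``noise=False``
    skips the Poisson step for noise-free oracle frames). Returns the frames
    (dicts with ``"anchor"``/``"partner"`` arrays) and the ground-truth blob
    table.
    """
    rng = _rng(seed, "images")
    sigma = truth.blob_sigma
    frames: list[dict[str, np.ndarray]] = []
    rows: list[dict] = []
    n_assoc = int(round(truth.association_fraction * truth.n_anchors))
    for fi in range(n_frames):
        anchors = _pack_points(
            rng,
            truth.n_anchors,
            frame_size,
            margin=12 * sigma,
            min_sep=12 * sigma,
        )
        assoc_idx = rng.choice(truth.n_anchors, size=n_assoc, replace=False)
        assoc_mask = np.zeros(truth.n_anchors, dtype=bool)
        assoc_mask[assoc_idx] = True

        partner_centers = []
        for i in np.flatnonzero(assoc_mask):
            angle = rng.random() * 2 * np.pi
            dist = rng.random() * 2 * sigma
            partner_centers.append(anchors[i] + dist * np.array([np.sin(angle), np.cos(angle)]))
        partner_centers = (
            np.array(partner_centers).reshape(-1, 2)
        )
        free = _pack_points(
            rng,
            truth.n_free_partners,
            frame_size,
            margin=12 * sigma,
            min_sep=6 * sigma,
            avoid=anchors,
            avoid_dist=10 * sigma,
        )
        all_partners = np.vstack([partner_centers, free])

        anchor_img = _render(frame_size, anchors, sigma, truth.amplitude)
        partner_img = _render(frame_size, all_partners, sigma, truth.amplitude)
        if noise:
            frames.append(
                {
                    "anchor": rng.poisson(truth.background + anchor_img).astype(float),
                    "partner": rng.poisson(truth.background + partner_img).astype(float),
                }
            )
        else:
            frames.append(
                {
                    "anchor": truth.background + anchor_img,
                    "partner": truth.background + partner_img,
                }
            )
        for i, (cy, cx) in enumerate(anchors):
            rows.append(
                {
                    "frame": fi,
                    "role": "anchor",
                    "blob_id": i,
                    "row": cy,
                    "col": cx,
                    "associated": bool(assoc_mask[i]),
                }
            )
        for i, (cy, cx) in enumerate(all_partners):
            rows.append(
                {
                    "frame": fi,
                    "role": "partner",
                    "blob_id": i,
                    "row": cy,
                    "col": cx,
                    "associated": i < len(partner_centers),
                }
            )
    return frames, pd.DataFrame(rows)


def write_frames_tiff(
    frames: Sequence[Mapping[str, np.ndarray]], directory: str | Path
) -> list[Path]:
    """One multi-page TIFF per frame (page order: anchor, partner)."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        path = directory / f"frame_{i:03d}.tiff"
        tifffile.imwrite(
            path, np.stack([frame["anchor"], frame["partner"]]).astype(np.float32)
        )
        paths.append(path)
    return paths
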