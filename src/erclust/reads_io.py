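"""Read loading, strand-aware shifting, bin construction and the short-bin statistic.

The atomic unit downstream of this module is the *bin*: the gap between two
neighboring shifted 5' read positions on a chromosome.  Coordinates are
0-based, half-open (BED dialect) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeModel",
    "ReadSet",
    "BinSequence",
    "ShiftEstimate",
    "load_chrom_sizes",
    "load_reads",
    "shift_reads",
    "build_bins",
    "short_bin_fraction",
    "estimate_shift",
    "snr_estimate",
]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus the mappability-corrected mean read density.

    ``d_genome`` is derived lazily from a case library size via
    :meth:`density`: total reads / (genome length x mappability factor).
    """

    chrom_sizes: dict[str, int]
    mcf: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.mcf <= 1.0:
            raise ValueError(f"MCF must be in (0, 1], got {self.mcf}")
        if not self.chrom_sizes:
            raise ValueError("empty chromosome table")

    @property
    def l_genome(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def density(self, total_reads: int) -> float:
        """Mean read density d = R / (l_genome x MCF), in reads/bp."""
        d = total_reads / (self.l_genome * self.mcf)
        if d <= 0:
            raise ValueError("non-positive genome read density")
        return d


@dataclass
class ReadSet:
    """Per-chromosome sorted 5' read positions (or fragment midpoints).

    ``strands`` holds +1 / -1 / 0 (0 = strandless, e.g. paired-end
    midpoints).  Positions and strands are kept index-aligned; both are
    re-sorted together whenever positions change.
    """

    sample_label: str
    positions: dict[str, np.ndarray]
    strands: dict[str, np.ndarray]
    layout: str = "single"  # single | paired
    fragment_hint: int = 200

    def __post_init__(self) -> None:
        if self.layout not in ("single", "paired"):
            raise ValueError(f"bad layout {self.layout!r}")
        for chrom in self.positions:
            self.positions[chrom] = np.asarray(self.positions[chrom], dtype=np.int64)
            self.strands[chrom] = np.asarray(self.strands[chrom], dtype=np.int8)
            if self.positions[chrom].shape != self.strands[chrom].shape:
                raise ValueError(f"positions/strands mismatch on {chrom}")

    @property
    def total_reads(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    def sort(self) -> None:
        for chrom, pos in self.positions.items():
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = pos[order]
            self.strands[chrom] = self.strands[chrom][order]

    def is_sorted(self) -> bool:
        return all(np.all(np.diff(p) >= 0) for p in self.positions.values())


@dataclass
class BinSequence:
    """Ordered inter-read gaps per chromosome.

    ``starts[c][i]`` / ``lengths[c][i]`` describe the i-th bin on
    chromosome ``c``; a chromosome with n reads yields n-1 bins.
    """

    starts: dict[str, np.ndarray]
    lengths: dict[str, np.ndarray]

    @property
    def total_bins(self) -> int:
        return int(sum(len(v) for v in self.lengths.values()))

    def all_lengths(self) -> np.ndarray:
        vals = [v for v in self.lengths.values() if len(v)]
        if not vals:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(vals)


@dataclass(frozen=True)
class ShiftEstimate:
    optimized_shift: int
    candidate_shifts: tuple[int, ...] = ()
    short_bin_fraction_by_candidate: tuple[float, ...] = ()
    short_bin_cutoff: int = 0


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, size = line.split()[:2]
            sizes[name] = int(size)
    if not sizes:
        raise ValueError(f"no chromosomes in {path}")
    return sizes


def _reads_from_bed(path: str | Path, known: set[str]):
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "+"
            if chrom not in known:
                dropped += 1
                continue
            # 5' end: interval start for +, last base for -
            if strand == "-":
                per_chrom.setdefault(chrom, []).append((end - 1, -1))
            else:
                per_chrom.setdefault(chrom, []).append((start, +1))
    return per_chrom, dropped


def _reads_from_bam(path: str | Path, known: set[str], layout: str):
    import pysam

    per_chrom: dict[str, list[tuple[int, int]]] = {}
    dropped = 0
    tlens: list[int] = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            if chrom not in known:
                dropped += 1
                continue
            if layout == "paired":
                if not aln.is_proper_pair or aln.is_read2:
                    continue
                mid = aln.reference_start + abs(aln.template_length) // 2
                per_chrom.setdefault(chrom, []).append((mid, 0))
                tlens.append(abs(aln.template_length))
            else:
                if aln.is_reverse:
                    per_chrom.setdefault(chrom, []).append((aln.reference_end - 1, -1))
                else:
                    per_chrom.setdefault(chrom, []).append((aln.reference_start, +1))
    median_insert = int(np.median(tlens)) if tlens else None
    return per_chrom, dropped, median_insert


def load_reads(
    path: str | Path,
    genome: GenomeModel,
    fmt: str = "bed",
    layout: str = "single",
    sample_label: str | None = None,
    fragment_hint: int = 200,
) -> ReadSet:
    """Load mapped reads from BED6 or BAM into a sorted :class:`ReadSet`.

    Single-end reads contribute their 5' position; paired-end BAM reads
    contribute the fragment midpoint (strandless).  Reads on chromosomes
    absent from ``genome`` are dropped with a logged count.
    """
    known = set(genome.chrom_sizes)
    if fmt == "bed":
        per_chrom, dropped = _reads_from_bed(path, known)
    elif fmt == "bam":
        per_chrom, dropped, median_insert = _reads_from_bam(path, known, layout)
        if layout == "paired" and median_insert:
            fragment_hint = median_insert
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if dropped:
        logger.warning("%s: dropped %d reads on unknown chromosomes", path, dropped)

    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, rows in per_chrom.items():
        arr = np.array(rows, dtype=np.int64)
        size = genome.chrom_sizes[chrom]
        pos = np.clip(arr[:, 0], 0, size - 1)
        positions[chrom] = pos
        strands[chrom] = arr[:, 1].astype(np.int8)
    rs = ReadSet(
        sample_label=sample_label or Path(path).stem,
        positions=positions,
        strands=strands,
        layout=layout,
        fragment_hint=fragment_hint,
    )
    if rs.total_reads == 0:
        raise ValueError(f"no usable reads in {path}")
    rs.sort()
    return rs


def shift_reads(reads: ReadSet, shift: int, genome: GenomeModel | None = None) -> ReadSet:
    """Move + reads right and - reads left by ``shift`` bp; re-sort.

    Strandless reads stay in place.  Positions are clipped to chromosome
    bounds when a genome model is supplied.
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    for chrom, pos in reads.positions.items():
        strand = reads.strands[chrom]
        new = pos + shift * strand.astype(np.int64)
        if genome is not None:
            new = np.clip(new, 0, genome.chrom_sizes[chrom] - 1)
        else:
            new = np.maximum(new, 0)
        positions[chrom] = new
        strands[chrom] = strand.copy()
    out = ReadSet(
        sample_label=reads.sample_label,
        positions=positions,
        strands=strands,
        layout=reads.layout,
        fragment_hint=reads.fragment_hint,
    )
    out.sort()
    return out


def build_bins(reads: ReadSet) -> BinSequence:
    """One bin per adjacent read pair per chromosome; length may be 0."""
    if not reads.is_sorted():
        raise ValueError("reads must be sorted before binning")
    starts: dict[str, np.ndarray] = {}
    lengths: dict[str, np.ndarray] = {}
    for chrom, pos in reads.positions.items():
        if len(pos) < 2:
            starts[chrom] = np.empty(0, dtype=np.int64)
            lengths[chrom] = np.empty(0, dtype=np.int64)
            continue
        starts[chrom] = pos[:-1].copy()
        lengths[chrom] = np.diff(pos)
    return BinSequence(starts=starts, lengths=lengths)


def _smooth(counts: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(counts.astype(float), kernel, mode="same")


def short_bin_fraction(bins: BinSequence) -> tuple[float, int]:
    """Fraction of bins at or below the first mode of the bin-length histogram.

    The histogram is taken at 1-bp resolution and smoothed with a centered
    moving average of width 5; the cutoff is the raw-count argmax inside the
    first non-increasing plateau of the smoothed curve.  A monotone histogram
    (no interior peak) falls back to the smallest occupied length.
    Returns ``(fraction, cutoff)``.
    """
    lengths = bins.all_lengths()
    n = len(lengths)
    if n == 0:
        raise ValueError("no bins")
    if n < 1000:
        logger.warning("only %d bins; short-bin fraction may be unstable", n)
    maxlen = int(lengths.max())
    counts = np.bincount(lengths, minlength=maxlen + 1)

    occupied = np.nonzero(counts)[0]
    cutoff = None
    diffs = np.diff(counts[occupied[0] : occupied[-1] + 1])
    if len(occupied) == 1 or np.all(diffs <= 0) or np.all(diffs >= 0):
        cutoff = int(occupied[0])
        logger.warning("monotone bin-length histogram; cutoff=%d", cutoff)
    else:
        h = _smooth(counts)
        descent = np.nonzero(h[:-1] > h[1:])[0]
        if len(descent) == 0:
            cutoff = int(occupied[0])
            logger.warning("no histogram descent; cutoff=%d", cutoff)
        else:
            i = int(descent[0])
            j = i
            while j > 0 and h[j - 1] == h[i]:
                j -= 1
            cutoff = j + int(np.argmax(counts[j : i + 1]))
    frac = float(np.count_nonzero(lengths <= cutoff)) / n
    return frac, int(cutoff)


def estimate_shift(
    reads: ReadSet,
    max_shift: int | None = None,
    step: int = 5,
    genome: GenomeModel | None = None,
) -> ShiftEstimate:
    """Pick the read shift maximizing the short-bin fraction.

    Candidates run from 0 to ``max_shift`` (default: the fragment-size hint)
    in strides of ``step``.  Paired-end data is not scanned: the shift is
    half the median fragment size (the stored hint).
    """
    if reads.layout == "paired":
        return ShiftEstimate(optimized_shift=reads.fragment_hint // 2)
    if max_shift is None:
        max_shift = reads.fragment_hint
    if max_shift <= 0:
        raise ValueError("max_shift must be > 0")
    candidates = list(range(0, max_shift + 1, step))
    if candidates[-1] != max_shift:
        candidates.append(max_shift)

    fracs: list[float] = []
    cutoffs: list[int] = []
    for cand in candidates:
        shifted = shift_reads(reads, cand, genome)
        bins = build_bins(shifted)
        if bins.total_bins == 0:
            fallback = reads.fragment_hint // 2
            logger.warning("no bins at shift %d; falling back to %d", cand, fallback)
            return ShiftEstimate(optimized_shift=fallback)
        frac, cut = short_bin_fraction(bins)
        fracs.append(frac)
        cutoffs.append(cut)

    if len(set(fracs)) == 1 and len(fracs) > 1:
        fallback = reads.fragment_hint // 2
        logger.warning("flat short-bin profile; falling back to shift %d", fallback)
        return ShiftEstimate(
            optimized_shift=fallback,
            candidate_shifts=tuple(candidates),
            short_bin_fraction_by_candidate=tuple(fracs),
            short_bin_cutoff=cutoffs[0],
        )
    best = int(np.argmax(fracs))
    return ShiftEstimate(
        optimized_shift=candidates[best],
        candidate_shifts=tuple(candidates),
        short_bin_fraction_by_candidate=tuple(fracs),
        short_bin_cutoff=cutoffs[best],
    )


def subsample(reads: ReadSet, sample_size: int, seed: int) -> ReadSet:
    """Seeded subsample without replacement across the whole library."""
    total = reads.total_reads
    if sample_size >= total:
        if sample_size > total:
            logger.warning("sample_size %d > total %d; using all reads", sample_size, total)
        return reads
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(total, size=sample_size, replace=False))
    positions: dict[str, np.ndarray] = {}
    strands: dict[str, np.ndarray] = {}
    offset = 0
    for chrom, pos in reads.positions.items():
        n = len(pos)
        lo = np.searchsorted(keep, offset, side="left")
        hi = np.searchsorted(keep, offset + n, side="left")
        idx = keep[lo:hi] - offset
        positions[chrom] = pos[idx]
        strands[chrom] = reads.strands[chrom][idx]
        offset += n
    out = ReadSet(
        sample_label=reads.sample_label,
        positions=positions,
        strands=strands,
        layout=reads.layout,
        fragment_hint=reads.fragment_hint,
    )
    out.sort()
    return out


def snr_estimate(
    reads: ReadSet,
    sample_size: int,
    seed: int,
    shift: int | None = None,
    genome: GenomeModel | None = None,
) -> float:
    """Short-bin fraction of a fixed-size seeded subsample (signal-to-noise proxy)."""
    sub = subsample(reads, sample_size, seed)
    if shift is None:
        shift = estimate_shift(sub, genome=genome).optimized_shift
    shifted = shift_reads(sub, shift, genome)
    frac, _ = short_bin_fraction(build_bins(shifted))
    return frac
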