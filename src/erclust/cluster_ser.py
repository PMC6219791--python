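"""Clustering enriched regions into short-ER clusters (SERs).

Fragmentation is diagnosed with FR-D, the fraction of neighboring ER pairs
whose gap is small relative to the ER lengths.  Candidate connecting lengths
come from percentiles of neighbor distances of coordinate-shuffled ERs
(PDNP); each candidate drives a re-run of the bin-window caller whose merged
significant windows are trimmed to the shortest regions covering the ERs
they contain.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .reads_io import GenomeModel, ReadSet
from .window_engine import (
    CallerParams,
    by_qvalues,
    merged_significant_windows,
    report_region,
    training_chromosomes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterRegion",
    "PdnpGrid",
    "fr_d",
    "shuffle_regions",
    "pdnp_candidates",
    "ser_window_bins",
    "call_sers",
]

SER_PERCENTILES = tuple(range(1, 11))
SER_CAP = 10_000


@dataclass
class ClusterRegion:
    """An SER or LER: the shortest region covering its member units."""

    kind: str  # "SER" | "LER"
    chrom: str
    start: int
    end: int
    members: list[int]  # indices into the input unit list
    r_case: int = 0
    p: float = float("nan")
    q: float = float("nan")
    fc: float = float("nan")
    stat: float = float("nan")  # FR-D / FR-RE of the reported set
    name: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PdnpGrid:
    """Connecting-length candidates from shuffled neighbor-gap percentiles."""

    levels: tuple[int, ...]
    values: tuple[int, ...]
    cap: int
    seed: int = 0

    def __len__(self) -> int:
        return len(self.values)


def _as_intervals(units) -> list[tuple[str, int, int]]:
    out = []
    for u in units:
        if isinstance(u, tuple):
            out.append(u)
        else:
            out.append((u.chrom, u.start, u.end))
    return out


def _by_chrom(intervals: list[tuple[str, int, int]]) -> dict[str, list[tuple[int, int]]]:
    grouped: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        grouped.setdefault(chrom, []).append((start, end))
    for chrom in grouped:
        grouped[chrom].sort()
    return grouped


def fr_d(units, rule: str = "or") -> float:
    """Fraction of neighboring same-chromosome pairs that look fragmented.

    With gap d and lengths l1, l2, the "or" rule (default) flags
    d < l1/2 or d < l2/2; the "and" rule requires both.
    """
    grouped = _by_chrom(_as_intervals(units))
    pairs = fragged = 0
    for regions in grouped.values():
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            d = s2 - e1
            l1, l2 = e1 - s1, e2 - s2
            pairs += 1
            if rule == "or":
                hit = 2 * d < max(l1, l2)
            elif rule == "and":
                hit = 2 * d < min(l1, l2)
            else:
                raise ValueError(f"unknown FR-D rule {rule!r}")
            fragged += bool(hit)
    if pairs == 0:
        return 0.0
    return fragged / pairs


def shuffle_regions(units, genome: GenomeModel, seed: int) -> list[tuple[str, int, int]]:
    """Place each region uniformly at random on its own chromosome, no overlap.

    Lengths are preserved; placement is rejection-sampled (1000 attempts per
    region before giving up).
    """
    rng = np.random.default_rng(seed)
    grouped = _by_chrom(_as_intervals(units))
    out: list[tuple[str, int, int]] = []
    for chrom, regions in grouped.items():
        size = genome.chrom_sizes[chrom]
        placed_starts: list[int] = []
        placed_ends: list[int] = []
        for s, e in regions:
            length = e - s
            if length > size:
                raise RuntimeError(f"region longer than chromosome {chrom}")
            for _ in range(1000):
                cand = int(rng.integers(0, size - length + 1))
                i = bisect_left(placed_starts, cand)
                if i > 0 and placed_ends[i - 1] > cand:
                    continue
                if i < len(placed_starts) and placed_starts[i] < cand + length:
                    continue
                placed_starts.insert(i, cand)
                placed_ends.insert(i, cand + length)
                out.append((chrom, cand, cand + length))
                break
            else:
                raise RuntimeError(f"could not place region of {length} bp on {chrom}")
    out.sort()
    return out


def neighbor_gaps(intervals: list[tuple[str, int, int]]) -> np.ndarray:
    grouped = _by_chrom(intervals)
    gaps: list[int] = []
    for regions in grouped.values():
        for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
            gaps.append(max(0, s2 - e1))
    return np.asarray(sorted(gaps), dtype=np.int64)


def pdnp_candidates(
    shuffled: list[tuple[str, int, int]],
    levels: tuple[int, ...] = SER_PERCENTILES,
    cap: int = SER_CAP,
    seed: int = 0,
) -> PdnpGrid:
    """Nearest-rank percentiles of shuffled neighbor gaps, below the cap."""
    gaps = neighbor_gaps(shuffled)
    n = len(gaps)
    if n < 100:
        logger.warning("only %d neighbor gaps for PDNP estimation", n)
    if n == 0:
        return PdnpGrid(levels=(), values=(), cap=cap, seed=seed)
    keep_levels: list[int] = []
    keep_values: list[int] = []
    for level in levels:
        idx = max(0, int(np.ceil(level / 100.0 * n)) - 1)
        val = int(gaps[idx])
        if val >= cap:
            continue
        keep_levels.append(level)
        keep_values.append(max(1, val))
    if not keep_values:
        logger.warning("all PDNP candidates at or above the %d bp cap", cap)
    return PdnpGrid(levels=tuple(keep_levels), values=tuple(keep_values), cap=cap, seed=seed)


def ser_window_bins(l_pdnp: int, d_genome: float) -> int:
    """Bins per clustering initial window: min(max(floor(l*d*5), 20), 500)."""
    if l_pdnp <= 0 or d_genome <= 0:
        raise ValueError("l_pdnp and d_genome must be positive")
    return int(min(max(np.floor(l_pdnp * d_genome * 5), 20), 500))


def trim_windows_to_units(
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    units,
) -> list[tuple[str, int, int, list[int]]]:
    """Shrink merged windows to the shortest regions covering their member units.

    Windows covering no unit are discarded.  Trimmed regions that come to
    overlap (a unit straddling two windows) are merged, unioning members.
    Returns ``(chrom, start, end, member_indices)`` sorted by coordinate.
    """
    intervals = _as_intervals(units)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, (chrom, s, e) in enumerate(intervals):
        by_chrom.setdefault(chrom, []).append((s, e, i))
    out: list[tuple[str, int, int, list[int]]] = []
    for chrom, (w_starts, w_ends) in merged.items():
        if chrom not in by_chrom:
            continue
        regs = sorted(by_chrom[chrom])
        u_starts = np.array([r[0] for r in regs], dtype=np.int64)
        u_ends = np.array([r[1] for r in regs], dtype=np.int64)
        trimmed: list[tuple[int, int, list[int]]] = []
        for ws, we in zip(w_starts, w_ends):
            i0 = int(np.searchsorted(u_ends, ws, side="right"))
            i1 = int(np.searchsorted(u_starts, we, side="left"))
            if i1 <= i0:
                continue
            members = [regs[i][2] for i in range(i0, i1)]
            trimmed.append((int(u_starts[i0]), int(u_ends[i1 - 1]), members))
        trimmed.sort()
        cur = None
        for s, e, members in trimmed:
            if cur is not None and s < cur[1]:
                cur = (cur[0], max(cur[1], e), sorted(set(cur[2]) | set(members)))
            else:
                if cur is not None:
                    out.append((chrom, *cur))
                cur = (s, e, members)
        if cur is not None:
            out.append((chrom, *cur))
    out.sort()
    return out


def _cluster_candidate(
    units,
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    l_pdnp: int,
    params: CallerParams,
    chroms: list[str] | None,
) -> list[tuple[str, int, int, list[int]]]:
    """One clustering pass at a fixed connecting length."""
    d_genome = genome.density(case.total_reads)
    n_bins = ser_window_bins(l_pdnp, d_genome)
    scan = merged_significant_windows(
        case,
        control,
        genome,
        n_bins,
        l_pdnp,
        params.merge_p_threshold,
        chroms=chroms,
    )
    return trim_windows_to_units(scan.merged, units)


def finalize_clusters(
    kind: str,
    trimmed: list[tuple[str, int, int, list[int]]],
    stat: float,
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    shift: int,
) -> list[ClusterRegion]:
    """Attach read counts, p/q/FC and names to trimmed cluster regions."""
    clusters = []
    for chrom, start, end, members in trimmed:
        rep = report_region(
            chrom, start, end, case, control, genome, shift, with_summit=False
        )
        clusters.append(
            ClusterRegion(
                kind=kind,
                chrom=chrom,
                start=start,
                end=end,
                members=members,
                r_case=rep.r_case,
                p=rep.p,
                fc=rep.fc,
                stat=stat,
            )
        )
    if clusters:
        q = by_qvalues([max(c.p, np.nextafter(0, 1)) for c in clusters])
        for c, qv in zip(clusters, q):
            c.q = float(qv)
    for i, c in enumerate(clusters, start=1):
        c.name = f"{kind}_{i}"
    return clusters


def call_sers(
    ers,
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    shift: int,
    grid: PdnpGrid | None = None,
    frd_threshold: float = 0.01,
    frd_rule: str = "or",
    params: CallerParams | None = None,
    seed: int = 0,
) -> list[ClusterRegion]:
    """Cluster ERs into SERs.

    Skips entirely when the genome-wide FR-D is already at or below the
    threshold.  Otherwise candidate connecting lengths are swept on the
    training chromosomes; the largest candidate whose clustered output has
    FR-D below the threshold wins (else the FR-D-minimizing candidate), and
    is applied genome-wide.
    """
    params = params or CallerParams()
    if len(ers) < 2:
        return []
    frd_all = fr_d(ers, rule=frd_rule)
    if frd_all <= frd_threshold:
        logger.info("FR-D %.4f <= %.4f; no SER calling needed", frd_all, frd_threshold)
        return []
    if grid is None:
        shuffled = shuffle_regions(ers, genome, seed)
        grid = pdnp_candidates(shuffled, SER_PERCENTILES, SER_CAP, seed)
    if len(grid) == 0:
        logger.warning("empty PDNP grid; SER calling skipped")
        return []

    # ascending sweep stops at the first candidate reaching the FR-D target;
    # if none does, the FR-D-minimizing candidate is used
    chroms = training_chromosomes(genome, case.chroms)
    sweep: list[tuple[int, float]] = []
    chosen = None
    for l_pdnp in grid.values:
        trimmed = _cluster_candidate(ers, case, control, genome, l_pdnp, params, chroms)
        frd = fr_d([(c, s, e) for c, s, e, _ in trimmed], rule=frd_rule)
        logger.debug("SER candidate l=%d: FR-D %.4f (%d regions)", l_pdnp, frd, len(trimmed))
        sweep.append((l_pdnp, frd))
        if frd < frd_threshold:
            chosen, stat = l_pdnp, frd
            break
    if chosen is None:
        chosen, stat = min(sweep, key=lambda t: t[1])
        logger.warning(
            "no connecting length reached FR-D < %.3f; using minimum (l=%d, FR-D %.4f)",
            frd_threshold, chosen, stat,
        )
    trimmed = _cluster_candidate(ers, case, control, genome, chosen, params, None)
    return finalize_clusters("SER", trimmed, stat, case, control, genome, shift)
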