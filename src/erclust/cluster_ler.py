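"""Clustering enriched regions (or SERs) into long-ER clusters (LERs).

Fragmentation of broad domains is diagnosed with FR-RE: the fraction of
covering regions of neighboring units whose case/control reads enrichment
(RE) exceeds a threshold.  Candidate connecting lengths come from shuffled
neighbor-gap percentiles (5th..50th, capped at 100 kb); the winning
candidate is the largest one that keeps FR-RE of the member gaps inside the
clustered output at or above the stop level.
"""

from __future__ import annotations

import logging

import numpy as np

from .cluster_ser import (
    ClusterRegion,
    PdnpGrid,
    _as_intervals,
    _by_chrom,
    _cluster_candidate,
    finalize_clusters,
    pdnp_candidates,
    shuffle_regions,
)
from .reads_io import GenomeModel, ReadSet
from .window_engine import CallerParams, training_chromosomes

logger = logging.getLogger(__name__)

__all__ = [
    "scale_factor",
    "region_re",
    "fr_re",
    "call_lers",
    "length_dissimilarity",
    "call_matched_lers",
    "LER_PERCENTILES",
    "LER_CAP",
]

LER_PERCENTILES = tuple(range(5, 51, 5))
LER_CAP = 100_000


def scale_factor(case_total: int, control_total: int) -> float:
    """Library-size ratio case/control."""
    if control_total <= 0:
        raise ValueError("LER calling requires a control sample with reads")
    return case_total / control_total


def region_re(
    r_case: int,
    r_control: int,
    sf: float,
    d_genome: float,
    l_region: int,
    floor: bool = True,
) -> float:
    """Reads enrichment of a region: case over scaled control.

    With ``floor`` (default) the denominator is floored by the genome-density
    expectation, mirroring the window background; without it the raw scaled
    control is used (infinite when the control is empty).
    """
    if l_region <= 0:
        raise ValueError("l_region must be > 0")
    if r_case <= 0:
        return 0.0
    denom = r_control * sf
    if floor:
        denom = max(denom, d_genome * l_region)
    if denom <= 0:
        return float("inf")
    return r_case / denom


def _count(pos: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


def _pair_re(
    chrom: str,
    left: tuple[int, int],
    right: tuple[int, int],
    case: ReadSet,
    control: ReadSet,
    sf: float,
    d_genome: float,
    floor: bool,
) -> float:
    start, end = left[0], right[1]
    case_pos = case.positions.get(chrom, np.empty(0, dtype=np.int64))
    ctrl_pos = control.positions.get(chrom, np.empty(0, dtype=np.int64))
    return region_re(
        _count(case_pos, start, end),
        _count(ctrl_pos, start, end),
        sf,
        d_genome,
        end - start,
        floor=floor,
    )


def fr_re(
    units,
    case: ReadSet,
    control: ReadSet,
    genome: GenomeModel,
    re_threshold: float = 1.5,
    floor: bool = True,
) -> float:
    """Fraction of neighboring-unit covering regions with RE above threshold."""
    sf = scale_factor(case.total_reads, control.total_reads)
    d_genome = genome.density(case.total_reads)
    grouped = _by_chrom(_as_intervals(units))
    pairs = hits = 0
    for chrom, regions in grouped.items():
        for left, right in zip(regions, regions[1:]):
            pairs += 1
            re = _pair_re(chrom, left, right, case, control, sf, d_genome, floor)
            hits += re > re_threshold
    if pairs == 0:
        return 0.0
    return hits / pairs


def _member_gap_frre(
    trimmed: list[tuple[str, int, int, list[int]]],
    unit_intervals: list[tuple[str, int, int]],
    case: ReadSet,
    control: ReadSet,
    sf: float,
    d_genome: float,
    re_threshold: float,
    floor: bool,
) -> float:
    """FR-RE over consecutive member units inside each cluster (1.0 if no pairs)."""
    pairs = hits = 0
    for chrom, _, _, members in trimmed:
        regs = sorted((unit_intervals[i][1], unit_intervals[i][2]) for i in members)
        for left, right in zip(regs, regs[1:]):
            pairs += 1
            re = _pair_re(chrom, left, right, case, control, sf, d_genome, floor)
            hits += re > re_threshold
    if pairs == 0:
        return 1.0
    return hits / pairs


def _sweep_lers(
    units,
    case: ReadSet,
    control: ReadSet,
    genome: GenomeModel,
    grid: PdnpGrid,
    params: CallerParams,
    re_threshold: float,
    floor: bool,
) -> list[tuple[int, float]]:
    """FR-RE of the clustered training output at each connecting length."""
    sf = scale_factor(case.total_reads, control.total_reads)
    d_genome = genome.density(case.total_reads)
    chroms = training_chromosomes(genome, case.chroms)
    intervals = _as_intervals(units)
    sweep: list[tuple[int, float]] = []
    for l_pdnp in grid.values:
        trimmed = _cluster_candidate(units, case, control, genome, l_pdnp, params, chroms)
        frre = _member_gap_frre(
            trimmed, intervals, case, control, sf, d_genome, re_threshold, floor
        )
        sweep.append((l_pdnp, frre))
        logger.debug("LER candidate l=%d: FR-RE %.4f (%d regions)", l_pdnp, frre, len(trimmed))
    return sweep


def call_lers(
    units,
    case: ReadSet,
    control: ReadSet,
    genome: GenomeModel,
    shift: int,
    grid: PdnpGrid | None = None,
    frre_trigger: float = 0.01,
    frre_stop: float = 0.99,
    re_threshold: float = 1.5,
    params: CallerParams | None = None,
    seed: int = 0,
    floor: bool = True,
) -> list[ClusterRegion]:
    """Cluster ERs (or SERs) into LERs.

    Skips when the genome-wide FR-RE is at or below the trigger.  Among the
    candidate connecting lengths the largest one keeping the member-gap
    FR-RE at or above the stop level wins (else the smallest candidate), and
    is applied genome-wide.
    """
    params = params or CallerParams()
    if control is None:
        raise ValueError("LER calling requires a control sample")
    if len(units) < 2:
        return []
    frre_all = fr_re(units, case, control, genome, re_threshold, floor=floor)
    if frre_all <= frre_trigger:
        logger.info("FR-RE %.4f <= %.4f; no LER calling needed", frre_all, frre_trigger)
        return []
    if grid is None:
        shuffled = shuffle_regions(units, genome, seed)
        grid = pdnp_candidates(shuffled, LER_PERCENTILES, LER_CAP, seed)
    if len(grid) == 0:
        logger.warning("empty PDNP grid; LER calling skipped")
        return []

    # ascending sweep keeps the largest candidate before FR-RE decays below
    # the stop level; iteration halts at the first failure
    sf = scale_factor(case.total_reads, control.total_reads)
    d_genome = genome.density(case.total_reads)
    chroms = training_chromosomes(genome, case.chroms)
    intervals = _as_intervals(units)
    chosen = None
    first = None
    for l_pdnp in grid.values:
        trimmed = _cluster_candidate(units, case, control, genome, l_pdnp, params, chroms)
        frre = _member_gap_frre(
            trimmed, intervals, case, control, sf, d_genome, re_threshold, floor
        )
        logger.debug("LER candidate l=%d: FR-RE %.4f (%d regions)", l_pdnp, frre, len(trimmed))
        if first is None:
            first = (l_pdnp, frre)
        if frre >= frre_stop:
            chosen, stat = l_pdnp, frre
        else:
            break
    if chosen is None:
        chosen, stat = first
        logger.warning(
            "no connecting length kept FR-RE >= %.3f; using smallest (l=%d, FR-RE %.4f)",
            frre_stop,
            chosen,
            stat,
        )
    trimmed = _cluster_candidate(units, case, control, genome, chosen, params, None)
    return finalize_clusters("LER", trimmed, stat, case, control, genome, shift)


def length_dissimilarity(a_lengths, b_lengths) -> float:
    """Area between the empirical CDFs of two length sets (bp units)."""
    a = np.sort(np.asarray(a_lengths, dtype=float))
    b = np.sort(np.asarray(b_lengths, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("length distributions must be non-empty")
    xs = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(a, xs, side="right") / a.size
    fb = np.searchsorted(b, xs, side="right") / b.size
    widths = np.diff(xs)
    return float(np.sum(np.abs(fa[:-1] - fb[:-1]) * widths))


def call_matched_lers(
    units,
    case: ReadSet,
    control: ReadSet,
    genome: GenomeModel,
    shift: int,
    reference_lengths,
    grid: PdnpGrid | None = None,
    frre_trigger: float = 0.01,
    frre_stop: float = 0.99,
    re_threshold: float = 1.5,
    params: CallerParams | None = None,
    seed: int = 0,
    floor: bool = True,
) -> list[ClusterRegion]:
    """Call the LER set whose length distribution best matches a reference.

    Candidate connecting lengths keeping FR-RE above the stop level each
    yield a genome-wide LER set; the one minimizing the CDF-area
    dissimilarity against ``reference_lengths`` is returned.  With no
    qualifying candidate, falls back to the standard LER call.
    """
    params = params or CallerParams()
    if len(units) < 2:
        return []
    if grid is None:
        shuffled = shuffle_regions(units, genome, seed)
        grid = pdnp_candidates(shuffled, LER_PERCENTILES, LER_CAP, seed)
    if len(grid) == 0:
        logger.warning("empty PDNP grid; matched-LER calling skipped")
        return []
    sweep = _sweep_lers(units, case, control, genome, grid, params, re_threshold, floor)
    qualifying = [l for l, f in sweep if f > frre_stop]
    if not qualifying:
        logger.warning("no candidate with FR-RE > %.3f; falling back to standard LERs", frre_stop)
        return call_lers(
            units,
            case,
            control,
            genome,
            shift,
            grid=grid,
            frre_trigger=frre_trigger,
            frre_stop=frre_stop,
            re_threshold=re_threshold,
            params=params,
            seed=seed,
            floor=floor,
        )
    best_set: list[ClusterRegion] | None = None
    best_score = float("inf")
    for l_pdnp in qualifying:
        trimmed = _cluster_candidate(units, case, control, genome, l_pdnp, params, None)
        if not trimmed:
            continue
        lengths = [e - s for _, s, e, _ in trimmed]
        score = length_dissimilarity(lengths, reference_lengths)
        if score < best_score:
            best_score = score
            stat = dict(sweep)[l_pdnp]
            best_set = finalize_clusters("LER", trimmed, stat, case, control, genome, shift)
    if best_set is None:
        logger.warning("all qualifying candidates produced empty sets")
        return []
    return best_set
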