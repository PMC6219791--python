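"""Sliding bin-window Poisson enrichment testing and enriched-region calling.

The caller slides an initial window of ``n_bins`` consecutive bins along each
chromosome (one bin per step), shrinks it from the 5' side into 3'-anchored
step windows, drops step windows containing an over-long bin, keeps the
most significant step window as the *final window*, adjusts final-window
p-values genome-wide (Benjamini-Yekutieli) and merges significant final
windows into enriched regions (ERs).

Two equivalent code paths exist: small composable operations
(:func:`build_initial_windows`, :func:`step_windows`,
:func:`select_final_window`) that define the semantics, and a vectorized
scanner used by :func:`call_ers` for full-size libraries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc

from .reads_io import BinSequence, GenomeModel, ReadSet

logger = logging.getLogger(__name__)

# Any window with r <= lam + _SKIP_Z*sqrt(lam) has exact Poisson tail
# probability >= 0.10 for every lam (verified numerically over
# lam in [1e-3, 1e7]), so at the default 0.05 merge threshold it can never
# become significant (q >= p) and never outranks a window that can.
_SKIP_Z = 1.28
_SKIP_SAFE_THRESHOLD = 0.10

__all__ = [
    "WindowRec",
    "EnrichedRegion",
    "CallerParams",
    "poisson_p",
    "window_background",
    "by_qvalues",
    "build_initial_windows",
    "step_windows",
    "select_final_window",
    "merged_significant_windows",
    "optimize_max_allowed_length",
    "call_ers",
    "report_region",
    "compute_summit",
    "training_chromosomes",
]


# ---------------------------------------------------------------------------
# records


@dataclass
class WindowRec:
    """A window of consecutive bins with its enrichment statistics."""

    chrom: str
    first_bin: int
    last_bin: int
    start: int  # bp, inclusive (first member read)
    end: int  # bp, exclusive (position of the read after the last bin)
    l_window: int
    r_case: int
    r_control: int
    background: float
    p: float

    @property
    def n_bins(self) -> int:
        return self.last_bin - self.first_bin + 1


@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    r_case: int
    background: float
    p: float
    fc: float
    summit: int
    q: float = math.nan
    r_control: float = math.nan
    d_er: float = math.nan
    d_1kb: float = math.nan
    d_10kb: float = math.nan
    d_local: float = math.nan
    name: str = ""

    @property
    def l_er(self) -> int:
        return self.end - self.start


@dataclass
class CallerParams:
    """Tunables of the ER caller; defaults follow the method's defaults."""

    maximum_allowed_length: int | None = None
    q_threshold: float = 0.05
    merge_p_threshold: float = 0.05
    initial_window_bins: int = 20
    length_criterion_fraction: float = 0.80
    mcf: float = 0.8

    def __post_init__(self) -> None:
        for name in ("q_threshold", "merge_p_threshold", "length_criterion_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.maximum_allowed_length is not None and self.maximum_allowed_length <= 0:
            raise ValueError("maximum_allowed_length must be > 0")


# ---------------------------------------------------------------------------
# scalar statistics


def poisson_p(r_case: int, background: float) -> float:
    """Upper-tail Poisson probability P(X >= r_case | lambda=background).

    Matches ``ppois(r_case - 1, background, lower=FALSE)``.
    """
    if r_case <= 0:
        return 1.0
    if background <= 0:
        raise ValueError("background must be > 0")
    # P(X >= k) equals the regularized lower incomplete gamma P(k, lambda)
    return float(gammainc(r_case, background))


def window_background(
    r_window_control: int | float,
    l_window: int,
    d_genome: float,
    sf: float | None,
) -> float:
    """max(d_genome * l, R_control * SF); genome term alone without a control."""
    if l_window <= 0:
        raise ValueError("l_window must be > 0")
    expected = d_genome * l_window
    if sf is None:
        return expected
    return max(expected, r_window_control * sf)


def by_qvalues(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# reference (composable) window operations


def build_initial_windows(bins: BinSequence, n_bins: int = 20):
    """Yield ``(chrom, first_bin, last_bin)`` spans of initial windows.

    Full windows cover exactly ``n_bins`` consecutive bins; trailing windows
    at the chromosome end keep their actual (shorter) span.  Chromosomes
    with fewer than 2 bins are skipped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    for chrom, lengths in bins.lengths.items():
        nb = len(lengths)
        if nb < 2:
            continue
        for first in range(nb):
            yield chrom, first, min(first + n_bins - 1, nb - 1)


def step_windows(first_bin: int, last_bin: int, bin_lengths, max_allowed: int):
    """3'-anchored shrinkages of an initial window, minus excluded ones.

    Step window k keeps bins ``first_bin + k .. last_bin``; it is excluded
    when it contains a bin of length >= ``max_allowed``.
    """
    if max_allowed <= 0:
        raise ValueError("max_allowed must be > 0")
    out = []
    for s in range(first_bin, last_bin + 1):
        if all(bin_lengths[t] < max_allowed for t in range(s, last_bin + 1)):
            out.append((s, last_bin))
    return out


def window_stats(
    chrom: str,
    first_bin: int,
    last_bin: int,
    case_pos: np.ndarray,
    ctrl_pos: np.ndarray | None,
    d_genome: float,
    sf: float | None,
) -> WindowRec:
    """Fill a :class:`WindowRec` for a bin span on one chromosome."""
    start = int(case_pos[first_bin])
    end = int(case_pos[last_bin + 1])
    l_window = end - start
    # windows start at a read by construction; that structural read is not
    # part of the Poisson draw, so it is excluded from the window count
    r_case = int(
        np.searchsorted(case_pos, end, side="left")
        - np.searchsorted(case_pos, start, side="left")
    ) - 1
    r_ctrl = 0
    if ctrl_pos is not None:
        r_ctrl = int(
            np.searchsorted(ctrl_pos, end, side="left")
            - np.searchsorted(ctrl_pos, start, side="left")
        )
    # an all-duplicate window has zero extent and is untestable
    if l_window == 0:
        bg, p = 0.0, 1.0
    else:
        bg = window_background(r_ctrl, l_window, d_genome, sf)
        p = poisson_p(r_case, bg)
    return WindowRec(
        chrom=chrom,
        first_bin=first_bin,
        last_bin=last_bin,
        start=start,
        end=end,
        l_window=l_window,
        r_case=r_case,
        r_control=r_ctrl,
        background=bg,
        p=p,
    )


def select_final_window(steps: list[WindowRec]) -> WindowRec | None:
    """Minimum-p step window; ties go to the longer, then 5'-most, window."""
    best = None
    for w in steps:
        if (
            best is None
            or w.p < best.p
            or (w.p == best.p and (w.n_bins, -w.first_bin) > (best.n_bins, -best.first_bin))
        ):
            best = w
    return best


# ---------------------------------------------------------------------------
# vectorized scanner


def _scan_chromosome(
    case_pos: np.ndarray,
    ctrl_pos: np.ndarray | None,
    d_genome: float,
    sf: float | None,
    n_bins: int,
    max_bin_len: int,
    skip_bound: bool = True,
):
    """Final window (start, end, p) per initial window on one chromosome."""
    n = len(case_pos)
    nb = n - 1
    if nb < 2:
        return None
    lengths = np.diff(case_pos)
    idx = np.arange(nb, dtype=np.int64)
    # last over-long bin at or before j (-1 if none)
    lastbad = np.maximum.accumulate(np.where(lengths >= max_bin_len, idx, -1))
    jend = np.minimum(idx + n_bins - 1, nb - 1)

    # first-occurrence index of each position; counts reads in [start, end)
    # as first_occ[right] - first_occ[left] even with duplicates
    first_occ = np.searchsorted(case_pos, case_pos, side="left")
    ctrl_at = (
        np.searchsorted(ctrl_pos, case_pos)
        if ctrl_pos is not None and sf is not None
        else None
    )

    best_p = np.full(nb, np.inf)
    best_s = np.full(nb, -1, dtype=np.int64)
    seen = np.zeros(nb, dtype=bool)  # row had >= 1 testable step window
    for k in range(n_bins):
        s = idx + k
        rows = np.nonzero((s <= jend) & (s > lastbad[jend]))[0]
        if rows.size == 0:
            continue
        sv = s[rows]
        jv = jend[rows]
        start = case_pos[sv]
        end = case_pos[jv + 1]
        testable = end > start  # all-duplicate windows have zero extent
        rows, sv, jv, start, end = (
            rows[testable], sv[testable], jv[testable], start[testable], end[testable]
        )
        if rows.size == 0:
            continue
        seen[rows] = True
        lam = (d_genome * (end - start)).astype(float)
        if ctrl_at is not None:
            lam = np.maximum(lam, (ctrl_at[jv + 1] - ctrl_at[sv]) * sf)
        # exclude the structural read at the window start (see window_stats);
        # windows with r below the guaranteed-insignificance bound
        # (exact p >= merge threshold, hence q >= threshold) are skipped:
        # they can neither become significant nor outrank a window that can
        r_case = first_occ[jv + 1] - sv - 1
        if skip_bound:
            hot = r_case > lam + _SKIP_Z * np.sqrt(lam)
            if not np.any(hot):
                continue
            rows, sv, r_case, lam = rows[hot], sv[hot], r_case[hot], lam[hot]
        p = gammainc(np.maximum(r_case, 0).astype(float), lam)
        better = p < best_p[rows]
        upd = rows[better]
        best_p[upd] = p[better]
        best_s[upd] = sv[better]

    if not np.any(seen):
        return None
    # rows whose every step window is guaranteed insignificant keep the
    # initial-window span and a surrogate p of 0.5 (only their count matters)
    out_start = np.where(best_s >= 0, case_pos[np.maximum(best_s, 0)], case_pos[idx])
    out_p = np.where(best_s >= 0, best_p, 0.5)
    return (
        out_start[seen],
        case_pos[jend[seen] + 1],
        out_p[seen],
    )


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Merge overlapping or book-ended sorted-by-start intervals."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_start, m_end = [], []
    for s, e in zip(starts, ends):
        if m_end and s <= m_end[-1]:
            m_end[-1] = max(m_end[-1], e)
        else:
            m_start.append(s)
            m_end.append(e)
    return np.array(m_start, dtype=np.int64), np.array(m_end, dtype=np.int64)


@dataclass
class WindowScanResult:
    """Merged significant windows plus final-window diagnostics."""

    merged: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    n_final_windows: int = 0
    n_significant: int = 0
    final_q: np.ndarray | None = None

    @property
    def merged_lengths(self) -> np.ndarray:
        out = [e - s for s, e in self.merged.values()]
        if not out:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(out)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, (starts, ends) in self.merged.items():
            out.extend((chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out


def merged_significant_windows(
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    n_bins: int,
    max_bin_len: int,
    merge_p_threshold: float = 0.05,
    chroms: list[str] | None = None,
    sf: float | None = None,
    d_genome: float | None = None,
) -> WindowScanResult:
    """Scan chromosomes, BY-correct final-window p-values and merge hits.

    ``d_genome`` and ``sf`` default to values derived from the full
    libraries, even when scanning restricted to training chromosomes.
    """
    if d_genome is None:
        d_genome = genome.density(case.total_reads)
    if sf is None and control is not None:
        sf = case.total_reads / control.total_reads
    if chroms is None:
        chroms = case.chroms

    # the guaranteed-insignificance shortcut is only valid while the merge
    # threshold stays below the bound's verified tail probability
    skip_bound = merge_p_threshold <= _SKIP_SAFE_THRESHOLD / 2
    per_chrom: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    for chrom in chroms:
        pos = case.positions.get(chrom)
        if pos is None or len(pos) < 3:
            continue
        ctrl_pos = control.positions.get(chrom) if control is not None else None
        res = _scan_chromosome(pos, ctrl_pos, d_genome, sf, n_bins, max_bin_len, skip_bound)
        if res is not None:
            per_chrom.append((chrom, *res))

    result = WindowScanResult()
    if not per_chrom:
        return result
    all_p = np.concatenate([np.clip(p, np.nextafter(0, 1), 1.0) for _, _, _, p in per_chrom])
    q = by_qvalues(all_p)
    result.n_final_windows = int(all_p.size)
    result.n_significant = int(np.count_nonzero(q < merge_p_threshold))
    result.final_q = q

    offset = 0
    for chrom, starts, ends, p in per_chrom:
        sig = q[offset : offset + len(p)] < merge_p_threshold
        offset += len(p)
        if np.any(sig):
            result.merged[chrom] = _merge_intervals(starts[sig], ends[sig])
    return result


# ---------------------------------------------------------------------------
# parameter training and ER calling


def training_chromosomes(genome: GenomeModel, available: list[str]) -> list[str]:
    """chr1..chr5 when present; otherwise the five longest; all if fewer."""
    lowered = {c.lower(): c for c in available}
    named = [lowered[f"chr{i}"] for i in range(1, 6) if f"chr{i}" in lowered]
    if len(named) == 5:
        return named
    ranked = sorted(available, key=lambda c: -genome.chrom_sizes.get(c, 0))
    return ranked[:5]


def max_allowed_candidates(shift: int, n: int = 10) -> list[int]:
    """Evenly spaced candidates 0.2*shift .. 2*shift (first one is 0.2*shift)."""
    return [max(1, int(round(0.2 * shift * i))) for i in range(1, n + 1)]


def optimize_max_allowed_length(
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    shift: int,
    params: CallerParams | None = None,
) -> int:
    """Sweep bin-length ceilings until merged training windows are long enough.

    Returns the first candidate for which at least 80% (configurable) of the
    merged significant windows on the training chromosomes are longer than
    twice the shift, else the last candidate (2*shift).
    """
    params = params or CallerParams()
    chroms = training_chromosomes(genome, case.chroms)
    target_len = 2 * shift
    candidates = max_allowed_candidates(shift)
    any_windows = False
    for cand in candidates:
        scan = merged_significant_windows(
            case,
            control,
            genome,
            params.initial_window_bins,
            cand,
            params.merge_p_threshold,
            chroms=chroms,
        )
        lens = scan.merged_lengths
        if lens.size == 0:
            continue
        any_windows = True
        frac = float(np.mean(lens > target_len))
        logger.debug("max-allowed candidate %d: %.3f of windows > %d bp", cand, frac, target_len)
        if frac >= params.length_criterion_fraction:
            return cand
    if not any_windows:
        logger.warning("no significant windows at any candidate; using 2*shift")
    return candidates[-1]


def compute_summit(
    chrom_start: int,
    chrom_end: int,
    case_pos: np.ndarray,
    shift: int,
) -> int:
    """Leftmost maximum of the fragment pileup inside [start, end).

    Each (shifted) read position is extended ``shift`` bases on both sides.
    Falls back to the region midpoint when the region holds no reads.
    """
    lo = np.searchsorted(case_pos, chrom_start, side="left")
    hi = np.searchsorted(case_pos, chrom_end, side="left")
    reads = case_pos[lo:hi]
    if reads.size == 0:
        logger.warning("summit requested for read-free region; using midpoint")
        return int((chrom_start + chrom_end) // 2)
    length = chrom_end - chrom_start
    diff = np.zeros(length + 1, dtype=np.int32)
    a = np.clip(reads - shift, chrom_start, chrom_end) - chrom_start
    b = np.clip(reads + shift + 1, chrom_start, chrom_end) - chrom_start
    np.add.at(diff, a, 1)
    np.add.at(diff, b, -1)
    cover = np.cumsum(diff[:-1])
    return int(chrom_start + int(np.argmax(cover)))


def _density(ctrl_pos: np.ndarray, start: int, end: int) -> float:
    if end <= start:
        return 0.0
    n = np.searchsorted(ctrl_pos, end) - np.searchsorted(ctrl_pos, start)
    return float(n) / (end - start)


def report_region(
    chrom: str,
    start: int,
    end: int,
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    shift: int,
    sf: float | None = None,
    d_genome: float | None = None,
    with_summit: bool = True,
) -> EnrichedRegion:
    """Per-region statistics: counts, local-control background, p, FC, summit.

    The control background uses the densest of the matched region and 1 kb /
    10 kb windows centered on it (1 kb only for regions <= 1 kb, neither for
    regions > 10 kb), clipped at chromosome ends.
    """
    if d_genome is None:
        d_genome = genome.density(case.total_reads)
    if sf is None and control is not None:
        sf = case.total_reads / control.total_reads
    l_er = end - start
    case_pos = case.positions.get(chrom, np.empty(0, dtype=np.int64))
    r_case = int(np.searchsorted(case_pos, end) - np.searchsorted(case_pos, start))

    d_er = d_1kb = d_10kb = d_local = math.nan
    background = d_genome * l_er
    r_control = math.nan
    if control is not None and sf is not None:
        ctrl_pos = control.positions.get(chrom, np.empty(0, dtype=np.int64))
        size = genome.chrom_sizes[chrom]
        center = (start + end) // 2
        d_er = _density(ctrl_pos, start, end)

        def centered(width: int) -> float:
            lo = max(0, center - width // 2)
            hi = min(size, center + width // 2)
            return _density(ctrl_pos, lo, hi)

        if l_er <= 1000:
            d_1kb = centered(1000)
            d_10kb = centered(10000)
            d_local = max(d_er, d_1kb, d_10kb)
        elif l_er <= 10000:
            d_10kb = centered(10000)
            d_local = max(d_er, d_10kb)
        else:
            d_local = d_er
        r_control = d_local * l_er
        background = max(d_genome * l_er, r_control * sf)

    p = poisson_p(r_case, background)
    fc = r_case / background if background > 0 else math.inf
    summit = (
        compute_summit(start, end, case_pos, shift)
        if with_summit
        else (start + end) // 2
    )
    return EnrichedRegion(
        chrom=chrom,
        start=start,
        end=end,
        r_case=r_case,
        background=background,
        p=p,
        fc=fc,
        summit=summit,
        r_control=r_control,
        d_er=d_er,
        d_1kb=d_1kb,
        d_10kb=d_10kb,
        d_local=d_local,
    )


def call_ers(
    case: ReadSet,
    control: ReadSet | None,
    genome: GenomeModel,
    params: CallerParams,
    shift: int,
    chroms: list[str] | None = None,
) -> list[EnrichedRegion]:
    """Call enriched regions genome-wide.

    Requires ``params.maximum_allowed_length`` (set by the optimizer or the
    user).  Reported regions carry BY q-values recomputed across the
    reported set; only regions with q below the threshold are returned.
    """
    if params.maximum_allowed_length is None:
        raise ValueError("maximum_allowed_length is unset; run the optimizer first")
    d_genome = genome.density(case.total_reads)
    sf = case.total_reads / control.total_reads if control is not None else None
    scan = merged_significant_windows(
        case,
        control,
        genome,
        params.initial_window_bins,
        params.maximum_allowed_length,
        params.merge_p_threshold,
        chroms=chroms,
        sf=sf,
        d_genome=d_genome,
    )
    ers: list[EnrichedRegion] = []
    for chrom, c_start, c_end in scan.intervals():
        ers.append(
            report_region(
                chrom, c_start, c_end, case, control, genome, shift, sf=sf, d_genome=d_genome
            )
        )
    ers.sort(key=lambda e: (e.chrom, e.start))
    if ers:
        q = by_qvalues([max(e.p, np.nextafter(0, 1)) for e in ers])
        for er, qv in zip(ers, q):
            er.q = float(qv)
        ers = [e for e in ers if e.q < params.q_threshold]
    for i, er in enumerate(ers, start=1):
        er.name = f"ER_{i}"
    return ers
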