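"""Seeded ChIP-seq read simulator with known feature truth.

Fragments are modeled explicitly: a feature emits fragment centers inside
itself and every single-end read reports one fragment endpoint (+ strand at
the start, - strand at the end, ``fragment_size`` apart), so the shift
estimator can recover half the fragment size.  Optional PCR duplication
resamples emitted reads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reads_io import ReadSet

logger = logging.getLogger(__name__)

__all__ = ["FeatureSpec", "SimConfig", "SimTruth", "simulate", "truth_eval", "write_reads_bed"]


@dataclass
class FeatureSpec:
    """One feature class.

    ``peak``: a single emitting interval of ``width`` bp.
    ``cluster``: ``n_sub`` peaks of ``width`` bp separated by ``gap`` bp.
    ``domain``: a span of ``width`` bp whose interior is split into
    ``n_sub`` emitting segments separated by ``gap`` bp of read-free space.
    ``enrichment`` weights how many in-feature reads the class attracts
    relative to its emitting length.
    """

    kind: str
    count: int
    width: int
    n_sub: int = 1
    gap: int = 0
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "cluster", "domain"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "peak":
            self.n_sub = 1

    @property
    def span(self) -> int:
        """Total genomic footprint of one feature."""
        if self.kind == "cluster":
            return self.n_sub * self.width + (self.n_sub - 1) * self.gap
        return self.width


@dataclass
class SimConfig:
    chrom_sizes: dict[str, int]
    features: list[FeatureSpec] = field(default_factory=list)
    fragment_size: int = 200
    case_reads: int = 100_000
    control_reads: int = 100_000
    in_feature_fraction: float = 0.5
    pcr_duplication_case: float = 0.0
    pcr_duplication_control: float = 0.0
    spacing: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("in_feature_fraction", "pcr_duplication_case", "pcr_duplication_control"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class SimTruth:
    """Truth intervals (chrom, start, end, label) plus expected read counts."""

    intervals: list[tuple[str, int, int, str]]
    expected_reads: dict[int, float]  # index into `intervals` -> expected in-feature reads

    def labeled(self, label: str) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, s, e, lab in self.intervals if lab == label]

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, (chrom, start, end, label) in enumerate(self.intervals):
                exp = self.expected_reads.get(i, 0.0)
                fh.write(f"{chrom}\t{start}\t{end}\t{label}_{i + 1}\t{exp:.1f}\t.\n")


def _default_chroms() -> dict[str, int]:
    return {f"chr{i}": 2_000_000 for i in range(1, 6)}


def _place_features(config: SimConfig, rng: np.random.Generator):
    """Rejection-place feature footprints, keeping ``spacing`` bp apart."""
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights = sizes / sizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    layout = []  # (spec, chrom, start)
    margin = config.fragment_size
    for spec in config.features:
        for _ in range(spec.count):
            span = spec.span
            for _attempt in range(2000):
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                size = config.chrom_sizes[chrom]
                if size - span - 2 * margin <= 0:
                    continue
                start = int(rng.integers(margin, size - span - margin))
                ok = all(
                    start >= e + config.spacing or start + span <= s - config.spacing
                    for s, e in placed[chrom]
                )
                if ok:
                    placed[chrom].append((start, start + span))
                    layout.append((spec, chrom, start))
                    break
            else:
                raise RuntimeError("could not place feature; genome too crowded")
    return layout


def _emitting_segments(spec: FeatureSpec, chrom: str, start: int):
    """Intervals that actually emit reads for one placed feature."""
    segs = []
    if spec.kind == "peak":
        segs.append((chrom, start, start + spec.width))
    elif spec.kind == "cluster":
        pos = start
        for _ in range(spec.n_sub):
            segs.append((chrom, pos, pos + spec.width))
            pos += spec.width + spec.gap
    else:  # domain: n_sub emitting segments inside `width`, separated by gaps
        seg_len = (spec.width - (spec.n_sub - 1) * spec.gap) // spec.n_sub
        if seg_len <= 0:
            raise ValueError("domain gaps exceed domain width")
        pos = start
        for _ in range(spec.n_sub):
            segs.append((chrom, pos, pos + seg_len))
            pos += seg_len + spec.gap
    return segs


def _emit_reads(
    centers_chrom: list[str],
    centers: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Fragment centers -> single-end 5' positions with strands."""
    half = config.fragment_size // 2
    strand = rng.choice(np.array([1, -1], dtype=np.int8), size=len(centers))
    pos = centers - strand * half  # + reads sit upstream, - reads downstream
    return centers_chrom, pos, strand


def _apply_pcr(chroms, pos, strand, rate: float, rng: np.random.Generator):
    n = len(pos)
    n_dup = int(round(rate * n))
    if n_dup == 0:
        return chroms, pos, strand
    keep = n - n_dup
    idx = rng.permutation(n)[:keep]
    dup = rng.choice(idx, size=n_dup, replace=True)
    final = np.concatenate([idx, dup])
    return [chroms[i] for i in final], pos[final], strand[final]


def _to_readset(label: str, chroms, pos, strand, config: SimConfig) -> ReadSet:
    positions: dict[str, list[int]] = {c: [] for c in config.chrom_sizes}
    strands: dict[str, list[int]] = {c: [] for c in config.chrom_sizes}
    for c, p, s in zip(chroms, pos, strand):
        size = config.chrom_sizes[c]
        positions[c].append(min(max(int(p), 0), size - 1))
        strands[c].append(int(s))
    rs = ReadSet(
        sample_label=label,
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        strands={c: np.array(v, dtype=np.int8) for c, v in strands.items()},
        layout="single",
        fragment_hint=config.fragment_size,
    )
    rs.sort()
    return rs


def simulate(config: SimConfig) -> tuple[ReadSet, ReadSet, SimTruth]:
    """Generate a case library, a feature-free control library and the truth."""
    rng = np.random.default_rng(config.seed)
    layout = _place_features(config, rng)

    truth_intervals: list[tuple[str, int, int, str]] = []
    expected: dict[int, float] = {}
    segments: list[tuple[str, int, int]] = []
    seg_weights: list[float] = []
    for spec, chrom, start in layout:
        truth_intervals.append((chrom, start, start + spec.span, spec.kind))
        if spec.kind == "cluster":
            for _, s, e in _emitting_segments(spec, chrom, start):
                truth_intervals.append((chrom, s, e, "peak"))
        for seg in _emitting_segments(spec, chrom, start):
            segments.append(seg)
            seg_weights.append((seg[2] - seg[1]) * spec.enrichment)

    chrom_names = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_w = sizes / sizes.sum()

    # case: in-feature + background fragment centers
    n_feat = int(round(config.in_feature_fraction * config.case_reads)) if segments else 0
    n_bg = config.case_reads - n_feat
    c_chroms: list[str] = []
    c_centers: list[np.ndarray] = []
    if n_feat:
        w = np.array(seg_weights) / np.sum(seg_weights)
        alloc = rng.multinomial(n_feat, w)
        seg_of_feature: dict[int, float] = {}
        for (chrom, s, e), k in zip(segments, alloc):
            if k:
                c_chroms.extend([chrom] * k)
                c_centers.append(rng.integers(s, e, size=k))
        # expected counts per truth feature footprint
        total_w = float(np.sum(seg_weights))
        i_seg = 0
        i_truth = 0
        for spec, chrom, start in layout:
            n_segs = len(_emitting_segments(spec, chrom, start))
            wsum = sum(seg_weights[i_seg : i_seg + n_segs])
            expected[i_truth] = n_feat * wsum / total_w
            i_truth += 1 + (spec.n_sub if spec.kind == "cluster" else 0)
            i_seg += n_segs
    if n_bg:
        counts = rng.multinomial(n_bg, chrom_w)
        for c, k in zip(chrom_names, counts):
            if k:
                c_chroms.extend([c] * k)
                c_centers.append(rng.integers(0, config.chrom_sizes[c], size=k))
    centers = np.concatenate(c_centers) if c_centers else np.empty(0, dtype=np.int64)
    chroms_l, pos, strand = _emit_reads(c_chroms, centers, config, rng)
    chroms_l, pos, strand = _apply_pcr(chroms_l, pos, strand, config.pcr_duplication_case, rng)
    case = _to_readset("case", chroms_l, pos, strand, config)

    # control: uniform background only
    g_chroms: list[str] = []
    g_centers: list[np.ndarray] = []
    counts = rng.multinomial(config.control_reads, chrom_w)
    for c, k in zip(chrom_names, counts):
        if k:
            g_chroms.extend([c] * k)
            g_centers.append(rng.integers(0, config.chrom_sizes[c], size=k))
    centers = np.concatenate(g_centers) if g_centers else np.empty(0, dtype=np.int64)
    chroms_l, pos, strand = _emit_reads(g_chroms, centers, config, rng)
    chroms_l, pos, strand = _apply_pcr(chroms_l, pos, strand, config.pcr_duplication_control, rng)
    control = _to_readset("control", chroms_l, pos, strand, config)

    return case, control, SimTruth(intervals=truth_intervals, expected_reads=expected)


def write_reads_bed(reads: ReadSet, path: str | Path) -> None:
    """1-bp BED6 records whose 5' end reproduces the stored position."""
    with open(path, "w") as fh:
        i = 0
        for chrom in reads.positions:
            pos = reads.positions[chrom]
            strand = reads.strands[chrom]
            for p, s in zip(pos, strand):
                i += 1
                sym = "-" if s < 0 else "+"
                fh.write(f"{chrom}\t{p}\t{p + 1}\tread_{i}\t0\t{sym}\n")


def write_config_json(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)


def truth_eval(calls, truth_intervals, criterion: float = 0.5) -> tuple[float, float]:
    """Precision/recall of calls against truth at a reciprocal-overlap cutoff.

    Matching is one-to-one, greedy by overlap size.
    """
    calls = [
        (c[0], c[1], c[2]) if isinstance(c, tuple) else (c.chrom, c.start, c.end)
        for c in calls
    ]
    truth = [(t[0], t[1], t[2]) for t in truth_intervals]
    if not calls:
        return 1.0, (0.0 if truth else 1.0)
    candidates = []
    for i, (cc, cs, ce) in enumerate(calls):
        for j, (tc, ts, te) in enumerate(truth):
            if cc != tc:
                continue
            ov = min(ce, te) - max(cs, ts)
            if ov <= 0:
                continue
            if ov >= criterion * (ce - cs) and ov >= criterion * (te - ts):
                candidates.append((ov, i, j))
    candidates.sort(reverse=True)
    used_c: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in candidates:
        if i not in used_c and j not in used_t:
            used_c.add(i)
            used_t.add(j)
    precision = len(used_c) / len(calls)
    recall = len(used_t) / len(truth) if truth else 1.0
    return precision, recall
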