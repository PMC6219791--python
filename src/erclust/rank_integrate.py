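"""Ranking of called regions, motif-based reliability evaluation, gene
association and the bivalent-domain candidate filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "ReliabilityCurve",
    "rank_ers",
    "rank_sers",
    "rank_lers",
    "summit_height",
    "reliability_curve",
    "area_ratio",
    "associate_genes",
    "bivalent_candidate_filter",
    "integration_table",
    "read_bed_intervals",
]


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED3+ intervals as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"feature_{i + 1}"
            out.append((f[0], int(f[1]), int(f[2]), name))
    return out


@dataclass
class RankedList:
    """Signals ordered by a rank-sum scheme.

    ``final_rank[i]`` is the 1-based rank of input signal i; ``order``
    lists input indices from best to worst.
    """

    ids: list[str]
    component_ranks: dict[str, np.ndarray]
    final_rank: np.ndarray

    @property
    def order(self) -> np.ndarray:
        return np.argsort(self.final_rank, kind="stable")

    def top(self, n: int) -> np.ndarray:
        return self.order[:n]


def _rank(values, coords, ascending: bool) -> np.ndarray:
    """1-based ranks with stable (chrom, start) tie-breaking."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    keys = sorted(
        range(n),
        key=lambda i: ((values[i] if ascending else -values[i]), coords[i]),
    )
    ranks = np.empty(n, dtype=np.int64)
    for r, i in enumerate(keys, start=1):
        ranks[i] = r
    return ranks


def _ranksum(components: dict[str, np.ndarray], coords) -> RankedList:
    total = sum(components.values())
    ids = [f"{c[0]}:{c[1]}-{c[2]}" if len(c) > 2 else str(c) for c in coords]
    final = _rank(total, coords, ascending=True)
    return RankedList(ids=ids, component_ranks=components, final_rank=final)


def summit_height(er, case, shift: int) -> int:
    """Fragment pileup depth at the ER summit (reads within +-shift)."""
    pos = case.positions.get(er.chrom, np.empty(0, dtype=np.int64))
    lo = np.searchsorted(pos, er.summit - shift, side="left")
    hi = np.searchsorted(pos, er.summit + shift, side="right")
    return int(hi - lo)


def rank_ers(ers, summit_heights) -> RankedList:
    """Rank-sum of q (ascending) and summit height (descending)."""
    coords = [(e.chrom, e.start, e.end) for e in ers]
    comp = {
        "q": _rank([e.q for e in ers], coords, ascending=True),
        "summit": _rank(summit_heights, coords, ascending=False),
    }
    rl = _ranksum(comp, coords)
    rl.ids = [e.name or rl.ids[i] for i, e in enumerate(ers)]
    return rl


def rank_sers(sers, order: str = "desc") -> RankedList:
    """Rank SERs by read number (descending by default; "asc" is literal)."""
    coords = [(s.chrom, s.start, s.end) for s in sers]
    comp = {"reads": _rank([s.r_case for s in sers], coords, ascending=order == "asc")}
    rl = RankedList(
        ids=[s.name or f"{c[0]}:{c[1]}-{c[2]}" for s, c in zip(sers, coords)],
        component_ranks=comp,
        final_rank=comp["reads"].copy(),
    )
    return rl


def rank_lers(lers) -> RankedList:
    """Rank-sum of fold-change (descending) and length (descending)."""
    coords = [(l.chrom, l.start, l.end) for l in lers]
    comp = {
        "fc": _rank([l.fc for l in lers], coords, ascending=False),
        "length": _rank([l.end - l.start for l in lers], coords, ascending=False),
    }
    rl = _ranksum(comp, coords)
    rl.ids = [l.name or rl.ids[i] for i, l in enumerate(lers)]
    return rl


@dataclass
class ReliabilityCurve:
    cutoffs: np.ndarray
    fractions: np.ndarray

    @property
    def area(self) -> float:
        if len(self.cutoffs) == 1:
            return float(self.fractions[0] * self.cutoffs[0])
        return float(np.trapezoid(self.fractions, self.cutoffs))


def _group_intervals(intervals) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    grouped: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(iv[0], []).append((iv[1], iv[2]))
    out = {}
    for chrom, rows in grouped.items():
        rows.sort()
        out[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
        )
    return out


def _near_any(index, chrom: str, start: int, end: int, dist: int) -> bool:
    if chrom not in index:
        return False
    starts, ends = index[chrom]
    return bool(np.any((starts < end + dist) & (ends > start - dist)))


def reliability_curve(
    ers_in_rank_order,
    motif_hits,
    window: int = 150,
    step: int = 100,
) -> ReliabilityCurve:
    """Fraction of top-N regions with a motif hit within +-window of summit."""
    index = _group_intervals(motif_hits)
    hit = np.array(
        [
            _near_any(index, e.chrom, e.summit, e.summit + 1, window)
            for e in ers_in_rank_order
        ]
    )
    n = len(hit)
    cutoffs = list(range(step, n + 1, step)) or [n]
    fractions = [float(np.mean(hit[:c])) for c in cutoffs]
    return ReliabilityCurve(
        cutoffs=np.array(cutoffs, dtype=float), fractions=np.array(fractions)
    )


def area_ratio(rival: ReliabilityCurve, ours: ReliabilityCurve) -> tuple[float, str]:
    """rival area / our area; verdict L (>1.01) / H (<0.99) / E otherwise."""
    if not np.array_equal(rival.cutoffs, ours.cutoffs):
        raise ValueError("curves must share cutoffs")
    if ours.area == 0:
        ratio = float("inf") if rival.area > 0 else 1.0
    else:
        ratio = rival.area / ours.area
    if ratio > 1.01:
        verdict = "L"
    elif ratio < 0.99:
        verdict = "H"
    else:
        verdict = "E"
    return ratio, verdict


def associate_genes(signals, genes, mode: str) -> list[tuple[str, int]]:
    """Gene-signal association pairs (gene_id, signal_index).

    Modes: ``ser`` = overlap or within 1 kb; ``ler`` = at least 80% of the
    gene covered by one signal; ``tf_ler`` = overlap or within 10 kb.
    """
    if mode not in ("ser", "ler", "tf_ler"):
        raise ValueError(f"unknown mode {mode!r}")
    sig = [(s[0], s[1], s[2]) if isinstance(s, tuple) else (s.chrom, s.start, s.end) for s in signals]
    pairs: list[tuple[str, int]] = []
    for chrom, g_start, g_end, gene_id in genes:
        g_len = g_end - g_start
        for j, (s_chrom, s_start, s_end) in enumerate(sig):
            if s_chrom != chrom:
                continue
            if mode == "ler":
                overlap = min(g_end, s_end) - max(g_start, s_start)
                if g_len > 0 and overlap >= 0.8 * g_len:
                    pairs.append((gene_id, j))
            else:
                dist = 1000 if mode == "ser" else 10000
                if s_start < g_end + dist and s_end > g_start - dist:
                    pairs.append((gene_id, j))
    return pairs


def bivalent_candidate_filter(
    h3k4me3_sers_ranked,
    nanog_lers_ranked,
    oct4_lers_ranked,
    h3k27me3_lers,
    genes,
    top_ser: int = 300,
    top_tf: int = 1000,
    h3k27_rule: str = "overlap",
) -> list[str]:
    """Genes near top active marks and TF clusters, clear of repressive marks.

    Inputs are rank-ordered region lists (best first).  A gene passes when it
    (1) overlaps or lies within 1 kb of a top-``top_ser`` H3K4me3 SER,
    (2) overlaps or lies within 10 kb of a top-``top_tf`` Nanog or Oct4 LER,
    and (3) is not covered by any H3K27me3 LER (any overlap by default; set
    ``h3k27_rule="cover80"`` for the 80%-coverage reading).
    """
    def idx(regions):
        return _group_intervals(
            [(r[0], r[1], r[2]) if isinstance(r, tuple) else (r.chrom, r.start, r.end) for r in regions]
        )

    ser_idx = idx(h3k4me3_sers_ranked[:top_ser])
    tf_idx = idx(list(nanog_lers_ranked[:top_tf]) + list(oct4_lers_ranked[:top_tf]))
    k27_idx = idx(h3k27me3_lers)

    out = []
    for chrom, g_start, g_end, gene_id in genes:
        if not _near_any(ser_idx, chrom, g_start, g_end, 1000):
            continue
        if not _near_any(tf_idx, chrom, g_start, g_end, 10000):
            continue
        if h3k27_rule == "overlap":
            if _near_any(k27_idx, chrom, g_start, g_end, 0):
                continue
        else:  # cover80
            covered = 0.0
            if chrom in k27_idx:
                starts, ends = k27_idx[chrom]
                ov = np.minimum(ends, g_end) - np.maximum(starts, g_start)
                covered = float(np.clip(ov, 0, None).sum())
            if covered >= 0.8 * (g_end - g_start):
                continue
        out.append(gene_id)
    return sorted(set(out))


def integration_table(
    h3k4me3_sers,
    h3k27me3_lers,
    nanog_top,
    oct4_top,
) -> pd.DataFrame:
    """Per-SER association matrix with best-ranked TF clusters.

    ``nanog_top`` / ``oct4_top`` are rank-ordered (best first) region lists;
    the lowest-index LER within 10 kb of each SER is recorded.  H3K27me3
    LERs count when within 1 kb.
    """
    def best_within(regions, chrom, start, end, dist):
        for rank0, r in enumerate(regions):
            r_chrom, r_start, r_end = (
                (r[0], r[1], r[2]) if isinstance(r, tuple) else (r.chrom, r.start, r.end)
            )
            if r_chrom == chrom and r_start < end + dist and r_end > start - dist:
                return rank0 + 1
        return None

    k27_idx = _group_intervals(
        [(r[0], r[1], r[2]) if isinstance(r, tuple) else (r.chrom, r.start, r.end) for r in h3k27me3_lers]
    )
    rows = []
    for s in h3k4me3_sers:
        chrom, start, end = (
            (s[0], s[1], s[2]) if isinstance(s, tuple) else (s.chrom, s.start, s.end)
        )
        rows.append(
            {
                "ser": getattr(s, "name", f"{chrom}:{start}-{end}"),
                "chrom": chrom,
                "start": start,
                "end": end,
                "nanog_rank": best_within(nanog_top, chrom, start, end, 10000),
                "oct4_rank": best_within(oct4_top, chrom, start, end, 10000),
                "h3k27me3": _near_any(k27_idx, chrom, start, end, 1000),
            }
        )
    return pd.DataFrame(rows)
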