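"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops,
scipy.stats distributions and statsmodels adjustments so that it shares no
code path with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bf_poisson_upper(r: int, lam: float) -> float:
    """P(X >= r) by summing pmf terms (small r) or scipy sf."""
    if r <= 0:
        return 1.0
    return float(stats.poisson.sf(r - 1, lam))


def bf_by(pvalues):
    if len(pvalues) == 0:
        return np.array([])
    return multipletests(pvalues, method="fdr_by")[1]


def _count(sorted_pos, start, end):
    return sum(1 for p in sorted_pos if start <= p < end)


def bf_final_windows(case_pos, ctrl_pos, d_genome, sf, n_bins, max_allowed):
    """All final windows (start, end, p) for one chromosome, by enumeration."""
    pos = list(case_pos)
    nb = len(pos) - 1
    if nb < 2:
        return []
    lengths = [pos[i + 1] - pos[i] for i in range(nb)]
    finals = []
    for i in range(nb):
        j = min(i + n_bins - 1, nb - 1)
        steps = []
        for s in range(i, j + 1):
            if any(lengths[t] >= max_allowed for t in range(s, j + 1)):
                continue
            start, end = pos[s], pos[j + 1]
            if end <= start:
                continue
            r = _count(pos, start, end) - 1  # structural read excluded
            lam = d_genome * (end - start)
            if ctrl_pos is not None and sf is not None:
                lam = max(lam, _count(ctrl_pos, start, end) * sf)
            steps.append((bf_poisson_upper(r, lam), s, start, end))
        if not steps:
            continue
        # min p; ties -> longer window (smaller s)
        best = min(steps, key=lambda t: (t[0], t[1]))
        finals.append((best[2], best[3], best[0]))
    return finals


def bf_merge(intervals):
    """Merge overlapping or book-ended (start, end) pairs."""
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def bf_report_p(chrom, start, end, case, control, genome, d_genome, sf):
    """Region p-value with the local-control background, independently."""
    case_pos = list(case.positions.get(chrom, []))
    l_er = end - start
    r_case = _count(case_pos, start, end)
    bg = d_genome * l_er
    if control is not None and sf is not None:
        ctrl_pos = list(control.positions.get(chrom, []))
        size = genome.chrom_sizes[chrom]
        center = (start + end) // 2

        def dens(a, b):
            a, b = max(0, a), min(size, b)
            return _count(ctrl_pos, a, b) / (b - a) if b > a else 0.0

        d_er = dens(start, end)
        if l_er <= 1000:
            d_local = max(d_er, dens(center - 500, center + 500), dens(center - 5000, center + 5000))
        elif l_er <= 10000:
            d_local = max(d_er, dens(center - 5000, center + 5000))
        else:
            d_local = d_er
        bg = max(bg, d_local * l_er * sf)
    return bf_poisson_upper(r_case, bg), r_case


def bf_call_ers(case, control, genome, n_bins, max_allowed,
                merge_p=0.05, q_threshold=0.05):
    """Full brute-force ER calling: enumerate, BY, merge, report, filter."""
    d_genome = case.total_reads / (genome.l_genome * genome.mcf)
    sf = case.total_reads / control.total_reads if control is not None else None
    finals = []  # (chrom, start, end, p)
    for chrom in case.positions:
        ctrl_pos = list(control.positions.get(chrom, [])) if control is not None else None
        for start, end, p in bf_final_windows(
            list(case.positions[chrom]), ctrl_pos, d_genome, sf, n_bins, max_allowed
        ):
            finals.append((chrom, start, end, p))
    if not finals:
        return []
    q = bf_by([min(max(f[3], 1e-300), 1.0) for f in finals])
    sig_by_chrom = {}
    for (chrom, start, end, _), qv in zip(finals, q):
        if qv < merge_p:
            sig_by_chrom.setdefault(chrom, []).append((start, end))
    regions = []
    for chrom in sorted(sig_by_chrom):
        for start, end in bf_merge(sig_by_chrom[chrom]):
            regions.append((chrom, start, end))
    if not regions:
        return []
    pvals = []
    for chrom, start, end in regions:
        p, _ = bf_report_p(chrom, start, end, case, control, genome, d_genome, sf)
        pvals.append(min(max(p, 1e-300), 1.0))
    qvals = bf_by(pvals)
    return [r for r, qv in zip(regions, qvals) if qv < q_threshold]
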