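"""Negative-selection CRISPR screen gene prioritization.

sgRNA counts are projected onto the rank positions of a non-targeting
control pool in each generation; a gene is scored by the largest
generation-to-generation rank drop among its sgRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SgRnaTable",
    "load_sgrna_table",
    "control_pool",
    "rank_position",
    "gene_scores",
    "ks_enrichment",
]


@dataclass
class SgRnaTable:
    """Per-sgRNA counts for two generations plus the non-targeting flag."""

    frame: pd.DataFrame  # columns: sgrna, gene, non_targeting, count_gen1, count_gen10

    def __post_init__(self) -> None:
        required = {"sgrna", "gene", "non_targeting", "count_gen1", "count_gen10"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if (self.frame[["count_gen1", "count_gen10"]] < 0).any().any():
            raise ValueError("negative counts")
        targeting = self.frame[~self.frame.non_targeting]
        if targeting.gene.isna().any() or (targeting.gene == "").any():
            raise ValueError("targeting sgRNA without gene ID")


def load_sgrna_table(path: str | Path) -> SgRnaTable:
    frame = pd.read_csv(path, sep="\t")
    frame["non_targeting"] = frame["non_targeting"].astype(bool)
    frame["gene"] = frame["gene"].fillna("").astype(str)
    return SgRnaTable(frame)


def control_pool(table: SgRnaTable, min_reads: int = 10) -> dict[str, np.ndarray]:
    """Non-targeting counts passing the generation-1 filter, ranked descending.

    The same sgRNAs (selected on generation 1) form the pool in both
    generations.
    """
    nt = table.frame[table.frame.non_targeting]
    passing = nt[nt.count_gen1 > min_reads]
    if passing.empty:
        raise ValueError(f"no non-targeting sgRNA with >{min_reads} reads at generation 1")
    return {
        "gen1": np.sort(passing.count_gen1.to_numpy())[::-1],
        "gen10": np.sort(passing.count_gen10.to_numpy())[::-1],
    }


def rank_position(count: int, pool: np.ndarray) -> int:
    """Descending insertion rank: 1 + number of pool counts strictly greater.

    A count tied with a pool entry shares that entry's position; a count
    below the whole pool lands at pool size + 1.
    """
    if len(pool) == 0:
        raise ValueError("empty control pool")
    ascending = pool[::-1]  # pool is sorted descending
    greater = len(pool) - np.searchsorted(ascending, count, side="right")
    return int(greater) + 1


def gene_scores(table: SgRnaTable, pools: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Per-gene best rank-position drop, genes ranked by score descending.

    Returns a frame with columns gene, score, rank (ties broken by gene ID).
    """
    if pools is None:
        pools = control_pool(table)
    targeting = table.frame[~table.frame.non_targeting]
    asc1 = pools["gen1"][::-1]
    asc10 = pools["gen10"][::-1]
    n1, n10 = len(asc1), len(asc10)
    pos1 = n1 - np.searchsorted(asc1, targeting.count_gen1.to_numpy(), side="right") + 1
    pos10 = n10 - np.searchsorted(asc10, targeting.count_gen10.to_numpy(), side="right") + 1
    delta = pos10 - pos1
    per_gene = (
        pd.DataFrame({"gene": targeting.gene.to_numpy(), "delta": delta})
        .groupby("gene", sort=False)["delta"]
        .max()
        .reset_index()
        .rename(columns={"delta": "score"})
    )
    per_gene = per_gene.sort_values(["score", "gene"], ascending=[False, True], kind="stable")
    per_gene["rank"] = np.arange(1, len(per_gene) + 1)
    return per_gene.reset_index(drop=True)


def ks_enrichment(candidates, ranked_genes) -> tuple[float, float]:
    """One-sided KS test for candidate enrichment at the top of a gene ranking.

    ``ranked_genes`` is the full ordered gene list (best first);
    ``candidates`` must be a subset.  Candidate positions are compared to a
    uniform null over the list.
    """
    order = {g: i + 1 for i, g in enumerate(ranked_genes)}
    missing = [g for g in candidates if g not in order]
    if missing:
        raise ValueError(f"candidates absent from ranking: {missing[:5]}")
    n = len(ranked_genes)
    positions = np.array([order[g] for g in candidates], dtype=float) / n
    res = stats.ks_1samp(positions, stats.uniform.cdf, alternative="greater")
    return float(res.statistic), float(res.pvalue)
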