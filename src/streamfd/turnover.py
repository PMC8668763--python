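"""Temporal turnover between consecutive surveys, taxonomic and functional.

Taxonomic turnover between surveys t and t+1 is (gains + losses) / pooled
richness. Functional turnover reuses the same arithmetic with trait
modalities as the "species" and community-weighted means (CWM) as the
"abundances": a modality is present in a year when its CWM exceeds a
threshold epsilon (default 0, strict positivity). Consecutive pairs are
consecutive *surveys*; gap years are allowed and the pair gap is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import CommunityMatrix

__all__ = ["TurnoverSeries", "taxonomic_turnover", "functional_turnover"]


@dataclass(frozen=True)
class TurnoverSeries:
    """Per consecutive survey pair: gains, losses, pooled richness, turnover."""

    table: pd.DataFrame  # columns: year_from, year_to, gap, gains, losses, total, turnover
    mode: str  # 'taxonomic' | 'functional'

    def __post_init__(self) -> None:
        t = self.table["turnover"].dropna()
        if ((t < 0) | (t > 1)).any():
            raise ValueError("turnover must lie in [0, 1]")

    @property
    def turnover(self) -> pd.Series:
        return self.table["turnover"]

    def mean(self) -> float:
        return float(self.table["turnover"].mean())


def _pairwise(years: list[int], presence: dict[int, set], mode: str) -> TurnoverSeries:
    rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        s0, s1 = presence[y0], presence[y1]
        total = len(s0 | s1)
        if total == 0:
            rows.append((y0, y1, y1 - y0, 0, 0, 0, np.nan))
            continue
        gains = len(s1 - s0)
        losses = len(s0 - s1)
        rows.append((y0, y1, y1 - y0, gains, losses, total, (gains + losses) / total))
    table = pd.DataFrame(
        rows,
        columns=["year_from", "year_to", "gap", "gains", "losses", "total", "turnover"],
    )
    return TurnoverSeries(table=table, mode=mode)


def taxonomic_turnover(comm: CommunityMatrix) -> TurnoverSeries:
    """Species replacement between consecutive surveys: (gains+losses)/union."""
    years = comm.years
    if len(years) < 2:
        raise ValueError("need >= 2 surveys")
    presence = {y: set(comm.present(y)) for y in years}
    return _pairwise(years, presence, "taxonomic")


def functional_turnover(cwm_series: pd.DataFrame, epsilon: float = 0.0) -> TurnoverSeries:
    """Modality replacement between consecutive surveys of a CWM table.

    ``cwm_series`` is year x modality; a modality counts as present when its
    CWM exceeds ``epsilon``.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    years = [int(y) for y in cwm_series.index]
    if len(years) < 2:
        raise ValueError("need >= 2 surveys")
    presence = {}
    for y in years:
        row = cwm_series.loc[y]
        presence[y] = set(row.index[row > epsilon])
    return _pairwise(years, presence, "functional")
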