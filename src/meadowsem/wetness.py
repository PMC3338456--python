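"""Composite meadow-scale hydrologic ranking.

Monitoring sites carry ordinal wetness ranks on a fixed 0-6 scale
(0 = driest grass/forb communities, 6 = continuously flooded). The
meadow-scale rank is the arithmetic mean of its site ranks, rounded to
the nearest integer. Rounding is half-up by default (3.5 -> 4) and is
configurable because the source convention for exact halves is
ambiguous; the documented worked example (mean 3.6 -> rank 4) does not
disambiguate halves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

RANK_MIN = 0
RANK_MAX = 6

RoundingRule = Literal["half-up", "banker"]


@dataclass(frozen=True)
class CompositeRank:
    """Meadow-level composite hydrologic rank.

    Attributes
    ----------
    mean_score : float
        Arithmetic mean of the site ranks, in [0, 6].
    rank : int
        Rounded integer meadow rank, in {0..6}.
    n_sites : int
        Number of site ranks averaged.
    """

    mean_score: float
    rank: int
    n_sites: int

    def __post_init__(self) -> None:
        if not (RANK_MIN <= self.mean_score <= RANK_MAX):
            raise ValueError(f"mean_score {self.mean_score} outside [0, 6]")
        if self.rank not in range(RANK_MIN, RANK_MAX + 1):
            raise ValueError(f"rank {self.rank} outside {{0..6}}")


def _round(x: float, rule: RoundingRule) -> int:
    if rule == "half-up":
        return int(math.floor(x + 0.5))
    if rule == "banker":
        return int(round(x))
    raise ValueError(f"unknown rounding rule: {rule!r}")


def composite_meadow_rank(
    site_ranks: Sequence[int] | Iterable[int],
    rounding: RoundingRule = "half-up",
) -> CompositeRank:
    """Average site hydrologic ranks into a composite meadow rank.

    Parameters
    ----------
    site_ranks : sequence of int
        Site wetness ranks, each in {0..6}. Must be non-empty.
    rounding : {"half-up", "banker"}
        How to round the mean score to an integer rank.

    Returns
    -------
    CompositeRank

    Examples
    --------
    >>> composite_meadow_rank([6, 6, 6, 0, 0])
    CompositeRank(mean_score=3.6, rank=4, n_sites=5)
    """
    ranks = list(site_ranks)
    if len(ranks) == 0:
        raise ValueError("site_ranks must be non-empty")
    for r in ranks:
        if not float(r).is_integer() or not (RANK_MIN <= int(r) <= RANK_MAX):
            raise ValueError(f"site rank {r!r} not an integer in {{0..6}}")
    mean_score = float(np.mean([int(r) for r in ranks]))
    return CompositeRank(
        mean_score=mean_score,
        rank=_round(mean_score, rounding),
        n_sites=len(ranks),
    )


def rank_meadows(
    sites: pd.DataFrame,
    rank_col: str = "rank",
    meadow_col: str = "meadow",
    rounding: RoundingRule = "half-up",
) -> pd.DataFrame:
    """Compute composite ranks for every meadow in a site table.

    Site ranks are one-time assignments, so duplicated (site, year,
    season) rows are collapsed to one rank per site before averaging.

    Returns a frame with columns ``meadow``, ``mean_score``, ``comp_rank``
    and ``n_sites``.
    """
    required = {rank_col, meadow_col, "site"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    per_site = sites.drop_duplicates(subset=[meadow_col, "site"])
    rows = []
    for meadow, grp in per_site.groupby(meadow_col, sort=True):
        comp = composite_meadow_rank(grp[rank_col].tolist(), rounding=rounding)
        rows.append(
            {
                meadow_col: meadow,
                "mean_score": comp.mean_score,
                "comp_rank": comp.rank,
                "n_sites": comp.n_sites,
            }
        )
    return pd.DataFrame(rows)
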