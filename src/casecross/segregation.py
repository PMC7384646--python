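"""Block-group racial composition and segregation indices.

Two census-derived measures of residential segregation are computed from
non-Hispanic white/black counts in nested census geographies (block groups
within tracts):

* **RRS** (racial residential segregation score), a concentration-at-the-
  extremes measure of the two races *within* a block group,

      RRS = (n_white - n_black) / n_total  in [-1, 1],

  negative for black-majority block groups, positive for white-majority ones,
  and 0 exactly when the two counts are equal.

* **IRD** (index of racial dissimilarity), the classical dissimilarity index
  of the block groups *within* their tract,

      D = 50 * sum_i | b_i / B - w_i / W |   (percent, in [0, 100]),

  where ``b_i``/``w_i`` are block-group black/white counts and ``B``/``W``
  the tract totals. D is the share of either group that would have to move
  across block groups to equalize the two distributions; every block group
  of the tract is assigned its tract's D.

RRS is additionally binned into five categories (G1 black-majority … G5
white-majority) used as a categorical effect modifier downstream, with G1 as
the reference level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedScoreError, ValidationError

__all__ = [
    "CensusUnit",
    "compute_rrs",
    "compute_ird",
    "categorize_rrs",
    "RRS_CATEGORIES",
    "score_census_table",
    "read_census_csv",
]

#: Category labels, black-majority to white-majority. G1 is the downstream
#: reference level.
RRS_CATEGORIES = ("G1", "G2", "G3", "G4", "G5")

#: Interior bin edges. Assignment is G1=[-1,-0.5), G2=[-0.5,-0.1),
#: G3=[-0.1,0.1], G4=(0.1,0.5], G5=(0.5,1] so that every score in [-1, 1]
#: falls in exactly one bin.
_RRS_EDGES = (-0.5, -0.1, 0.1, 0.5)


@dataclass(frozen=True)
class CensusUnit:
    """Race counts for one census block group and its parent tract."""

    block_group_id: str
    tract_id: str
    n_white: int
    n_black: int
    n_total: int

    def __post_init__(self):
        if self.n_white < 0 or self.n_black < 0 or self.n_total < 0:
            raise ValidationError(f"negative count in block group {self.block_group_id!r}")
        if self.n_white + self.n_black > self.n_total:
            raise ValidationError(
                f"block group {self.block_group_id!r}: n_white + n_black exceeds n_total"
            )


def compute_rrs(unit: CensusUnit) -> float:
    """Concentration-at-extremes segregation score of one block group.

    Raises
    ------
    UndefinedScoreError
        If the block group has zero total population.
    """
    if unit.n_total <= 0:
        raise UndefinedScoreError(
            f"block group {unit.block_group_id!r} has zero population; RRS undefined"
        )
    return (unit.n_white - unit.n_black) / unit.n_total


def compute_ird(units_in_tract: list[CensusUnit]) -> dict[str, float]:
    """Dissimilarity index of a tract, assigned to each member block group.

    Parameters
    ----------
    units_in_tract
        All block groups of a single tract.

    Returns
    -------
    dict mapping block_group_id to the tract's dissimilarity index (percent).

    Raises
    ------
    ValidationError
        If the units do not share one tract id.
    UndefinedScoreError
        If either race has a zero tract-level total (the index compares two
        distributions; an empty one is undefined, and such tracts are flagged
        and excluded downstream).
    """
    if not units_in_tract:
        raise ValidationError("empty tract")
    tract_ids = {u.tract_id for u in units_in_tract}
    if len(tract_ids) != 1:
        raise ValidationError(f"units span multiple tracts: {sorted(tract_ids)}")
    b = np.array([u.n_black for u in units_in_tract], dtype=float)
    w = np.array([u.n_white for u in units_in_tract], dtype=float)
    B, W = b.sum(), w.sum()
    if B <= 0 or W <= 0:
        raise UndefinedScoreError(
            f"tract {units_in_tract[0].tract_id!r} has a zero race total (B={B:g}, W={W:g}); "
            "dissimilarity undefined"
        )
    d = 50.0 * np.abs(b / B - w / W).sum()
    return {u.block_group_id: float(d) for u in units_in_tract}


def categorize_rrs(rrs: float) -> str:
    """Bin an RRS score into one of five categories G1..G5.

    G1=[-1,-0.5), G2=[-0.5,-0.1), G3=[-0.1,0.1], G4=(0.1,0.5], G5=(0.5,1].
    """
    if not np.isfinite(rrs) or rrs < -1.0 or rrs > 1.0:
        raise ValidationError(f"RRS {rrs!r} outside [-1, 1]")
    if rrs < _RRS_EDGES[0]:
        return "G1"
    if rrs < _RRS_EDGES[1]:
        return "G2"
    if rrs <= _RRS_EDGES[2]:
        return "G3"
    if rrs <= _RRS_EDGES[3]:
        return "G4"
    return "G5"


def read_census_csv(path) -> pd.DataFrame:
    """Read a census race-count table.

    Expected header: ``block_group_id,tract_id,n_white,n_black,n_total``.
    """
    df = pd.read_csv(path, dtype={"block_group_id": str, "tract_id": str})
    required = {"block_group_id", "tract_id", "n_white", "n_black", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"census table missing columns: {sorted(missing)}")
    return df


def score_census_table(census: pd.DataFrame) -> pd.DataFrame:
    """Compute composition percentages, RRS (with category) and IRD per block group.

    Block groups with zero population, and tracts with a zero race total, are
    retained in the output with NaN scores and a non-empty ``flag`` column so
    downstream joins can exclude them explicitly.

    Returns a frame with columns
    ``block_group_id, pct_white, pct_black, rrs, rrs_category, ird, flag``.
    """
    units = [
        CensusUnit(str(r.block_group_id), str(r.tract_id), int(r.n_white), int(r.n_black), int(r.n_total))
        for r in census.itertuples(index=False)
    ]
    seen: set[str] = set()
    for u in units:
        if u.block_group_id in seen:
            raise ValidationError(f"duplicate block group id {u.block_group_id!r}")
        seen.add(u.block_group_id)

    rows = []
    for u in units:
        if u.n_total > 0:
            rows.append(
                dict(
                    block_group_id=u.block_group_id,
                    tract_id=u.tract_id,
                    pct_white=100.0 * u.n_white / u.n_total,
                    pct_black=100.0 * u.n_black / u.n_total,
                    rrs=compute_rrs(u),
                    flag="",
                )
            )
        else:
            rows.append(
                dict(
                    block_group_id=u.block_group_id,
                    tract_id=u.tract_id,
                    pct_white=np.nan,
                    pct_black=np.nan,
                    rrs=np.nan,
                    flag="zero_population",
                )
            )
    out = pd.DataFrame(rows)
    out["rrs_category"] = [
        categorize_rrs(v) if np.isfinite(v) else "" for v in out["rrs"]
    ]

    ird = pd.Series(np.nan, index=out.index)
    for tract_id, idx in out.groupby("tract_id").groups.items():
        tract_units = [u for u in units if u.tract_id == tract_id]
        try:
            d = compute_ird(tract_units)
        except UndefinedScoreError:
            out.loc[idx, "flag"] = (
                out.loc[idx, "flag"].where(out.loc[idx, "flag"] != "", "undefined_ird")
            )
            continue
        ird.loc[idx] = [d[bg] for bg in out.loc[idx, "block_group_id"]]
    out["ird"] = ird

    cols = ["block_group_id", "pct_white", "pct_black", "rrs", "rrs_category", "ird", "flag"]
    return out[cols]
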