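"""Plant availability and Jacobs' selectivity index.

The vegetation survey assigns each taxon a Braun-Blanquet cover-abundance
category per quadrat; categories are converted to percent cover via the
median (midpoint) of each category's range, averaged over quadrats and
renormalized into an availability vector p. Selectivity contrasts the mean
relative read abundance r of a taxon in a species-year's diets against p:

    D = (r - p) / (r + p - 2 r p)

D ranges over [-1, 1]: negative = avoidance, positive = selection, ~0 =
use proportional to availability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SELECTED = "selected"
NEUTRAL = "neutral"
AVOIDED = "avoided"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class BraunBlanquetScale:
    """Ordered cover-abundance categories: (label, lower %, upper %]."""

    categories: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        uppers = [hi for _, _, hi in self.categories]
        if any(b < a for a, b in zip(uppers, uppers[1:])):
            raise ValueError("category upper bounds must be monotone")
        for label, lo, hi in self.categories:
            if not (0 <= lo < hi <= 100):
                raise ValueError(f"bad cover range for {label!r}: ({lo}, {hi}]")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.categories)

    def midpoint(self, label: str) -> float:
        """Median percent cover of a category's range ('' means absent, 0)."""
        if label in ("", None) or (isinstance(label, float) and np.isnan(label)):
            return 0.0
        for cat, lo, hi in self.categories:
            if cat == str(label):
                return (lo + hi) / 2.0
        raise ValueError(f"unknown Braun-Blanquet category {label!r}")

    def category_for_cover(self, cover: float) -> str:
        """Category whose (lo, hi] interval brackets a percent cover."""
        if cover <= 0:
            return ""
        for cat, lo, hi in self.categories:
            if lo < cover <= hi:
                return cat
        return self.categories[-1][0]  # > 100% crowding, top category


#: Extended 9-category scale. '1' (few individuals) and '2m' (many small
#: individuals) share the 1-5% cover band, as in the extended scale.
DEFAULT_BB_SCALE = BraunBlanquetScale(
    (
        ("r", 0.0, 0.1),
        ("+", 0.1, 1.0),
        ("1", 1.0, 5.0),
        ("2m", 1.0, 5.0),
        ("2a", 5.0, 12.5),
        ("2b", 12.5, 25.0),
        ("3", 25.0, 50.0),
        ("4", 50.0, 75.0),
        ("5", 75.0, 100.0),
    )
)


def braun_blanquet_to_relative(
    survey: pd.DataFrame, scale: BraunBlanquetScale = DEFAULT_BB_SCALE
) -> pd.Series:
    """Quadrat x taxon category table -> relative availability vector.

    Each cell maps to its category midpoint, per-taxon cover is averaged
    over quadrats, and the vector is renormalized to sum to 1.
    """
    cover = survey.map(scale.midpoint).mean(axis=0)
    total = cover.sum()
    if total == 0:
        raise ValueError("survey has no cover in any quadrat")
    return cover / total


def jacobs_d(r, p):
    """Jacobs' selectivity index D = (r - p) / (r + p - 2 r p).

    Accepts scalars or arrays with r, p in [0, 1]. Returns NaN where the
    denominator vanishes (r = p = 0 or r = p = 1).
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if ((r < 0) | (r > 1)).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("r and p must lie in [0, 1]")
    denom = r + p - 2 * r * p
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom == 0, np.nan, (r - p) / np.where(denom == 0, 1, denom))
    return float(d) if d.ndim == 0 else d


def classify_selection(d: float, neutral_band: float = 0.1) -> str:
    """Label a D value: selected (> band), avoided (< -band), else neutral."""
    if d is None or (isinstance(d, float) and np.isnan(d)):
        return UNDEFINED
    if d > neutral_band:
        return SELECTED
    if d < -neutral_band:
        return AVOIDED
    return NEUTRAL


def selectivity_table(
    profiles,
    availability: pd.Series,
    neutral_band: float = 0.1,
    per_individual: bool = False,
) -> pd.DataFrame:
    """Jacobs' D per (species, year, taxon) from RRA diet profiles.

    ``r`` is the group-mean RRA over that species-year's individuals (with
    ``per_individual=True``, the mean of per-individual D values is reported
    instead, as ``D``). Taxa eaten but absent from the survey get p = 0,
    hence D = 1, and are flagged ``survey_absent``.
    """
    rra = profiles.rra
    meta = profiles.meta.set_index("sample_id")
    records = []
    for (sp, year), idx in meta.groupby(["species", "year"]).groups.items():
        group = rra.loc[list(idx)]
        if group.empty:
            logger.info("selectivity_table: empty group %s %s skipped", sp, year)
            continue
        for taxon in rra.columns:
            r = float(group[taxon].mean())
            p = float(availability.get(taxon, 0.0))
            flagged = p == 0.0 and r > 0.0
            if flagged:
                d = 1.0
            elif per_individual:
                with np.errstate(invalid="ignore"):
                    d = float(np.nanmean(jacobs_d(group[taxon].to_numpy(), p)))
            else:
                d = jacobs_d(r, p)
            records.append(
                {
                    "species": sp,
                    "year": year,
                    "taxon": taxon,
                    "r": r,
                    "p": p,
                    "D": d,
                    "class": classify_selection(d, neutral_band),
                    "n_individuals": int((group[taxon] > 0).sum()),
                    "survey_absent": flagged,
                }
            )
    return pd.DataFrame.from_records(records)
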