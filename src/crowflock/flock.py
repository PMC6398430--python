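"""Mark-resight local flock size estimation.

A partially marked population is surveyed by repeated transect scans.
Unmarked birds cannot be told apart, so raw unmarked sighting counts
overestimate the number of unmarked individuals whenever birds are seen
more than once per day.  The within-day resighting ratio of the *marked*
birds provides a correction factor

    CF = (CM_t - CM_ind) / CM_t

where ``CM_t`` is the total number of marked-bird sightings on a day
(including resightings) and ``CM_ind`` the number of unique marked
individuals that day.  The daily local flock size estimate is then

    FS_e = CM_ind + (CU - CU * CF) / T

with ``CU`` the total unmarked sightings and ``T`` the number of transects
that day (the effort division applies only to the unmarked term — the
marked individuals are known exactly).  A per-transect variant
``CM_ind_t + CU_t * (1 - CF_day)`` feeds the count models, where ``CF_day``
is the day-level correction factor and no effort division is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DailyCounts",
    "DailyEstimate",
    "compute_correction_factor",
    "estimate_daily_flock_size",
    "estimate_transect_flock_size",
    "daily_series",
    "transect_series",
]


@dataclass(frozen=True)
class DailyCounts:
    """Per-day sighting tallies entering the estimator."""

    date: object
    CM_t: int  # marked sightings incl. resightings
    CM_ind: int  # unique marked individuals
    CU: int  # unmarked sightings incl. potential resightings
    T: int  # transects that day

    def __post_init__(self) -> None:
        if self.CM_ind > self.CM_t:
            raise ValueError("CM_ind cannot exceed CM_t")
        if min(self.CM_t, self.CM_ind, self.CU) < 0:
            raise ValueError("counts must be nonnegative")
        if self.T < 1:
            raise ValueError("need at least one transect per observation day")


@dataclass(frozen=True)
class DailyEstimate:
    """Correction factor and flock size estimate for one day."""

    date: object
    CF: float
    FS_e: float
    per_transect: tuple = field(default_factory=tuple)
    cf_imputed: bool = False


def compute_correction_factor(CM_t: int, CM_ind: int) -> float:
    """Within-day resighting ratio of marked birds.

    Returns a value in [0, 1).  Raises :class:`ZeroDivisionError`-style
    ``ValueError`` when ``CM_t`` is zero; the caller is expected to
    substitute the study-period mean CF for such days.
    """
    if CM_t < CM_ind or CM_ind < 0:
        raise ValueError("require CM_t >= CM_ind >= 0")
    if CM_t == 0:
        raise ValueError("CF undefined for CM_t = 0")
    return (CM_t - CM_ind) / CM_t


def estimate_daily_flock_size(counts: DailyCounts, CF: float) -> float:
    """Daily estimate CM_ind + (CU - CU*CF)/T."""
    if not 0.0 <= CF <= 1.0:
        raise ValueError("CF must lie in [0, 1]")
    return counts.CM_ind + (counts.CU - counts.CU * CF) / counts.T


def estimate_transect_flock_size(CM_ind_t: int, CU_t: int, CF_day: float) -> float:
    """Per-transect estimate CM_ind_t + CU_t*(1 - CF_day).

    Uses the day-level correction factor; no effort division because a
    single transect is a single sampling occasion.
    """
    if not 0.0 <= CF_day <= 1.0:
        raise ValueError("CF_day must lie in [0, 1]")
    return CM_ind_t + CU_t * (1.0 - CF_day)


def _deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate sighting rows (same session, bird, position).

    A bird legitimately reappears across sessions; identical rows within a
    session are data-entry duplicates.
    """
    keys = [c for c in ("date", "session", "bird_id", "x_m", "y_m") if c in records.columns]
    n0 = len(records)
    out = records.drop_duplicates(subset=keys)
    if len(out) < n0:
        logger.warning("dropped %d duplicate sighting rows", n0 - len(out))
    return out


def _split_counts(day: pd.DataFrame) -> tuple[int, int, int]:
    """(CM_t, CM_ind, CU) for one day's records.

    Marked birds whose ring could not be read (marked flag set, no id)
    carry no resighting information, so they are tallied with the unmarked
    sightings for abundance purposes.
    """
    marked = day["marked"].astype(int) == 1
    identified = marked & day["bird_id"].notna() & (day["bird_id"] != "unmarked") & (day["bird_id"] != "")
    CM_t = int(identified.sum())
    CM_ind = int(day.loc[identified, "bird_id"].nunique())
    CU = int(len(day) - CM_t)
    return CM_t, CM_ind, CU


def daily_series(records: pd.DataFrame) -> pd.DataFrame:
    """Daily counts, correction factors and flock size estimates.

    Parameters
    ----------
    records : DataFrame with columns ``date, session, bird_id, marked``.
        ``bird_id`` is ``"unmarked"`` (or empty) for unidentifiable birds.

    Returns
    -------
    DataFrame with one row per observation day:
    ``date, CM_t, CM_ind, CU, T, CF, FS_e, cf_imputed``.

    Days with marked sightings but no resighting information (``CM_t = 0``)
    receive the study-period mean CF so the daily series stays complete;
    such days are flagged in ``cf_imputed``.
    """
    records = _deduplicate(records)
    n_unid_marked = int(
        ((records["marked"].astype(int) == 1)
         & ((records["bird_id"].isna()) | (records["bird_id"] == "unmarked") | (records["bird_id"] == ""))).sum()
    )
    if n_unid_marked:
        logger.info("%d unidentifiable marked sightings counted with unmarked birds", n_unid_marked)

    rows = []
    for date, day in records.groupby("date", sort=True):
        T = int(day["session"].nunique())
        if T == 0 or len(day) == 0:
            logger.warning("day %s has no records; omitted", date)
            continue
        CM_t, CM_ind, CU = _split_counts(day)
        rows.append({"date": date, "CM_t": CM_t, "CM_ind": CM_ind, "CU": CU, "T": T})
    if not rows:
        raise ValueError("no observation days in input")
    table = pd.DataFrame(rows)

    with np.errstate(invalid="ignore", divide="ignore"):
        cf = (table["CM_t"] - table["CM_ind"]) / table["CM_t"]
    defined = table["CM_t"] > 0
    if not defined.any():
        raise ValueError("no day has marked sightings; correction factor cannot be estimated")
    mean_cf = float(cf[defined].mean())
    imputed = ~defined
    if imputed.any():
        logger.info("substituted study-mean CF=%.4f on %d day(s) with CM_t=0", mean_cf, int(imputed.sum()))
    table["CF"] = cf.where(defined, mean_cf)
    table["cf_imputed"] = imputed
    table["FS_e"] = table["CM_ind"] + (table["CU"] - table["CU"] * table["CF"]) / table["T"]
    return table


def transect_series(records: pd.DataFrame) -> pd.DataFrame:
    """Per-transect flock size estimates using the day-level CF.

    Returns ``date, session, CM_ind_t, CU_t, CF, FS_e_t`` with one row per
    transect (session) actually surveyed.
    """
    daily = daily_series(records).set_index("date")
    records = _deduplicate(records)
    rows = []
    for (date, session), grp in records.groupby(["date", "session"], sort=True):
        CM_t, CM_ind_t, CU_t = _split_counts(grp)
        cf = float(daily.loc[date, "CF"])
        rows.append(
            {
                "date": date,
                "session": session,
                "CM_ind_t": CM_ind_t,
                "CU_t": CU_t,
                "CF": cf,
                "FS_e_t": estimate_transect_flock_size(CM_ind_t, CU_t, cf),
            }
        )
    return pd.DataFrame(rows)
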