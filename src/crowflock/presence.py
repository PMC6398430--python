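"""Residency classification from individual sighting histories.

Each marked, individually identified bird yields a sighting history over
the monitoring calendar (the days on which at least one transect was
walked).  Three summary features describe the shape of that history:

* ``days_seen`` — number of monitoring days the bird was identified;
* ``max_gap`` — longest run of monitoring days without an observation,
  between the bird's first and last sighting;
* ``gap_sd`` — sample standard deviation of those interior gap lengths.

Birds seen on fewer than ``min_days`` days are labelled *rare* visitors a
priori.  The remaining birds are clustered (complete-linkage agglomerative
clustering on Euclidean distances between z-scored features) and the
resulting clusters are mapped onto *resident*, *continuous* and *periodic*
presence categories.

Gaps are measured in monitoring days, not calendar days: absence is only
observable when observers were in the field, and calendar gaps would
inflate every bird's gap statistics across survey interruptions.
Leading and trailing censored intervals (before first / after last
sighting) are excluded; set ``include_censored=True`` for the alternative
reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceFeatures",
    "extract_presence_features",
    "feature_table",
    "standardize_features",
    "hierarchical_cluster",
    "assign_categories",
]

CATEGORY_ORDER = ("resident", "continuous", "periodic", "rare")


@dataclass(frozen=True)
class PresenceFeatures:
    bird_id: str
    days_seen: int
    max_gap: int
    gap_sd: float


def extract_presence_features(
    bird_id: str,
    observation_days,
    monitoring_calendar,
    include_censored: bool = False,
) -> PresenceFeatures:
    """Gap statistics for one bird's sighting history.

    ``observation_days`` and ``monitoring_calendar`` are date-like
    sequences; every observation day must be a monitoring day.  A gap is
    ``d_{i+1} - d_i - 1`` counted in monitoring-day positions.  With
    ``include_censored`` the runs before the first and after the last
    sighting are appended to the gap list.
    """
    calendar = pd.DatetimeIndex(sorted(pd.to_datetime(monitoring_calendar).unique()))
    days = pd.DatetimeIndex(sorted(pd.to_datetime(pd.Index(observation_days)).unique()))
    if len(days) == 0:
        raise ValueError(f"bird {bird_id}: empty sighting history")
    pos = calendar.get_indexer(days)
    if (pos < 0).any():
        bad = days[pos < 0]
        raise ValueError(f"bird {bird_id}: observation days outside monitoring calendar: {list(bad)}")
    gaps = np.diff(pos) - 1
    if include_censored:
        gaps = np.concatenate([[pos[0]], gaps, [len(calendar) - 1 - pos[-1]]])
    max_gap = int(gaps.max()) if gaps.size else 0
    gap_sd = float(np.std(gaps, ddof=1)) if gaps.size >= 2 else 0.0
    return PresenceFeatures(bird_id=str(bird_id), days_seen=len(days), max_gap=max_gap, gap_sd=gap_sd)


def feature_table(
    records: pd.DataFrame,
    monitoring_calendar=None,
    include_censored: bool = False,
) -> pd.DataFrame:
    """Per-bird presence features from identified marked sightings.

    ``records`` is the sightings table; only rows with ``marked == 1`` and
    a readable id contribute.  The monitoring calendar defaults to the set
    of days present in ``records`` (every day with at least one record).
    """
    if monitoring_calendar is None:
        monitoring_calendar = records["date"].unique()
    ident = records[
        (records["marked"].astype(int) == 1)
        & records["bird_id"].notna()
        & ~records["bird_id"].isin(["unmarked", ""])
    ]
    rows = []
    for bird, grp in ident.groupby("bird_id", sort=True):
        f = extract_presence_features(bird, grp["date"].unique(), monitoring_calendar, include_censored)
        rows.append({"bird_id": f.bird_id, "days_seen": f.days_seen, "max_gap": f.max_gap, "gap_sd": f.gap_sd})
    return pd.DataFrame(rows, columns=["bird_id", "days_seen", "max_gap", "gap_sd"])


def standardize_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sample SD 1); constant columns dropped."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 birds to standardize")
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            logger.warning("feature %r is constant; dropped from clustering", col)
            continue
        out[col] = (x - x.mean()) / sd
    if not out:
        raise ValueError("all features constant; nothing to cluster on")
    return pd.DataFrame(out, index=matrix.index)


def hierarchical_cluster(standardized: pd.DataFrame | np.ndarray, k: int = 3) -> np.ndarray:
    """Complete-linkage agglomerative clustering cut into ``k`` clusters.

    Returns integer labels in ``{0..k-1}``; label identity is arbitrary
    (compare partitions, not labels).  Distance ties are resolved by the
    linkage implementation's lowest-index rule, making the result
    deterministic for a fixed row order.
    """
    X = np.asarray(standardized, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError("k cannot exceed the number of birds")
    if len(X) == 1:
        return np.zeros(1, dtype=int)
    Z = linkage(pdist(X), method="complete")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def dendrogram_table(standardized: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Merge list of the complete-linkage tree: one row per agglomeration
    with the indices joined (original points, then internal nodes numbered
    from n), the merge height, and the resulting cluster size."""
    X = np.asarray(standardized, dtype=float)
    Z = linkage(pdist(X), method="complete")
    return pd.DataFrame(
        {
            "node_a": Z[:, 0].astype(int),
            "node_b": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "size": Z[:, 3].astype(int),
        }
    )


def assign_categories(
    features: pd.DataFrame,
    min_days: int = 5,
    k: int = 3,
) -> pd.DataFrame:
    """Classify birds into resident / continuous / periodic / rare.

    Birds with ``days_seen < min_days`` are rare visitors and are excluded
    from clustering.  Clusters of the remaining birds are mapped to named
    categories by descending mean ``days_seen``, ties broken by ascending
    mean ``max_gap``: the most frequently seen cluster is *resident*, then
    *continuous*, then *periodic*.

    Returns a DataFrame ``bird_id, category, cluster_id`` (``cluster_id``
    is ``-1`` for rare visitors).
    """
    if features.empty:
        raise ValueError("no classified birds")
    rare = features[features["days_seen"] < min_days]
    eligible = features[features["days_seen"] >= min_days].reset_index(drop=True)
    if len(eligible) < k:
        raise ValueError(f"only {len(eligible)} birds with >= {min_days} days; cannot form {k} clusters")

    std = standardize_features(eligible[["days_seen", "max_gap", "gap_sd"]])
    labels = hierarchical_cluster(std, k=k)
    n_effective = len(np.unique(labels))
    if n_effective < k:
        logger.warning("only %d effective clusters found for k=%d", n_effective, k)

    summary = (
        eligible.assign(cluster=labels)
        .groupby("cluster")
        .agg(mean_days=("days_seen", "mean"), mean_gap=("max_gap", "mean"))
        .sort_values(["mean_days", "mean_gap"], ascending=[False, True])
    )
    names = ["resident", "continuous", "periodic"] + [f"cluster_{i}" for i in range(3, k)]
    mapping = {cl: names[i] for i, cl in enumerate(summary.index)}

    rows = [
        {"bird_id": b, "category": mapping[c], "cluster_id": int(c)}
        for b, c in zip(eligible["bird_id"], labels)
    ]
    rows += [{"bird_id": b, "category": "rare", "cluster_id": -1} for b in rare["bird_id"]]
    out = pd.DataFrame(rows, columns=["bird_id", "category", "cluster_id"])
    return out.sort_values("bird_id").reset_index(drop=True)
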