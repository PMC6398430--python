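"""Spatial subgroup detection within a transect session.

A foraging subgroup is a maximal chain of nonflying birds in which every
member has at least one neighbour within ``radius`` metres (boundary
inclusive) with an unobstructed line of sight.  Chains are the connected
components of the association graph whose edges join sighting pairs that
satisfy both conditions; a bird 8 m from another still belongs to the same
subgroup if an intermediate bird links them.

Line of sight is blocked when the *open* segment between two positions
properly crosses a barrier segment (walls, dense tree lines); merely
touching a barrier endpoint does not block, which avoids degenerate
occlusion by zero-measure contacts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = ["build_association_graph", "connected_components", "subgroup_table"]


def _blocked(p: np.ndarray, q: np.ndarray, barriers: np.ndarray) -> np.ndarray:
    """For stacked sight lines p[i]->q[i], whether any barrier blocks them.

    A barrier blocks when the interiors of the two segments intersect
    (proper crossing) or when they overlap collinearly over positive length.
    """
    if len(barriers) == 0:
        return np.zeros(len(p), dtype=bool)
    lines = shapely.linestrings(np.stack([p, q], axis=1))
    blocked = np.zeros(len(p), dtype=bool)
    for seg in barriers:
        bar = shapely.linestrings(seg.reshape(2, 2))
        # proper interior crossing, or collinear overlap of positive length
        blocked |= shapely.crosses(lines, bar)
        blocked |= shapely.length(shapely.intersection(lines, bar)) > 0
    return blocked


def build_association_graph(
    positions: np.ndarray,
    barriers: np.ndarray | None = None,
    radius: float = 5.0,
) -> np.ndarray:
    """Edges (i, j), i < j, of the within-``radius`` line-of-sight graph.

    Parameters
    ----------
    positions : (n, 2) array of planar coordinates in metres.
    barriers : (m, 4) array of segments ``(x1, y1, x2, y2)``, or None.
    radius : association radius in metres, boundary inclusive.
    """
    positions = np.asarray(positions, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if positions.size and not np.isfinite(positions).all():
        raise ValueError("positions must be finite")
    if len(positions) < 2:
        return np.empty((0, 2), dtype=int)
    barriers = np.empty((0, 4)) if barriers is None else np.asarray(barriers, dtype=float)

    tree = cKDTree(positions)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")  # inclusive of == r
    if len(pairs) == 0:
        return pairs.astype(int)
    keep = ~_blocked(positions[pairs[:, 0]], positions[pairs[:, 1]], barriers)
    return pairs[keep].astype(int)


def connected_components(edges: np.ndarray, n_points: int) -> np.ndarray:
    """Component label per point; isolated points are their own component."""
    if n_points == 0:
        return np.zeros(0, dtype=int)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    data = np.ones(len(edges))
    adj = csr_matrix((data, (edges[:, 0], edges[:, 1])), shape=(n_points, n_points))
    _, labels = _cc(adj, directed=False)
    return labels


def subgroup_table(
    records: pd.DataFrame,
    barriers: np.ndarray | None = None,
    radius: float = 5.0,
) -> pd.DataFrame:
    """Per-sighting subgroup sizes across all sessions.

    Flying birds are excluded (a flying bird is not foraging with anyone);
    records without coordinates are dropped with a warning.  Subgroups are
    computed independently per (date, session) — they never span scans.

    Returns the input's nonflying rows augmented with ``subgroup_id``
    (unique across the table) and ``subgroup_size``.  Each row carries the
    size of the subgroup containing that sighting, so sizes appear once per
    member (the size-biased, per-observation form used by the count
    models).
    """
    ground = records[records["flying"].astype(int) == 0].copy()
    missing = ground["x_m"].isna() | ground["y_m"].isna()
    if missing.any():
        logger.warning("%d nonflying records lack coordinates; excluded", int(missing.sum()))
        ground = ground[~missing]
    if ground.empty:
        out = records.iloc[0:0].copy()
        out["subgroup_id"] = pd.Series(dtype=int)
        out["subgroup_size"] = pd.Series(dtype=int)
        return out

    parts = []
    offset = 0
    for (date, session), grp in ground.groupby(["date", "session"], sort=True):
        pos = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        edges = build_association_graph(pos, barriers, radius)
        labels = connected_components(edges, len(pos))
        sizes = np.bincount(labels)
        grp = grp.copy()
        grp["subgroup_id"] = labels + offset
        grp["subgroup_size"] = sizes[labels]
        offset += labels.max() + 1 if len(labels) else 0
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)
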