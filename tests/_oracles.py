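"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library code paths they check: segment
intersection is done with orientation tests, component finding by boolean
transitive closure, and complete-linkage clustering by a direct O(n^4)
agglomeration over the raw distance matrix.
"""

from __future__ import annotations

import numpy as np


def _orient(a, b, c) -> float:
    return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])


def _on_open_segment(a, b, p) -> bool:
    """p strictly between a and b (collinearity assumed)."""
    if abs(_orient(a, b, p)) > 1e-12:
        return False
    t_num = (p[0] - a[0]) * (b[0] - a[0]) + (p[1] - a[1]) * (b[1] - a[1])
    t_den = (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2
    return 0 < t_num < t_den


def segments_block(p, q, r, s) -> bool:
    """Whether barrier r-s obstructs the open sight line p-q.

    Proper crossing (strict orientation sign change on both segments)
    blocks; touching an endpoint does not; collinear overlap of positive
    length blocks.
    """
    d1, d2 = _orient(r, s, p), _orient(r, s, q)
    d3, d4 = _orient(p, q, r), _orient(p, q, s)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and d1 != 0 and d2 != 0 and d3 != 0 and d4 != 0:
        return True
    # collinear overlap: both barrier endpoints on the sight line's carrier
    if abs(d1) < 1e-12 and abs(d2) < 1e-12:
        # overlap has positive length iff some interior point of one lies in the other
        mid_bar = ((r[0] + s[0]) / 2, (r[1] + s[1]) / 2)
        mid_line = ((p[0] + q[0]) / 2, (p[1] + q[1]) / 2)
        return _on_open_segment(p, q, mid_bar) or _on_open_segment(r, s, mid_line) or (
            _on_open_segment(p, q, r) and _on_open_segment(p, q, s)
        )
    return False


def brute_force_components(positions: np.ndarray, barriers: np.ndarray, radius: float) -> np.ndarray:
    """Component labels by pairwise checks + boolean transitive closure."""
    n = len(positions)
    adj = np.eye(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            p, q = positions[i], positions[j]
            if np.hypot(*(p - q)) > radius:
                continue
            if any(segments_block(p, q, b[:2], b[2:]) for b in barriers):
                continue
            adj[i, j] = adj[j, i] = True
    reach = adj.copy()
    while True:
        nxt = reach @ reach
        if (nxt == reach).all():
            break
        reach = nxt
    labels = np.full(n, -1)
    lab = 0
    for i in range(n):
        if labels[i] == -1:
            labels[reach[i]] = lab
            lab += 1
    return labels


def brute_force_complete_linkage(X: np.ndarray, k: int) -> np.ndarray:
    """Agglomerative complete linkage by direct set merging.

    At each step the pair of clusters with the smallest maximum
    inter-point distance merges; ties break on the lowest pair index of
    the current cluster list (the same rule scipy's linkage applies to its
    distance heap).
    """
    n = len(X)
    d = np.hypot(*(X[:, None, :] - X[None, :, :]).transpose(2, 0, 1)) if X.shape[1] == 2 else None
    if d is None:
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(-1))
    clusters = [[i] for i in range(n)]
    while len(clusters) > k:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = max(d[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[members] = lab
    return labels


def partitions_equal(a, b) -> bool:
    """Label-permutation-invariant partition comparison."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        return False
    return all(
        (set(np.flatnonzero(a == la)) in [set(np.flatnonzero(b == lb)) for lb in np.unique(b)])
        for la in np.unique(a)
    )
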