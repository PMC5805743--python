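"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from nhejsim.damage_generation import DSB, DamagePattern, Nucleus


@pytest.fixture()
def nucleus():
    return Nucleus()


def make_pattern(positions_nm, complexities=None, nucleus=None, track_ids=None):
    """Build a DamagePattern directly from coordinates (for toy scenarios)."""
    nucleus = nucleus or Nucleus()
    positions_nm = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    n = len(positions_nm)
    complexities = complexities if complexities is not None else [0] * n
    track_ids = track_ids if track_ids is not None else [0] * n
    dsbs = tuple(
        DSB(position_nm=tuple(p), complexity=int(c), track_id=int(t))
        for p, c, t in zip(positions_nm, complexities, track_ids)
    )
    return DamagePattern(nucleus=nucleus, exposure=None, dsbs=dsbs)


def brute_force_cluster_oracle(positions, strands, eps):
    """O(n²) union-find single-linkage clustering, independent of sklearn.

    Returns the set of DSB centroids (rounded) for clusters containing both
    strands, plus each cluster's member count.
    """
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    pos = np.asarray(positions, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if np.sqrt(((pos[i] - pos[j]) ** 2).sum()) <= eps:
                union(i, j)

    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    out = set()
    for members in clusters.values():
        s = {strands[i] for i in members}
        if s == {1, 2}:
            centroid = pos[members].mean(axis=0)
            out.add((tuple(np.round(centroid, 9)), len(members)))
    return out


@pytest.fixture()
def toy_two_dsb_pattern():
    """Two co-located DSBs: the canonical misrepair enumeration scenario."""
    return make_pattern([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
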