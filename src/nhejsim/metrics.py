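"""Descriptive statistics over damage patterns and repair outcomes.

Cluster density — the mean number of *other* DSBs within a fixed radius
(default 70 nm) of each DSB — is the central statistic: it summarises how
locally crowded the initial damage pattern is and predicts misrepair.
Also provided: the pairwise DSB separation probability density, end
displacement percentiles, and a standard-error summary across repeat runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ClusterDensityConfig",
    "RepeatSummary",
    "cluster_density",
    "separation_pdf",
    "displacement_percentile",
    "summarize_repeats",
    "radius_scan",
]


@dataclass(frozen=True)
class ClusterDensityConfig:
    radius: float = 70.0  # nm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class RepeatSummary:
    """Mean and standard error of the mean over repeat simulations."""

    mean: float
    standard_error: float
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.standard_error < 0:
            raise ValueError("standard_error must be non-negative")


def _positions(pattern) -> np.ndarray:
    """Accept a DamagePattern or a bare (n, 3) array of positions."""
    if hasattr(pattern, "positions"):
        return np.asarray(pattern.positions(), dtype=float)
    return np.atleast_2d(np.asarray(pattern, dtype=float))


def cluster_density(
    pattern, config: ClusterDensityConfig = ClusterDensityConfig()
) -> float:
    """Mean number of other DSBs within ``config.radius`` of each DSB.

    The focal DSB is excluded from its own neighbour count.  Patterns with
    fewer than two DSBs return 0.0 (a legitimately sparse low-dose pattern,
    not an error).
    """
    pos = _positions(pattern)
    n = len(pos)
    if n < 2:
        return 0.0
    tree = cKDTree(pos)
    # count_neighbors over all pairs, minus self-pairs
    counts = tree.query_ball_point(pos, r=config.radius, return_length=True)
    return float(np.mean(counts - 1))


def separation_pdf(pattern, bin_width: float = 50.0):
    """Probability density of pairwise DSB separations.

    Returns ``(bin_edges_nm, density)`` with the first bin covering
    ``[0, bin_width)``; the density integrates to 1 over all unordered
    pairs.  Fewer than two DSBs -> empty arrays.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pos = _positions(pattern)
    if len(pos) < 2:
        return np.array([0.0]), np.array([])
    diffs = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diffs**2).sum(-1))
    iu = np.triu_indices(len(pos), k=1)
    seps = dist[iu]
    n_bins = int(np.ceil((seps.max() + bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    density, edges = np.histogram(seps, bins=edges, density=True)
    return edges, density


def displacement_percentile(displacements, q: float) -> float:
    """``q``-th percentile (q in (0, 100]) of end displacement magnitudes.

    ``displacements`` is either a RepairOutcome (with an
    ``end_displacements`` array) or a 1-D array of magnitudes in nm.
    """
    if not 0 < q <= 100:
        raise ValueError("percentile q must lie in (0, 100]")
    if hasattr(displacements, "end_displacements"):
        displacements = displacements.end_displacements
    arr = np.asarray(displacements, dtype=float)
    if arr.size == 0:
        raise ValueError("no displacements recorded")
    return float(np.percentile(arr, q))


def summarize_repeats(values) -> RepeatSummary:
    """Mean and standard error of the mean (population sd / √n)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if arr.size == 1:
        return RepeatSummary(mean=float(arr[0]), standard_error=0.0, n_repeats=1)
    se = float(np.std(arr) / np.sqrt(arr.size))
    return RepeatSummary(mean=float(np.mean(arr)), standard_error=se,
                         n_repeats=int(arr.size))


def radius_scan(patterns, misrepair_fractions, radii_nm):
    """R² of the linear misrepair-vs-cluster-density fit at each radius.

    ``patterns`` is a list (one entry per grid cell) of lists of
    DamagePatterns; ``misrepair_fractions`` the matching per-cell misrepair
    fractions.  Used to probe how sharply the 70 nm choice is preferred.
    """
    fmis = np.asarray(misrepair_fractions, dtype=float)
    out = {}
    for radius in radii_nm:
        cfg = ClusterDensityConfig(radius=float(radius))
        cds = np.array(
            [np.mean([cluster_density(p, cfg) for p in cell]) for cell in patterns]
        )
        design = np.vander(cds, 2)
        coef, *_ = np.linalg.lstsq(design, fmis, rcond=None)
        pred = design @ coef
        ss_res = float(np.sum((fmis - pred) ** 2))
        ss_tot = float(np.sum((fmis - fmis.mean()) ** 2))
        out[float(radius)] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return out
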