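"""Nucleosome periodicity and map-to-map comparison.

The nucleosome repeat length (nucleosome + linker, ~165 bp in budding
yeast) shows up as the dominant period of the nucleosome-centre series;
a Fourier periodogram over 50-400 bp periods detects it, with power
normalized so that a pure sinusoid of amplitude A peaks at A^2.

Two maps are compared through the distances from each centre in one map
to the nearest centre in the other: a 1 bp histogram (moving-average
smoothed, window 10), its cumulative curve, the Euclidean distance
between cumulative curves, and a UPGMA tree over many maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .calling import NucleosomeMap

__all__ = [
    "Periodogram",
    "DistanceProfile",
    "UpgmaTree",
    "periodogram",
    "nearest_distances",
    "profile_distance",
    "upgma",
]


@dataclass
class Periodogram:
    periods: np.ndarray
    power: np.ndarray
    n_events: int

    @property
    def peak_period(self) -> float:
        return float(self.periods[int(np.argmax(self.power))])

    def save(self, path) -> None:
        pd.DataFrame({"period": self.periods, "power": self.power}).to_csv(
            path, sep="\t", index=False
        )


def periodogram(
    positions,
    region: tuple[int, int] = (0, 1000),
    period_range: tuple[int, int] = (50, 400),
    min_events: int = 10,
) -> Periodogram:
    """Fourier periodogram of a set of (relative) centre positions.

    Positions inside ``region`` are binned at 1 bp into an occurrence
    series, mean-subtracted, and the squared modulus of the discrete
    Fourier sum is evaluated on a 1 bp period grid.  Power is
    ``|2/N * sum x_n exp(-i 2 pi n / T)|^2`` so an injected sinusoid of
    amplitude A yields peak power A^2 (amplitude-squared units), and
    duplicating every event scales all powers by 4.
    """
    pos = np.asarray(positions, dtype=float)
    pos = pos[(pos >= region[0]) & (pos < region[1])]
    if pos.size < min_events:
        raise ValueError(f"only {pos.size} events in region; need >= {min_events}")
    n_bins = int(region[1] - region[0])
    counts = np.bincount((pos - region[0]).astype(int), minlength=n_bins).astype(float)
    x = counts - counts.mean()
    n = np.arange(n_bins)
    periods = np.arange(period_range[0], period_range[1] + 1, dtype=float)
    phases = np.exp(-2j * np.pi * np.outer(1.0 / periods, n))
    power = np.abs((2.0 / n_bins) * phases.dot(x)) ** 2
    return Periodogram(periods=periods, power=power, n_events=int(pos.size))


@dataclass
class DistanceProfile:
    """Nearest-centre distance distribution between two maps."""

    distances: np.ndarray
    histogram: np.ndarray  # 1 bp bins from 0
    smoothed: np.ndarray  # centered moving average, window 10, edges truncated
    cumulative: np.ndarray  # non-decreasing, ends at 1
    n_skipped: int = 0

    def cumulative_on_grid(self, max_d: int = 500) -> np.ndarray:
        """Cumulative frequency resampled onto the fixed 0..max_d bp
        grid (value 1 beyond the largest observed distance)."""
        d = np.sort(self.distances)
        grid = np.arange(max_d + 1)
        return np.searchsorted(d, grid, side="right") / len(d)

    def save(self, path) -> None:
        pd.DataFrame(
            {
                "distance": np.arange(len(self.histogram)),
                "count": self.histogram,
                "smoothed": self.smoothed,
                "cumulative": self.cumulative,
            }
        ).to_csv(path, sep="\t", index=False)


def _moving_average(v: np.ndarray, window: int = 10) -> np.ndarray:
    # centered, edge windows truncated to the available bins
    n = len(v)
    c = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(n)
    lo = np.maximum(idx - (window - 1) // 2, 0)
    hi = np.minimum(idx + window // 2 + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def nearest_distances(map_a: NucleosomeMap, map_b: NucleosomeMap,
                      window: int = 10) -> DistanceProfile:
    """Distance from each a-summit to the nearest b-summit on the same
    chromosome (directional: A -> B).  Summits on chromosomes absent from
    map_b are skipped and counted."""
    if len(map_a) == 0 or len(map_b) == 0:
        raise ValueError("both maps must be non-empty")
    dists: list[np.ndarray] = []
    skipped = 0
    b_chroms = set(map_b.chroms)
    for chrom in map_a.chroms:
        a = map_a.summits(chrom)
        if chrom not in b_chroms:
            skipped += len(a)
            continue
        b = np.sort(map_b.summits(chrom))
        idx = np.searchsorted(b, a)
        left = b[np.clip(idx - 1, 0, len(b) - 1)]
        right = b[np.clip(idx, 0, len(b) - 1)]
        dists.append(np.minimum(np.abs(a - left), np.abs(a - right)))
    if not dists:
        raise ValueError("maps share no chromosome")
    d = np.concatenate(dists)
    hist = np.bincount(d.astype(int))
    return DistanceProfile(
        distances=d.astype(float),
        histogram=hist.astype(float),
        smoothed=_moving_average(hist.astype(float), window),
        cumulative=np.cumsum(hist) / len(d),
        n_skipped=skipped,
    )


def profile_distance(p: DistanceProfile, q: DistanceProfile,
                     max_d: int = 500) -> float:
    """Euclidean distance between two cumulative nearest-distance curves,
    resampled onto the shared 0..max_d bp grid."""
    return float(np.linalg.norm(p.cumulative_on_grid(max_d) - q.cumulative_on_grid(max_d)))


@dataclass
class UpgmaTree:
    labels: list[str]
    merges: list[tuple[int, int, float]]  # (cluster_i, cluster_j, height)
    newick: str

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]


def upgma(distance_matrix, labels: list[str] | None = None) -> UpgmaTree:
    """Average-linkage (UPGMA) clustering of a symmetric distance matrix.

    Produces an ultrametric: merge heights are non-decreasing, leaves sit
    at height 0, and newick branch lengths are height differences.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("matrix must be non-negative")
    if not np.allclose(np.diag(D), 0, atol=1e-9):
        raise ValueError("diagonal must be zero")
    if labels is None:
        labels = [f"S{i}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count mismatch")
    Z = linkage(squareform(D, checks=False), method="average")
    heights = {i: 0.0 for i in range(n)}
    newicks = {i: labels[i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for k, (i, j, dist, _size) in enumerate(Z):
        i, j = int(i), int(j)
        h = float(dist) / 2.0  # ultrametric height of the new node
        node = n + k
        bi, bj = h - heights[i], h - heights[j]
        newicks[node] = f"({newicks[i]}:{bi:.6g},{newicks[j]}:{bj:.6g})"
        heights[node] = h
        merges.append((i, j, h))
    return UpgmaTree(labels=list(labels), merges=merges,
                     newick=newicks[2 * n - 2] + ";")
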