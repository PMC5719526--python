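"""Nucleosome calling: summits, occupancy, fuzziness, Poisson significance.

A nucleosome call is a local maximum of the dyad-density track with value
above a threshold; maxima closer than a merge distance collapse onto the
higher one.  Each call carries

* occupancy — the track height at the summit (how often the position is
  bound across the cell population),
* fuzziness — the positional spread (bp) of the dyads contributing to the
  call (how variable the position is across cells),
* p_value — a Poisson enrichment test of the summit-window signal mass
  against a background track over the same window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .tracks import DyadTrack

__all__ = [
    "NUCLEOSOME_LENGTH",
    "Nucleosome",
    "NucleosomeMap",
    "call_nucleosomes",
    "fuzziness",
    "poisson_sf",
    "significance",
]

NUCLEOSOME_LENGTH = 147
_HALF = NUCLEOSOME_LENGTH // 2  # 73


@dataclass
class Nucleosome:
    chrom: str
    summit: int
    occupancy: float
    fuzziness: float = float("nan")
    p_value: float = 1.0
    n_dyads: int = 0

    @property
    def start(self) -> int:
        return self.summit - _HALF

    @property
    def end(self) -> int:
        return self.summit + _HALF + 1


@dataclass
class NucleosomeMap:
    """A sample's full set of called nucleosomes, sorted by (chrom, summit)."""

    sample_label: str
    nucleosomes: list[Nucleosome]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nucleosomes.sort(key=lambda n: (n.chrom, n.summit))

    def __len__(self) -> int:
        return len(self.nucleosomes)

    def summits(self, chrom: str | None = None) -> np.ndarray:
        nucs = self.nucleosomes if chrom is None else [
            n for n in self.nucleosomes if n.chrom == chrom
        ]
        return np.asarray([n.summit for n in nucs], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return sorted({n.chrom for n in self.nucleosomes})

    def significant(self, alpha: float = 0.01) -> "NucleosomeMap":
        """Filter view at p < alpha."""
        return NucleosomeMap(
            self.sample_label,
            [n for n in self.nucleosomes if n.p_value < alpha],
            dict(self.params),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [n.chrom for n in self.nucleosomes],
                "start": [n.start for n in self.nucleosomes],
                "end": [n.end for n in self.nucleosomes],
                "name": [f"nuc{i}" for i in range(len(self.nucleosomes))],
                "occupancy": [n.occupancy for n in self.nucleosomes],
                "strand": ["."] * len(self.nucleosomes),
                "summit": [n.summit for n in self.nucleosomes],
                "fuzziness": [n.fuzziness for n in self.nucleosomes],
                "p_value": [n.p_value for n in self.nucleosomes],
            }
        )

    def save(self, path) -> None:
        """BED6+3 table: chrom start end name occupancy strand summit
        fuzziness p_value."""
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path, sample_label: str | None = None) -> "NucleosomeMap":
        df = pd.read_csv(path, sep="\t")
        nucs = [
            Nucleosome(
                chrom=str(r.chrom),
                summit=int(r.summit),
                occupancy=float(r.occupancy),
                fuzziness=float(r.fuzziness),
                p_value=float(r.p_value),
            )
            for r in df.itertuples()
        ]
        return cls(sample_label or str(path), nucs)


def fuzziness(summit: int, dyad_positions) -> float:
    """Population standard deviation (bp) of the dyad positions
    contributing to a nucleosome."""
    pos = np.asarray(dyad_positions, dtype=float)
    if pos.size == 0:
        raise ValueError("no dyads in window")
    return float(pos.std(ddof=0))


def _local_maxima(v: np.ndarray, min_height: float) -> tuple[np.ndarray, np.ndarray]:
    """Positions (leftmost on plateaus) and heights of local maxima >= min_height."""
    peaks, props = _signal.find_peaks(v, height=min_height, plateau_size=1)
    return props["left_edges"], props["peak_heights"]


def _mean_shift(dy: np.ndarray, start: int, window: int, max_iter: int = 5) -> int:
    """Iterate summit <- round(mean of dyads within +/- window) to a
    fixed point (the dyad-cloud centroid the start belongs to)."""
    p = int(start)
    for _ in range(max_iter):
        lo = np.searchsorted(dy, p - window, side="left")
        hi = np.searchsorted(dy, p + window + 1, side="left")
        if hi <= lo:
            return p
        q = int(round(float(dy[lo:hi].mean())))
        if q == p:
            break
        p = q
    return p


def call_nucleosomes(
    track: DyadTrack,
    min_height: float | None = None,
    merge_distance: int = 100,
    dyad_positions: dict[str, np.ndarray] | None = None,
    fuzziness_window: int | None = None,
    refine_summits: bool = True,
    refine_window: int = 80,
) -> NucleosomeMap:
    """Call nucleosomes on a (raw or corrected) density track.

    Candidate summits are local maxima with height >= ``min_height``
    (default: 2x the genome-wide mean track value); maxima closer than
    ``merge_distance`` merge, keeping the higher (ties: leftmost), so
    summits in the returned map are always >= ``merge_distance`` apart.

    When the raw ``dyad_positions`` that built the track are supplied:

    * with ``refine_summits`` each candidate summit is moved to the
      centroid of its dyad cloud by mean-shift iteration over a
      ``refine_window`` bp half-window (the centroid is a far less noisy
      centre estimate than the smoothed-density mode at low coverage),
      and refined summits are re-merged;
    * each call's fuzziness is the population sd of the dyads within
      ``fuzziness_window`` bp of its summit (default: ``merge_distance``,
      i.e. the call's exclusive territory).

    Without dyads, summits stay at the density maxima and fuzziness
    is NaN.
    """
    if min_height is None:
        min_height = 2.0 * track.mean_value
    if min_height <= 0:
        raise ValueError("min_height must be > 0")
    if fuzziness_window is None:
        fuzziness_window = merge_distance
    nucs: list[Nucleosome] = []
    for chrom, v in track.values.items():
        pos, heights = _local_maxima(v, min_height)
        if len(pos) == 0:
            continue
        # greedy merge: accept by descending height, leftmost on ties
        order = np.lexsort((pos, -heights))
        accepted: list[int] = []
        for i in order:
            p = pos[i]
            if all(abs(p - q) >= merge_distance for q in accepted):
                accepted.append(int(p))
        dy = None
        if dyad_positions is not None:
            dy = np.sort(np.asarray(dyad_positions.get(chrom, []), dtype=np.int64))
        if dy is not None and dy.size and refine_summits:
            refined = sorted(
                {min(max(_mean_shift(dy, p, refine_window), 0), len(v) - 1)
                 for p in accepted}
            )
            accepted = []
            for p in sorted(refined, key=lambda q: (-v[q], q)):
                if all(abs(p - q) >= merge_distance for q in accepted):
                    accepted.append(int(p))
        for p in accepted:
            fz = float("nan")
            n_dy = 0
            if dy is not None and dy.size:
                lo = np.searchsorted(dy, p - fuzziness_window, side="left")
                hi = np.searchsorted(dy, p + fuzziness_window + 1, side="left")
                n_dy = int(hi - lo)
                if n_dy > 0:
                    fz = fuzziness(p, dy[lo:hi])
            nucs.append(
                Nucleosome(chrom=chrom, summit=p, occupancy=float(v[p]),
                           fuzziness=fz, n_dyads=n_dy)
            )
    return NucleosomeMap(
        sample_label=track.sample_label,
        nucleosomes=nucs,
        params={
            "min_height": float(min_height),
            "merge_distance": int(merge_distance),
            "bandwidth": float(track.smoothing_bandwidth),
            "fuzziness_window": int(fuzziness_window),
            "refine_summits": bool(refine_summits),
            "refine_window": int(refine_window),
        },
    )


def poisson_sf(count: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= count) for X ~ Poisson(lam)."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if count <= 0:
        return 1.0
    return float(stats.poisson.sf(count - 1, lam))


def significance(
    nmap: NucleosomeMap,
    source: DyadTrack,
    background: DyadTrack,
    lam_floor: float = 0.1,
) -> NucleosomeMap:
    """Attach a Poisson p-value to every call.

    For each nucleosome, the signal mass of the source track over its
    147 bp extent (rounded to an integer count) is tested against the
    background-track mass over the same window (clamped below at
    ``lam_floor``).  No multiple-testing correction — a p < 0.01 filter
    view is available via :meth:`NucleosomeMap.significant`.
    """
    out = []
    for n in nmap.nucleosomes:
        sv = source.values[n.chrom]
        bv = background.values[n.chrom]
        lo, hi = max(n.start, 0), min(n.end, len(sv))
        count = int(round(float(sv[lo:hi].sum())))
        lam = max(float(bv[lo:hi].sum()), lam_floor)
        out.append(replace(n, p_value=poisson_sf(count, lam)))
    return NucleosomeMap(nmap.sample_label, out, dict(nmap.params))
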