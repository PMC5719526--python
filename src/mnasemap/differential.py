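"""Comparison of two nucleosome maps or tracks.

Covers the condition-vs-condition analyses: one-to-one matching of
nucleosomes across maps with per-pair occupancy and fuzziness changes,
signed log-p difference curves between two tracks, 2D occupancy-vs-
fuzziness kernel-density heat maps, Pearson correlation, and the small
battery of category-level statistical tests (KS, t, Mann-Whitney,
hypergeometric enrichment, Fisher's exact).

Named fuzziness thresholds: nucleosomes scoring above
``HIGH_FUZZINESS_THRESHOLD`` (40) count as highly fuzzy; below
``LOW_FUZZINESS_THRESHOLD`` (30) as well positioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .calling import Nucleosome, NucleosomeMap, poisson_sf

__all__ = [
    "HIGH_FUZZINESS_THRESHOLD",
    "LOW_FUZZINESS_THRESHOLD",
    "NucleosomePair",
    "Density2D",
    "match_nucleosomes",
    "signed_logp_curve",
    "density2d",
    "pearson",
    "ks_test",
    "t_test",
    "mannwhitney_test",
    "hypergeom_enrichment",
    "fisher_exact_test",
    "category_tests",
]

HIGH_FUZZINESS_THRESHOLD = 40.0
LOW_FUZZINESS_THRESHOLD = 30.0


@dataclass
class NucleosomePair:
    a: Nucleosome
    b: Nucleosome

    @property
    def summit_offset(self) -> int:
        return self.b.summit - self.a.summit

    @property
    def delta_occupancy(self) -> float:
        return self.b.occupancy - self.a.occupancy

    @property
    def delta_fuzziness(self) -> float:
        return self.b.fuzziness - self.a.fuzziness


def match_nucleosomes(
    map_a: NucleosomeMap, map_b: NucleosomeMap, max_offset: int = 74
) -> tuple[list[NucleosomePair], list[Nucleosome], list[Nucleosome]]:
    """Pair each a-nucleosome with the nearest b-summit within
    ``max_offset`` bp (half a nucleosome by default).

    Pairing is one-to-one, greedy by ascending distance; returns
    (pairs, unmatched_a, unmatched_b).
    """
    pairs: list[NucleosomePair] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    a_by_chrom: dict[str, list[tuple[int, Nucleosome]]] = {}
    b_by_chrom: dict[str, list[tuple[int, Nucleosome]]] = {}
    for i, n in enumerate(map_a.nucleosomes):
        a_by_chrom.setdefault(n.chrom, []).append((i, n))
    for j, n in enumerate(map_b.nucleosomes):
        b_by_chrom.setdefault(n.chrom, []).append((j, n))
    candidates: list[tuple[int, int, int]] = []  # (|offset|, a_idx, b_idx)
    for chrom, a_list in a_by_chrom.items():
        b_list = b_by_chrom.get(chrom, [])
        if not b_list:
            continue
        b_summits = np.asarray([n.summit for _, n in b_list])
        for i, na in a_list:
            k = np.searchsorted(b_summits, na.summit)
            for kk in range(max(0, k - 2), min(len(b_list), k + 2)):
                d = abs(b_list[kk][1].summit - na.summit)
                if d <= max_offset:
                    candidates.append((d, i, b_list[kk][0]))
    candidates.sort()
    a_nucs, b_nucs = map_a.nucleosomes, map_b.nucleosomes
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(NucleosomePair(a_nucs[i], b_nucs[j]))
    unmatched_a = [n for i, n in enumerate(a_nucs) if i not in used_a]
    unmatched_b = [n for j, n in enumerate(b_nucs) if j not in used_b]
    return pairs, unmatched_a, unmatched_b


def pairs_to_dataframe(pairs: list[NucleosomePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.a.chrom for p in pairs],
            "summit_a": [p.a.summit for p in pairs],
            "summit_b": [p.b.summit for p in pairs],
            "summit_offset": [p.summit_offset for p in pairs],
            "delta_occupancy": [p.delta_occupancy for p in pairs],
            "delta_fuzziness": [p.delta_fuzziness for p in pairs],
        }
    )


def signed_logp_curve(raw, corrected, lam_floor: float = 0.1,
                      base: float = 10.0) -> np.ndarray:
    """Signed per-bin significance of the difference between two signals.

    Per bin a Poisson test of the larger value against the smaller
    (floored at ``lam_floor``); the plotted value is -log(p) where
    raw > corrected and +log(p) (a negative number) where raw <
    corrected, 0 at equality.  Antisymmetric under swapping the inputs.
    """
    r = np.asarray(raw, dtype=float)
    c = np.asarray(corrected, dtype=float)
    if r.shape != c.shape:
        raise ValueError("vectors differ in length")
    if np.any(r < 0) or np.any(c < 0):
        raise ValueError("values must be non-negative")
    out = np.zeros_like(r)
    logbase = np.log(base)
    for i in range(len(r)):
        if r[i] == c[i]:
            continue
        hi, lo = (r[i], c[i]) if r[i] > c[i] else (c[i], r[i])
        p = poisson_sf(int(round(hi)), max(lo, lam_floor))
        logp = np.log(p) / logbase
        out[i] = -logp if r[i] > c[i] else logp
    return out


@dataclass
class Density2D:
    """Gaussian kernel density of scatter points on a 100 x 100 grid.

    ``radius`` is the kernel truncation radius in grid cells, with the
    Gaussian's sigma = radius / 3 (so the kernel's support covers
    3 sigma).
    """

    grid: np.ndarray
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    kernel: str = "gaussian"
    radius: int = 30

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# x_range\t{self.x_range[0]:.8g}\t{self.x_range[1]:.8g}\n")
            fh.write(f"# y_range\t{self.y_range[0]:.8g}\t{self.y_range[1]:.8g}\n")
            np.savetxt(fh, self.grid, delimiter="\t", fmt="%.8g")


def density2d(points, n_bins: int = 100, radius: int = 30,
              pad_fraction: float = 0.05) -> Density2D:
    """2D Gaussian kernel density of (delta_fuzziness, delta_occupancy)
    points on an ``n_bins`` x ``n_bins`` grid spanning the data range
    padded by ``pad_fraction`` on each side."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("no points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    x, y = pts[:, 0], pts[:, 1]

    def _range(v: np.ndarray) -> tuple[float, float]:
        lo, hi = float(v.min()), float(v.max())
        span = hi - lo
        pad = pad_fraction * span if span > 0 else 0.5
        return lo - pad, hi + pad

    xr, yr = _range(x), _range(y)
    hist, _, _ = np.histogram2d(x, y, bins=n_bins, range=[xr, yr])
    sigma = radius / 3.0
    off = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (off / sigma) ** 2)
    kernel = np.outer(k1, k1)
    kernel /= kernel.sum()
    grid = ndimage.convolve(hist, kernel, mode="constant", cval=0.0)
    return Density2D(grid=grid, x_range=xr, y_range=yr, radius=radius)


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with the two-sided p-value from the t
    transform; (nan, nan) when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# --- category-level tests -------------------------------------------------

def ks_test(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (exact p on small samples)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    res = stats.ks_2samp(a, b, method="exact" if max(a.size, b.size) <= 50 else "auto")
    if res.statistic == 0.0:  # exact path degenerates; p is exactly 1
        return 0.0, 1.0
    return float(res.statistic), float(res.pvalue)


def t_test(a, b) -> tuple[float, float]:
    """Two-sample Student's t test (equal variances)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_test(a, b) -> tuple[float, float]:
    """Wilcoxon-Mann-Whitney U test, two-sided (exact p on small
    tie-free samples)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def hypergeom_enrichment(population: int, successes: int, draws: int,
                         observed: int) -> float:
    """Upper-tail hypergeometric enrichment p-value P(X >= observed)."""
    if draws > population or successes > population:
        raise ValueError("inconsistent hypergeometric parameters")
    return float(stats.hypergeom.sf(observed - 1, population, successes, draws))


def fisher_exact_test(table) -> tuple[float, float]:
    """Fisher's exact test (two-sided) on a 2x2 count table."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


def category_tests(results: dict) -> pd.DataFrame:
    """Run a keyed batch of tests and return a tidy report.

    ``results`` maps a label to a tuple ``(kind, *args)`` where kind is
    one of ks/t/mannwhitney/hypergeom/fisher and args match the
    corresponding function.
    """
    dispatch = {
        "ks": lambda *a: ks_test(*a),
        "t": lambda *a: t_test(*a),
        "mannwhitney": lambda *a: mannwhitney_test(*a),
        "hypergeom": lambda *a: (float("nan"), hypergeom_enrichment(*a)),
        "fisher": lambda *a: fisher_exact_test(*a),
    }
    rows = []
    for label, (kind, *args) in results.items():
        stat, p = dispatch[kind](*args)
        rows.append({"label": label, "test": kind, "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)
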