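"""Naked-DNA sequence-bias correction.

MNase cuts DNA with a sequence preference, so a partial chromatin digest
carries peaks that reflect the enzyme rather than nucleosomes.  Digesting
protein-free (naked) DNA with the same enzyme measures that preference
directly; subtracting the depth-normalized naked track from the chromatin
track removes it.  The qPCR-style ratio normalization, z-scoring and a
GC-content diagnostic for the naked signal live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .tracks import DyadTrack, ReadSet

__all__ = [
    "CorrectedTrack",
    "GcDiagnostic",
    "subtract_background",
    "ratio_normalize",
    "zscore",
    "gc_fraction",
    "gc_diagnostic",
]


@dataclass
class CorrectedTrack(DyadTrack):
    background_label: str = ""
    floor_applied: bool = True


def _check_compatible(a: DyadTrack, b: DyadTrack) -> None:
    if a.genome_lengths != b.genome_lengths:
        raise ValueError("tracks cover different chromosomes/lengths")


def subtract_background(
    chromatin: DyadTrack, naked: DyadTrack, floor_at_zero: bool = True
) -> CorrectedTrack:
    """Pointwise chromatin - naked; both tracks should already be
    depth-normalized (see :func:`mnasemap.tracks.normalize_depth`).

    With ``floor_at_zero`` the difference is clipped at 0, which downstream
    peak calling requires; the unfloored signed difference is what the
    signed log-p curves consume.
    """
    _check_compatible(chromatin, naked)
    values = {}
    for chrom, v in chromatin.values.items():
        diff = v - naked.values[chrom]
        values[chrom] = np.maximum(diff, 0.0) if floor_at_zero else diff
    return CorrectedTrack(
        sample_label=f"{chromatin.sample_label}-corrected",
        values=values,
        smoothing_bandwidth=chromatin.smoothing_bandwidth,
        depth_scale=chromatin.depth_scale,
        background_label=naked.sample_label,
        floor_applied=floor_at_zero,
    )


def ratio_normalize(
    chromatin_values, naked_values, pseudo: float = 0.0
) -> np.ma.MaskedArray:
    """Divide chromatin signal by naked signal plus a pseudocount
    (the qPCR-style normalization).

    With ``pseudo == 0`` a zero denominator yields a masked value; the
    mask count is available as ``result.mask.sum()``.
    """
    c = np.asarray(chromatin_values, dtype=float)
    n = np.asarray(naked_values, dtype=float)
    if c.shape != n.shape:
        raise ValueError("vectors differ in length")
    if np.any(n < 0):
        raise ValueError("naked values must be >= 0")
    denom = n + pseudo
    mask = denom == 0
    out = np.divide(c, denom, out=np.zeros_like(c), where=~mask)
    return np.ma.MaskedArray(out, mask=mask)


def zscore(values) -> np.ndarray:
    """Standardize to mean 0 and sample (ddof=1) standard deviation 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (v - v.mean()) / sd


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    n = len(s)
    if n == 0:
        return 0.0
    return (s.count("G") + s.count("C")) / n


@dataclass
class GcDiagnostic:
    """Fragment-level GC vs signal relationship in a (naked) sample.

    ``gc`` holds per-fragment GC fraction minus the genome-wide GC
    fraction; ``log_signal`` the log10 mean track signal over the
    fragment (plus pseudocount).  A positive ``pearson_r`` reproduces the
    expectation that GC-rich, MNase-resistant fragments are
    overrepresented in the naked digest.
    """

    gc: np.ndarray
    log_signal: np.ndarray
    pearson_r: float
    p_value: float
    n_skipped: int = 0

    @property
    def defined(self) -> bool:
        return np.isfinite(self.pearson_r)


def gc_diagnostic(
    fragments: ReadSet,
    genome: dict[str, str],
    signal: DyadTrack,
    pseudo: float = 0.5,
) -> GcDiagnostic:
    """Correlate fragment GC content (genome-average-subtracted) with
    log10 fragment signal."""
    total_gc = sum(
        seq.upper().count("G") + seq.upper().count("C") for seq in genome.values()
    )
    total_len = sum(len(s) for s in genome.values())
    genome_gc = total_gc / total_len
    gcs, sigs = [], []
    skipped = 0
    for r in fragments.reads:
        if r.chrom not in genome or r.end > len(genome[r.chrom]):
            skipped += 1
            continue
        gcs.append(gc_fraction(genome[r.chrom][r.start : r.end]) - genome_gc)
        sigs.append(np.log10(signal.values[r.chrom][r.start : r.end].mean() + pseudo))
    gcs_a = np.asarray(gcs)
    sigs_a = np.asarray(sigs)
    if len(gcs_a) < 3 or np.ptp(gcs_a) == 0 or np.ptp(sigs_a) == 0:
        r_val, p_val = float("nan"), float("nan")
    else:
        res = stats.pearsonr(gcs_a, sigs_a)
        r_val, p_val = float(res.statistic), float(res.pvalue)
    return GcDiagnostic(gcs_a, sigs_a, r_val, p_val, n_skipped=skipped)
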