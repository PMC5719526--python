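"""Read handling and dyad-density tracks.

Aligned single-end reads come in as BED intervals; clonal duplicates are
removed, each read is reduced to the dyad (central base pair) of the
nucleosome it derives from, and the dyads are accumulated into a smoothed,
depth-normalisable 1 bp-resolution density track per chromosome — the
central signal object of the pipeline.

All coordinates are 0-based half-open internally; BED comes in,
bedGraph/wiggle go out.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "ReadSet",
    "DyadTrack",
    "read_bed",
    "read_chrom_sizes",
    "deduplicate",
    "dyads",
    "smooth",
    "normalize_depth",
    "write_track",
    "read_bedgraph",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ReadSet:
    """A labelled collection of aligned reads plus the chromosome sizes."""

    sample_label: str
    reads: list[GenomicInterval]
    genome_lengths: dict[str, int]
    n_out_of_bounds: int = 0
    n_unknown_chrom: int = 0

    def __len__(self) -> int:
        return len(self.reads)

    def sorted(self) -> "ReadSet":
        return replace(self, reads=sorted(self.reads))

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in enumerate(self.reads):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column chrom<TAB>length table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, length = line.split("\t")[:2]
            sizes[chrom] = int(length)
    return sizes


def read_bed(
    path,
    genome_lengths: dict[str, int],
    sample_label: str | None = None,
    on_unknown_chrom: str = "skip",
) -> ReadSet:
    """Parse a 3- or 6-column BED file into a :class:`ReadSet`.

    Reads extending past chromosome bounds are rejected (counted in
    ``n_out_of_bounds``).  ``on_unknown_chrom`` is either ``"skip"``
    (count and drop) or ``"fail"`` (raise).

    Raises
    ------
    ValueError
        For malformed lines (fewer than 3 fields, non-integer or
        inverted coordinates), with the offending line number.
    """
    if on_unknown_chrom not in ("skip", "fail"):
        raise ValueError("on_unknown_chrom must be 'skip' or 'fail'")
    reads: list[GenomicInterval] = []
    n_oob = 0
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValueError(f"start >= end at line {lineno}")
            if start < 0:
                raise ValueError(f"negative start at line {lineno}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            if chrom not in genome_lengths:
                if on_unknown_chrom == "fail":
                    raise ValueError(f"line {lineno}: unknown chromosome {chrom!r}")
                n_unknown += 1
                continue
            if end > genome_lengths[chrom]:
                n_oob += 1
                continue
            reads.append(GenomicInterval(chrom, start, end, strand))
    return ReadSet(
        sample_label=sample_label or str(path),
        reads=reads,
        genome_lengths=dict(genome_lengths),
        n_out_of_bounds=n_oob,
        n_unknown_chrom=n_unknown,
    )


def deduplicate(readset: ReadSet, max_copies: int = 1) -> ReadSet:
    """Clonally cut the read set: cap identical (chrom, start, end, strand)
    tuples at ``max_copies``, preserving the order of retained reads.

    Removes PCR amplification bias; idempotent by construction.
    """
    if max_copies < 1:
        raise ValueError("max_copies must be >= 1")
    seen: Counter = Counter()
    kept = []
    for r in readset.reads:
        key = (r.chrom, r.start, r.end, r.strand)
        if seen[key] < max_copies:
            kept.append(r)
            seen[key] += 1
    return replace(readset, reads=kept)


def dyads(readset: ReadSet, fragment_length: int = 147) -> dict[str, np.ndarray]:
    """Assign each read the dyad of the nucleosome-sized fragment it marks.

    A single-end read tags one end of an (assumed) ``fragment_length``
    fragment, so the dyad sits ``fragment_length // 2`` bp interior to the
    5' end: ``start + L//2`` on +, ``(end - 1) - L//2`` on -.  Unstranded
    reads use their own midpoint.  Dyads are clipped to chromosome bounds.
    """
    half = fragment_length // 2
    out: dict[str, list[int]] = {c: [] for c in readset.genome_lengths}
    for r in readset.reads:
        if r.strand == "+":
            d = r.start + half
        elif r.strand == "-":
            d = (r.end - 1) - half
        else:
            d = (r.start + r.end - 1) // 2
        L = readset.genome_lengths[r.chrom]
        out[r.chrom].append(min(max(d, 0), L - 1))
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


@dataclass
class DyadTrack:
    """Per-chromosome 1 bp-resolution dyad-density vectors."""

    sample_label: str
    values: dict[str, np.ndarray]
    smoothing_bandwidth: float = 0.0
    depth_scale: float = 1.0

    @property
    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    @property
    def mean_value(self) -> float:
        n = sum(len(v) for v in self.values.values())
        return self.total_mass / n if n else 0.0

    def validate(self) -> None:
        for c, v in self.values.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values on {c}")

    def scaled(self, factor: float) -> "DyadTrack":
        return replace(
            self,
            values={c: v * factor for c, v in self.values.items()},
            depth_scale=self.depth_scale * factor,
        )


def _gaussian_kernel(bandwidth: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * bandwidth))
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / bandwidth) ** 2)
    return k / k.sum()  # renormalised after +/-4 sigma truncation


def smooth(
    dyad_positions: dict[str, np.ndarray],
    bandwidth: float,
    genome_lengths: dict[str, int],
    sample_label: str = "track",
) -> DyadTrack:
    """Build a density track where each dyad contributes a unit-mass
    Gaussian of standard deviation ``bandwidth`` (truncated at 4 sigma).

    Kernel mass falling outside chromosome bounds is reflected back onto
    the boundary bins, so total mass equals the dyad count exactly.
    ``bandwidth == 0`` yields the raw count vector.
    """
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    values: dict[str, np.ndarray] = {}
    for chrom, L in genome_lengths.items():
        pos = dyad_positions.get(chrom, np.empty(0, dtype=np.int64))
        counts = np.bincount(np.asarray(pos, dtype=np.int64), minlength=L).astype(float)
        if bandwidth == 0 or len(pos) == 0:
            values[chrom] = counts
            continue
        kernel = _gaussian_kernel(bandwidth)
        radius = (len(kernel) - 1) // 2
        full = np.convolve(counts, kernel)
        core = full[radius : radius + L].copy()
        if radius > 0:
            left = full[:radius]
            core[: len(left)] += left[::-1]
            right = full[radius + L :]
            core[L - len(right) :] += right[::-1]
        values[chrom] = core
    return DyadTrack(sample_label=sample_label, values=values,
                     smoothing_bandwidth=float(bandwidth))


def normalize_depth(
    track_a: DyadTrack, track_b: DyadTrack, mode: str = "geometric"
) -> tuple[DyadTrack, DyadTrack]:
    """Scale both tracks to a common total mass.

    ``geometric`` (default) matches both to the geometric mean of the two
    input masses — symmetric between samples; ``per_million`` scales each
    to 1e6 total mass.
    """
    ma, mb = track_a.total_mass, track_b.total_mass
    if ma <= 0 or mb <= 0:
        raise ValueError("cannot depth-normalize a zero-mass track")
    if mode == "geometric":
        target = float(np.sqrt(ma * mb))
    elif mode == "per_million":
        target = 1e6
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return track_a.scaled(target / ma), track_b.scaled(target / mb)


def write_track(track: DyadTrack, path, fmt: str = "bedGraph") -> None:
    """Write a track as bedGraph (runs of equal value merged, zeros
    omitted) or fixed-step wiggle."""
    if fmt not in ("bedGraph", "wiggle"):
        raise ValueError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            if fmt == "wiggle":
                fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
                fh.writelines(f"{x:.8g}\n" for x in v)
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.8g}\n")


def read_bedgraph(path, genome_lengths: dict[str, int],
                  sample_label: str | None = None) -> DyadTrack:
    """Read a bedGraph written by :func:`write_track` back into a track."""
    values = {c: np.zeros(L) for c, L in genome_lengths.items()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, val = line.split("\t")[:4]
            values[chrom][int(s) : int(e)] = float(val)
    return DyadTrack(sample_label=sample_label or str(path), values=values)
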