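"""Gene-anchored (metagene) averaging and gene-relative classification.

Genes are scaled to a common pseudo-length (1000 bins by default) with
unscaled 500 bp flanks, aligned to either the TSS or the pAS, and the
per-bin mean of a signal over any gene stratum (TATA class, tag, or
transcription-rate quartile) gives the metagene profile.  Related
gene-relative utilities: classifying nucleosomes into promoter / gene
body / other, positional mean-fuzziness curves, and position-dependent
nucleotide-frequency profiles with promoter/body region t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import NucleosomeMap
from .differential import t_test
from .tracks import DyadTrack

__all__ = [
    "GeneModel",
    "MetageneProfile",
    "load_genes",
    "save_genes",
    "extract_gene_signal",
    "metagene",
    "classify_nucleosomes",
    "fuzziness_profile",
    "nucleotide_profile",
    "pas_isolated_genes",
]

NUCLEOTIDES = "ACGT"


@dataclass
class GeneModel:
    """One annotated gene: anchors, core-promoter class, category tags and
    transcription rate.  For + genes tss < pas; for - genes tss > pas."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    pas: int
    promoter_class: str = "unknown"  # TATA | TATA-like | unknown
    tags: set[str] = field(default_factory=set)
    transcription_rate: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.pas:
            raise ValueError(f"{self.gene_id}: + gene requires tss < pas")
        if self.strand == "-" and not self.tss > self.pas:
            raise ValueError(f"{self.gene_id}: - gene requires tss > pas")

    @property
    def start(self) -> int:
        return min(self.tss, self.pas)

    @property
    def end(self) -> int:
        return max(self.tss, self.pas)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def relative_position(self, pos: int) -> int:
        """Genomic offset of ``pos`` from the TSS in transcription
        orientation (positive = downstream)."""
        return pos - self.tss if self.strand == "+" else self.tss - pos


def save_genes(genes: list[GeneModel], path) -> None:
    pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "pas": [g.pas for g in genes],
            "promoter_class": [g.promoter_class for g in genes],
            "tags": [",".join(sorted(g.tags)) for g in genes],
            "transcription_rate": [
                g.transcription_rate if g.transcription_rate is not None else np.nan
                for g in genes
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def load_genes(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        rate = None if pd.isna(r.transcription_rate) else float(r.transcription_rate)
        tags = set() if pd.isna(r.tags) or not str(r.tags) else set(str(r.tags).split(","))
        genes.append(
            GeneModel(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                tss=int(r.tss),
                pas=int(r.pas),
                promoter_class=str(r.promoter_class),
                tags=tags,
                transcription_rate=rate,
            )
        )
    return genes


@dataclass
class MetageneProfile:
    """Anchor-aligned mean signal: strictly increasing relative axis,
    per-bin means, and the number of genes averaged."""

    axis: np.ndarray
    values: np.ndarray
    n_genes: int
    sample_label: str = ""
    anchor: str = "TSS"
    n_per_bin: np.ndarray | None = None

    def save(self, path) -> None:
        df = pd.DataFrame({"position": self.axis, "mean": self.values})
        if self.n_per_bin is not None:
            df["n"] = self.n_per_bin
        df.to_csv(path, sep="\t", index=False)


def _gene_positions(gene: GeneModel, upstream: int, body_bins: int,
                    downstream: int) -> np.ndarray:
    """Fractional genomic coordinates of every profile bin, in
    transcription orientation: unscaled upstream flank, body scaled to
    ``body_bins`` samples, unscaled downstream flank."""
    sgn = 1 if gene.strand == "+" else -1
    up = gene.tss + sgn * np.arange(-upstream, 0)
    L = gene.length
    body = gene.tss + sgn * np.arange(body_bins) * (L - 1) / (body_bins - 1)
    down = gene.pas + sgn * np.arange(1, downstream + 1)
    return np.concatenate([up, body, down])


def extract_gene_signal(
    track: DyadTrack,
    gene: GeneModel,
    upstream: int = 500,
    body_bins: int = 1000,
    downstream: int = 500,
    body_min: int = 200,
) -> np.ndarray:
    """Per-gene signal vector: 1 bp upstream flank, linearly interpolated
    scaled body, 1 bp downstream flank, all in transcription orientation.
    Bins falling outside the chromosome are NaN-masked.

    Raises ``ValueError`` for genes with body shorter than ``body_min``.
    """
    if gene.length < body_min:
        raise ValueError(f"{gene.gene_id}: body {gene.length} < body_min {body_min}")
    v = track.values[gene.chrom]
    L = len(v)
    coords = _gene_positions(gene, upstream, body_bins, downstream)
    out = np.interp(coords, np.arange(L), v, left=np.nan, right=np.nan)
    out[(coords < 0) | (coords > L - 1)] = np.nan
    return out


def _profile_axis(upstream: int, body_bins: int, downstream: int) -> np.ndarray:
    # pseudo-bp axis: upstream -500..-1, body samples spread over 0..1000,
    # downstream 1000+1..1000+500
    body = np.linspace(0.0, 1000.0, body_bins)
    return np.concatenate(
        [np.arange(-upstream, 0, dtype=float), body,
         1000.0 + np.arange(1, downstream + 1, dtype=float)]
    )


def transcription_quartiles(genes: list[GeneModel]) -> dict[str, list[GeneModel]]:
    """Partition the genes with a transcription rate into quartiles
    Q1 (highest) .. Q4 (lowest); sizes differ by at most one."""
    rated = [g for g in genes if g.transcription_rate is not None]
    order = sorted(rated, key=lambda g: (-g.transcription_rate, g.gene_id))
    chunks = np.array_split(np.arange(len(order)), 4)
    return {f"Q{i + 1}": [order[j] for j in idx] for i, idx in enumerate(chunks)}


def _strata(genes: list[GeneModel], stratify_by: str | None) -> dict[str, list[GeneModel]]:
    if stratify_by is None:
        return {"all": list(genes)}
    if stratify_by == "promoter_class":
        out: dict[str, list[GeneModel]] = {}
        for g in genes:
            out.setdefault(g.promoter_class, []).append(g)
        return out
    if stratify_by == "transcription_quartile":
        return transcription_quartiles(genes)
    if stratify_by.startswith("tag:"):
        tag = stratify_by[4:]
        return {
            tag: [g for g in genes if tag in g.tags],
            f"not_{tag}": [g for g in genes if tag not in g.tags],
        }
    raise ValueError(f"unknown stratification {stratify_by!r}")


def metagene(
    track: DyadTrack,
    genes: list[GeneModel],
    anchor: str = "TSS",
    stratify_by: str | None = None,
    upstream: int = 500,
    body_bins: int = 1000,
    downstream: int = 500,
    body_min: int = 200,
) -> dict[str, MetageneProfile]:
    """Gene-scaled, anchor-aligned mean profile per stratum.

    The per-gene vectors are identical for both anchors; the anchor only
    shifts the reported axis (TSS at 0 or pAS at 0).  Masked bins are
    excluded from the per-bin mean; empty strata are dropped with a
    warning.
    """
    if anchor not in ("TSS", "pAS"):
        raise ValueError("anchor must be 'TSS' or 'pAS'")
    axis = _profile_axis(upstream, body_bins, downstream)
    if anchor == "pAS":
        axis = axis - 1000.0
    profiles: dict[str, MetageneProfile] = {}
    for name, members in _strata(genes, stratify_by).items():
        rows = []
        for g in members:
            if g.length < body_min:
                continue
            rows.append(extract_gene_signal(track, g, upstream, body_bins,
                                            downstream, body_min))
        if not rows:
            warnings.warn(f"empty stratum {name!r} dropped")
            continue
        mat = np.vstack(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            means = np.nanmean(mat, axis=0)
        n_per_bin = np.sum(~np.isnan(mat), axis=0)
        profiles[name] = MetageneProfile(
            axis=axis, values=means, n_genes=len(rows),
            sample_label=track.sample_label, anchor=anchor, n_per_bin=n_per_bin,
        )
    return profiles


def _assign_genes(nmap: NucleosomeMap, genes: list[GeneModel],
                  max_distance: int = 1000) -> list[GeneModel | None]:
    """Assign every nucleosome to the nearest gene (interval distance,
    0 inside the gene) within ``max_distance`` bp; None when no gene is
    close enough."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[GeneModel | None] = []
    for n in nmap.nucleosomes:
        best: GeneModel | None = None
        best_d = max_distance + 1
        for g in by_chrom.get(n.chrom, []):
            if g.start <= n.summit <= g.end:
                d = 0
            else:
                d = min(abs(n.summit - g.start), abs(n.summit - g.end))
            if d < best_d:
                best, best_d = g, d
        out.append(best)
    return out


def classify_nucleosomes(
    nmap: NucleosomeMap,
    genes: list[GeneModel],
    convention: str = "scaled",
    max_distance: int = 1000,
) -> pd.DataFrame:
    """Label every nucleosome promoter / body / other relative to its
    nearest gene.

    Two conventions exist in the field and both are supported:

    * ``scaled``  — promoter is relative position [-500, 0) bp upstream of
      the TSS, body is scaled position [0, 1000] over the gene;
    * ``genomic`` — promoter is TSS-500..TSS, body is TSS..gene end in
      genomic bp.

    Returns a table with gene_id, relative (genomic) position, scaled
    position and region label.
    """
    if convention not in ("scaled", "genomic"):
        raise ValueError("convention must be 'scaled' or 'genomic'")
    assigned = _assign_genes(nmap, genes, max_distance)
    rows = []
    for n, g in zip(nmap.nucleosomes, assigned):
        if g is None:
            rows.append(
                {"chrom": n.chrom, "summit": n.summit, "gene_id": None,
                 "rel_position": np.nan, "scaled_position": np.nan,
                 "region": "other", "fuzziness": n.fuzziness,
                 "occupancy": n.occupancy}
            )
            continue
        rel = g.relative_position(n.summit)
        scaled = rel / (g.length - 1) * 1000.0 if rel >= 0 else float(rel)
        if convention == "scaled":
            if -500 <= rel < 0:
                region = "promoter"
            elif rel >= 0 and scaled <= 1000.0:
                region = "body"
            else:
                region = "other"
        else:
            if -500 <= rel < 0:
                region = "promoter"
            elif 0 <= rel <= g.length - 1:
                region = "body"
            else:
                region = "other"
        rows.append(
            {"chrom": n.chrom, "summit": n.summit, "gene_id": g.gene_id,
             "rel_position": float(rel), "scaled_position": scaled,
             "region": region, "fuzziness": n.fuzziness,
             "occupancy": n.occupancy}
        )
    return pd.DataFrame(rows)


def fuzziness_profile(
    nmap: NucleosomeMap,
    genes: list[GeneModel],
    bin_width: int = 50,
    rel_range: tuple[int, int] = (-500, 1500),
    max_distance: int = 1000,
) -> pd.DataFrame:
    """Mean nucleosome fuzziness per TSS-relative position bin.

    Bins with no classified nucleosome are omitted; each retained bin
    reports its nucleosome count.
    """
    cls = classify_nucleosomes(nmap, genes, convention="genomic",
                               max_distance=max_distance)
    cls = cls.dropna(subset=["rel_position", "fuzziness"])
    cls = cls[(cls.rel_position >= rel_range[0]) & (cls.rel_position < rel_range[1])]
    if cls.empty:
        return pd.DataFrame(columns=["bin_start", "mean_fuzziness", "n"])
    bins = ((cls.rel_position - rel_range[0]) // bin_width).astype(int)
    grouped = cls.groupby(bins)["fuzziness"]
    out = pd.DataFrame(
        {
            "bin_start": grouped.mean().index * bin_width + rel_range[0],
            "mean_fuzziness": grouped.mean().to_numpy(),
            "n": grouped.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _coding_window(genome: dict[str, str], gene: GeneModel,
                   upstream: int, downstream: int) -> str | None:
    """Coding-strand sequence from -upstream to +downstream around the
    TSS; None when the window crosses a chromosome edge."""
    seq = genome[gene.chrom]
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream + 1
        if lo < 0 or hi > len(seq):
            return None
        return seq[lo:hi].upper()
    lo, hi = gene.tss - downstream, gene.tss + upstream + 1
    if lo < 0 or hi > len(seq):
        return None
    return seq[lo:hi].upper().translate(_COMPLEMENT)[::-1]


@dataclass
class NucleotideProfile:
    """Per-position nucleotide frequencies around the TSS per stratum,
    plus promoter/body region means and cross-strata t-tests."""

    positions: np.ndarray
    frequencies: dict[str, np.ndarray]  # stratum -> (4, n_positions)
    n_genes: dict[str, int]
    region_means: pd.DataFrame
    region_tests: pd.DataFrame


def nucleotide_profile(
    genome: dict[str, str],
    genes: list[GeneModel],
    stratify_by: str = "promoter_class",
    upstream: int = 500,
    downstream: int = 500,
    promoter_region: tuple[int, int] = (-500, -100),
    body_region: tuple[int, int] = (50, 500),
) -> NucleotideProfile:
    """Position-dependent A/C/G/T frequencies on the coding strand around
    the TSS, stratified, with two-sample t-tests comparing the per-gene
    promoter-region and body-region nucleotide contents across strata."""
    positions = np.arange(-upstream, downstream + 1)
    strata = _strata(genes, stratify_by)
    freqs: dict[str, np.ndarray] = {}
    n_genes: dict[str, int] = {}
    per_gene_region: dict[str, dict[str, dict[str, list[float]]]] = {}
    p_sl = slice(promoter_region[0] + upstream, promoter_region[1] + upstream + 1)
    b_sl = slice(body_region[0] + upstream, body_region[1] + upstream + 1)
    for name, members in strata.items():
        counts = np.zeros((4, len(positions)))
        covered = np.zeros(len(positions))
        regions = {"promoter": {b: [] for b in NUCLEOTIDES},
                   "body": {b: [] for b in NUCLEOTIDES}}
        n_used = 0
        for g in members:
            win = _coding_window(genome, g, upstream, downstream)
            if win is None:
                continue
            n_used += 1
            arr = np.frombuffer(win.encode("ascii"), dtype=np.uint8)
            for bi, base in enumerate(NUCLEOTIDES):
                hit = arr == ord(base)
                counts[bi] += hit
                regions["promoter"][base].append(float(hit[p_sl].mean()))
                regions["body"][base].append(float(hit[b_sl].mean()))
            covered += 1
        with np.errstate(invalid="ignore"):
            freqs[name] = counts / covered
        n_genes[name] = n_used
        per_gene_region[name] = regions
    mean_rows, test_rows = [], []
    names = [n for n in strata if n_genes.get(n, 0) > 0]
    for region in ("promoter", "body"):
        for base in NUCLEOTIDES:
            for name in names:
                vals = per_gene_region[name][region][base]
                mean_rows.append({"stratum": name, "region": region, "base": base,
                                  "mean_frequency": float(np.mean(vals))})
            if len(names) == 2:
                a = per_gene_region[names[0]][region][base]
                b = per_gene_region[names[1]][region][base]
                if len(a) >= 2 and len(b) >= 2:
                    t, p = t_test(a, b)
                    test_rows.append({"region": region, "base": base,
                                      "t": t, "p_value": p,
                                      "stratum_a": names[0], "stratum_b": names[1]})
    return NucleotideProfile(
        positions=positions,
        frequencies=freqs,
        n_genes=n_genes,
        region_means=pd.DataFrame(mean_rows),
        region_tests=pd.DataFrame(test_rows),
    )


def pas_isolated_genes(genes: list[GeneModel], min_gap: int = 500) -> list[GeneModel]:
    """Keep genes whose pAS lies at least ``min_gap`` bp from the TSS of
    every other gene (the isolation filter used for clean pAS-anchored
    profiles)."""
    out = []
    for g in genes:
        ok = True
        for h in genes:
            if h is g or h.chrom != g.chrom:
                continue
            if abs(h.tss - g.pas) < min_gap:
                ok = False
                break
        if ok:
            out.append(g)
    return out
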