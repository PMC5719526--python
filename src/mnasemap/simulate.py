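"""Synthetic MNase-seq experiment generator with known ground truth.

Emulates the full experimental design the pipeline is built for:

* a random genome with controlled GC content;
* a gene annotation with TSS/pAS, promoter classes (TATA genes get
  GC-shifted promoter/body sequence so sequence-composition analyses have
  signal), category tags (RP), and transcription rates;
* a ground-truth nucleosome landscape per gene — a nucleosome-depleted
  region (NDR) upstream of the TSS, a +1 nucleosome just downstream, and a
  phased array at a fixed repeat length into the body, each nucleosome
  carrying an occupancy weight and a positional jitter sigma (its true
  fuzziness), with an optional fraction of MNase-fragile -1 nucleosomes;
* an MNase sequence-preference model (per-base cut weights plus a
  log-linear GC protection term) applied to both arms;
* chromatin reads — dyads jittered around true summits, fragments thinned
  by the cut preference at their ends, plus a small naked-like background
  component (the sub-nucleosomal DNA any partial digest contains);
* naked-DNA reads — fragments between sequence-biased cuts, kept only at
  mononucleosome size (gel size selection).

Everything is deterministic under the seed, and the truth serializes to
plain-text files for exact reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .metagene import GeneModel, load_genes, save_genes
from .tracks import GenomicInterval, ReadSet

__all__ = [
    "BiasModel",
    "TrueNucleosome",
    "SyntheticTruth",
    "make_genome",
    "write_genome",
    "read_genome",
    "make_landscape",
    "sample_chromatin_reads",
    "sample_naked_reads",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


def _chrom_name(i: int) -> str:
    return f"chr{_ROMAN[i]}" if i < len(_ROMAN) else f"chr{i + 1}"


def _seq_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.zeros(256, dtype=np.uint8)
    for b, i in _CODE.items():
        table[ord(b)] = i
    return table[raw]


def _codes_to_seq(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def make_genome(
    n_chrom: int = 1,
    length: int = 200_000,
    gc_fraction: float = 0.38,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, int]]:
    """I.i.d. random genome with expected GC content ``gc_fraction``.

    Returns (sequences, lengths); deterministic under ``seed``.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(n_chrom):
        genome[_chrom_name(i)] = _codes_to_seq(_random_codes(rng, length, gc_fraction))
    return genome, {c: len(s) for c, s in genome.items()}


def write_genome(genome: dict[str, str], fasta_path, sizes_path=None) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(fasta_path), "fasta")
    if sizes_path is not None:
        with open(sizes_path, "w") as fh:
            for c, s in genome.items():
                fh.write(f"{c}\t{len(s)}\n")


def read_genome(fasta_path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def _genome_gc(genome_codes: dict[str, np.ndarray]) -> float:
    total = sum(len(v) for v in genome_codes.values())
    gc = sum(int(np.sum((v == 1) | (v == 2))) for v in genome_codes.values())
    return gc / total


@dataclass
class BiasModel:
    """MNase sequence-preference model.

    ``weights`` gives the relative preference of cutting 5' of each base;
    ``gc_effect`` is a log-linear protection term — cut probability is
    multiplied by ``exp(-gc_effect * (local GC - genomic GC))`` over a
    ``gc_window`` bp window, so GC-rich DNA resists cutting and its
    fragments are overrepresented (the empirical naked-DNA phenomenon).
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in _BASES}
    )
    gc_effect: float = 0.0
    gc_window: int = 101

    def __post_init__(self) -> None:
        if set(self.weights) != set(_BASES) or any(
            w <= 0 for w in self.weights.values()
        ):
            raise ValueError("weights must be positive for all of A, C, G, T")

    @classmethod
    def uniform(cls) -> "BiasModel":
        return cls()

    @property
    def is_uniform(self) -> bool:
        return len(set(self.weights.values())) == 1 and self.gc_effect == 0.0

    def cut_weight_array(self, codes: np.ndarray, genome_gc: float) -> np.ndarray:
        """Per-position relative cut weight along one chromosome."""
        base_w = np.asarray([self.weights[b] for b in _BASES])
        w = base_w[codes]
        if self.gc_effect != 0.0:
            is_gc = ((codes == 1) | (codes == 2)).astype(float)
            kernel = np.ones(self.gc_window) / self.gc_window
            local_gc = np.convolve(is_gc, kernel, mode="same")
            w = w * np.exp(-self.gc_effect * (local_gc - genome_gc))
        return w

    def to_dict(self) -> dict:
        return {"weights": dict(self.weights), "gc_effect": float(self.gc_effect),
                "gc_window": int(self.gc_window)}

    @classmethod
    def from_dict(cls, d: dict) -> "BiasModel":
        return cls(weights={k: float(v) for k, v in d["weights"].items()},
                   gc_effect=float(d.get("gc_effect", 0.0)),
                   gc_window=int(d.get("gc_window", 101)))


@dataclass
class TrueNucleosome:
    chrom: str
    summit: int
    weight: float
    jitter_sd: float
    fragile: bool = False
    gene_id: str = ""


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment."""

    genome: dict[str, str]
    genes: list[GeneModel]
    nucleosomes: list[TrueNucleosome]
    ndrs: list[tuple[str, int, int]]
    bias: BiasModel
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def genome_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def summits(self, chrom: str | None = None) -> np.ndarray:
        nucs = self.nucleosomes if chrom is None else [
            n for n in self.nucleosomes if n.chrom == chrom
        ]
        return np.asarray([n.summit for n in nucs], dtype=np.int64)

    def validate(self) -> None:
        by_chrom: dict[str, list[int]] = {}
        for n in self.nucleosomes:
            by_chrom.setdefault(n.chrom, []).append(n.summit)
        for chrom, summits in by_chrom.items():
            s = np.sort(np.asarray(summits))
            if len(s) > 1 and np.min(np.diff(s)) < 80:
                raise ValueError(f"summits closer than 80 bp on {chrom}")

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(self.genome, out / "genome.fa", out / "genome.chrom.sizes")
        save_genes(self.genes, out / "genes.tsv")
        with open(out / "truth_nucleosomes.tsv", "w") as fh:
            fh.write("chrom\tsummit\tweight\tjitter_sd\tfragile\tgene_id\n")
            for n in self.nucleosomes:
                fh.write(
                    f"{n.chrom}\t{n.summit}\t{n.weight:.8g}\t{n.jitter_sd:.8g}\t"
                    f"{int(n.fragile)}\t{n.gene_id}\n"
                )
        with open(out / "ndrs.tsv", "w") as fh:
            for chrom, s, e in self.ndrs:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {"seed": int(self.seed), "bias": self.bias.to_dict(),
                 "params": self.params},
                fh, sort_keys=True,
            )

    @classmethod
    def load(cls, outdir) -> "SyntheticTruth":
        out = Path(outdir)
        genome = read_genome(out / "genome.fa")
        genes = load_genes(out / "genes.tsv")
        nucleosomes = []
        with open(out / "truth_nucleosomes.tsv") as fh:
            next(fh)
            for line in fh:
                c, s, w, j, f, g = line.rstrip("\n").split("\t")
                nucleosomes.append(
                    TrueNucleosome(c, int(s), float(w), float(j), bool(int(f)), g)
                )
        ndrs = []
        with open(out / "ndrs.tsv") as fh:
            for line in fh:
                c, s, e = line.rstrip("\n").split("\t")
                ndrs.append((c, int(s), int(e)))
        with open(out / "config.yaml") as fh:
            cfg = yaml.safe_load(fh)
        return cls(
            genome=genome, genes=genes, nucleosomes=nucleosomes, ndrs=ndrs,
            bias=BiasModel.from_dict(cfg["bias"]), seed=int(cfg["seed"]),
            params=cfg.get("params", {}),
        )


def _draw_jitter(rng: np.random.Generator, spec) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    lo, hi = spec
    return float(rng.uniform(lo, hi))


def make_landscape(
    genome: dict[str, str],
    n_genes: int = 60,
    repeat_length: int = 165,
    ndr_width: int = 140,
    jitter_spec=20.0,
    occupancy_sigma: float = 0.3,
    fragile_fraction: float = 0.1,
    tata_fraction: float = 0.2,
    rp_fraction: float = 0.08,
    tata_gc_offset: float = 0.06,
    tatalike_gc_offset: float = -0.02,
    bias: BiasModel | None = None,
    free_cassette: tuple[str, int, int] | None = None,
    cassette_gc_amplitude: float = 0.3,
    cassette_block_range: tuple[int, int] = (125, 165),
    seed: int = 0,
) -> SyntheticTruth:
    """Build a ground-truth nucleosome landscape over ``genome``.

    Genes are packed left to right with intergenic gaps wide enough for a
    -1 nucleosome and an NDR; each gene gets a +1 nucleosome just
    downstream of its TSS and a phased array at ``repeat_length`` through
    the body.  ``jitter_spec`` is either a constant sigma (bp) or a
    (low, high) range sampled per nucleosome.  ``free_cassette`` reserves
    a nucleosome- and gene-free region (used to test bias correction); its
    sequence is re-drawn as mononucleosome-sized MNase-resistant (GC-rich,
    ``+cassette_gc_amplitude``) elements separated by cuttable (AT-rich)
    spacers — the kind of protein-free resistant DNA that yields
    nucleosome-like fragments in a partial digest.
    TATA / TATA-like promoter classes are assigned and their promoter and
    body sequences re-drawn with class-specific GC offsets so that
    sequence-composition analyses have a real effect to find.

    Raises ``ValueError`` when ``n_genes`` cannot be packed.
    """
    rng = np.random.default_rng(seed)
    codes = {c: _seq_to_codes(s) for c, s in genome.items()}
    base_gc = _genome_gc(codes)

    if free_cassette is not None and cassette_gc_amplitude > 0:
        # alternate mononucleosome-sized MNase-resistant (GC-rich) elements
        # with cuttable (AT-rich) spacers: resistant elements of this size
        # survive digestion intact and masquerade as nucleosomal fragments
        cchrom, cs, ce = free_cassette
        hi_gc = float(np.clip(base_gc + cassette_gc_amplitude, 0.05, 0.95))
        lo_gc = float(np.clip(base_gc - cassette_gc_amplitude, 0.05, 0.95))
        pos = cs
        resistant = False
        while pos < ce:
            if resistant:
                blen = int(rng.integers(*cassette_block_range))
                gc_block = hi_gc
            else:
                blen = int(rng.integers(200, 400))
                gc_block = lo_gc
            hi = min(pos + blen, ce)
            codes[cchrom][pos:hi] = _random_codes(rng, hi - pos, gc_block)
            resistant = not resistant
            pos = hi

    genes: list[GeneModel] = []
    nucleosomes: list[TrueNucleosome] = []
    ndrs: list[tuple[str, int, int]] = []

    # class / tag / rate assignment up front, deterministic under seed
    n_tata = int(round(tata_fraction * n_genes))
    n_rp = int(round(rp_fraction * n_genes))
    classes = np.array(["TATA"] * n_tata + ["TATA-like"] * (n_genes - n_tata))
    rng.shuffle(classes)
    tatalike_idx = np.flatnonzero(classes == "TATA-like")
    rp_set = set(rng.choice(tatalike_idx, size=min(n_rp, len(tatalike_idx)),
                            replace=False).tolist()) if n_rp else set()
    n_fragile = int(round(fragile_fraction * n_genes))
    fragile_order = list(sorted(rp_set)) + [
        i for i in rng.permutation(n_genes).tolist() if i not in rp_set
    ]
    fragile_set = set(fragile_order[:n_fragile])

    import bisect

    placed: dict[str, list[int]] = {c: [] for c in genome}

    def _clear(chrom: str, pos: int, min_dist: int = 85) -> bool:
        s = placed[chrom]
        i = bisect.bisect_left(s, pos)
        if i > 0 and pos - s[i - 1] < min_dist:
            return False
        if i < len(s) and s[i] - pos < min_dist:
            return False
        return True

    def _place(nuc: TrueNucleosome) -> None:
        nucleosomes.append(nuc)
        bisect.insort(placed[nuc.chrom], nuc.summit)

    gi = 0
    chrom_names = sorted(genome)
    for chrom in chrom_names:
        L = len(codes[chrom])
        cursor = 700
        while gi < n_genes:
            # gap wide enough for NDR + -1 nucleosome on both gene flanks
            gap = int(rng.integers(560, 760))
            gene_len = int(rng.integers(900, 2100))
            start = cursor + gap
            end = start + gene_len - 1
            if end + 700 > L:
                break
            if free_cassette is not None and free_cassette[0] == chrom:
                _, cs, ce = free_cassette
                if start - 500 < ce and end + 500 > cs:
                    cursor = max(cursor, ce + 500)
                    continue
            strand = "+" if rng.random() < 0.5 else "-"
            sgn = 1 if strand == "+" else -1
            tss = start if strand == "+" else end
            pas = end if strand == "+" else start
            gene_id = f"g{gi:04d}"
            promoter_class = str(classes[gi])
            tags = set()
            if gi in rp_set:
                tags.add("RP")
            rate = float(rng.lognormal(mean=2.0, sigma=1.0))
            if "RP" in tags:
                rate *= 8.0
            genes.append(
                GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                          pas=pas, promoter_class=promoter_class, tags=tags,
                          transcription_rate=rate)
            )
            # NDR immediately upstream of the TSS
            ndr_lo = tss - sgn * ndr_width
            ndrs.append((chrom, min(tss, ndr_lo), max(tss, ndr_lo)))
            # -1 nucleosome beyond the NDR
            m1 = tss - sgn * (ndr_width + 74)
            if 80 <= m1 <= L - 80 and _clear(chrom, int(m1)):
                _place(
                    TrueNucleosome(
                        chrom=chrom, summit=int(m1),
                        weight=float(rng.lognormal(0.0, occupancy_sigma)),
                        jitter_sd=_draw_jitter(rng, jitter_spec),
                        fragile=gi in fragile_set, gene_id=gene_id,
                    )
                )
            # +1 and the phased body array
            k = 0
            while True:
                summit = tss + sgn * (73 + k * repeat_length)
                if not (start <= summit <= end) or not 80 <= summit <= L - 80:
                    break
                if _clear(chrom, int(summit)):
                    _place(
                        TrueNucleosome(
                            chrom=chrom, summit=int(summit),
                            weight=float(rng.lognormal(0.0, occupancy_sigma)),
                            jitter_sd=_draw_jitter(rng, jitter_spec),
                            fragile=False, gene_id=gene_id,
                        )
                    )
                k += 1
            # class-specific sequence composition: re-draw promoter
            # (-400..-1) and gene body with GC offsets
            offset = tata_gc_offset if promoter_class == "TATA" else tatalike_gc_offset
            body_gc = float(np.clip(base_gc + offset, 0.05, 0.95))
            prom_gc = float(np.clip(base_gc + (0.08 if promoter_class == "TATA" else -0.02),
                                    0.05, 0.95))
            codes[chrom][start : end + 1] = _random_codes(rng, gene_len, body_gc)
            p_lo, p_hi = (start - 400, start) if strand == "+" else (end + 1, end + 401)
            p_lo, p_hi = max(p_lo, 0), min(p_hi, L)
            codes[chrom][p_lo:p_hi] = _random_codes(rng, p_hi - p_lo, prom_gc)
            cursor = end
            gi += 1
    if gi < n_genes:
        raise ValueError(f"could only pack {gi} of {n_genes} genes into the genome")

    truth = SyntheticTruth(
        genome={c: _codes_to_seq(v) for c, v in codes.items()},
        genes=genes,
        nucleosomes=nucleosomes,
        ndrs=ndrs,
        bias=bias or BiasModel.uniform(),
        seed=int(seed),
        params={
            "n_genes": int(n_genes), "repeat_length": int(repeat_length),
            "ndr_width": int(ndr_width),
            "jitter_spec": jitter_spec if isinstance(jitter_spec, (int, float))
            else list(jitter_spec),
            "occupancy_sigma": float(occupancy_sigma),
            "fragile_fraction": float(fragile_fraction),
            "tata_fraction": float(tata_fraction),
            "rp_fraction": float(rp_fraction),
            "free_cassette": list(free_cassette) if free_cassette else None,
        },
    )
    truth.validate()
    return truth


def _naked_fragments(
    codes: dict[str, np.ndarray],
    bias: BiasModel,
    n_needed: int,
    size_range: tuple[int, int],
    cut_rate: float,
    rng: np.random.Generator,
    weights: dict[str, np.ndarray] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Draw ``n_needed`` size-selected fragments from the sequence-biased
    cut process; returns (chroms, starts, ends).

    ``weights`` overrides the per-position cut weights (used by the
    chromatin background arm to fold in nucleosome protection).
    """
    if weights is None:
        genome_gc = _genome_gc(codes)
        weights = {
            c: bias.cut_weight_array(v, genome_gc) for c, v in sorted(codes.items())
        }
    lo, hi = size_range
    chroms: list[str] = []
    starts: list[np.ndarray] = []
    ends: list[np.ndarray] = []
    n_have = 0
    for _round in range(500):
        if n_have >= n_needed:
            break
        for chrom in sorted(codes):
            w = weights[chrom]
            p = np.clip(cut_rate * w / w.mean(), 0.0, 0.9)
            cuts = np.flatnonzero(rng.random(len(w)) < p)
            if len(cuts) < 2:
                continue
            fs, fe = cuts[:-1], cuts[1:]
            keep = (fe - fs >= lo) & (fe - fs <= hi)
            fs, fe = fs[keep], fe[keep]
            if len(fs) == 0:
                continue
            chroms.extend([chrom] * len(fs))
            starts.append(fs)
            ends.append(fe)
            n_have += len(fs)
    if n_have == 0:
        return [], np.empty(0, np.int64), np.empty(0, np.int64)
    s = np.concatenate(starts)[:n_needed]
    e = np.concatenate(ends)[:n_needed]
    return chroms[:n_needed], s, e


def _fragments_to_reads(
    chroms: list[str],
    starts: np.ndarray,
    ends: np.ndarray,
    read_length: int,
    rng: np.random.Generator,
) -> list[GenomicInterval]:
    """Emit one single-end read per fragment, from a uniformly random end
    with the matching strand."""
    from_five_prime = rng.random(len(starts)) < 0.5
    reads = []
    for chrom, s, e, five in zip(chroms, starts, ends, from_five_prime):
        if five:
            reads.append(GenomicInterval(chrom, int(s), int(s) + read_length, "+"))
        else:
            reads.append(GenomicInterval(chrom, int(e) - read_length, int(e), "-"))
    return reads


def sample_chromatin_reads(
    truth: SyntheticTruth,
    mean_dyads_per_nucleosome: float = 50.0,
    read_length: int = 36,
    background_fraction: float = 0.2,
    fragile_retention: float = 1.0,
    bias: BiasModel | None = None,
    size_range: tuple[int, int] = (120, 180),
    cut_rate: float = 1.0 / 150.0,
    nucleosome_protection: float = 0.05,
    seed: int = 0,
) -> ReadSet:
    """Sample the chromatin arm of the experiment.

    Nucleosomal fragments: a nucleosome is sampled in proportion to its
    occupancy weight (fragile -1 nucleosomes additionally scaled by
    ``fragile_retention``), the dyad is the true summit plus rounded
    N(0, sigma) jitter, and the 147 bp fragment around it is kept in
    proportion to the cut-preference weight at its two ends
    (sequence-preference thinning); a 36 bp single-end read is emitted
    from a random end.  A ``background_fraction`` of naked-process
    fragments drawn from the accessible (non-nucleosomal, cut weight
    scaled by ``nucleosome_protection`` under footprints) genome models
    the free DNA any partial digest contains.  Deterministic under seed.
    """
    if mean_dyads_per_nucleosome <= 0:
        raise ValueError("coverage must be > 0")
    bias = bias or truth.bias
    rng = np.random.default_rng(seed)
    codes = {c: _seq_to_codes(s) for c, s in truth.genome.items()}
    genome_gc = _genome_gc(codes)
    lengths = truth.genome_lengths

    weights = np.asarray(
        [n.weight * (fragile_retention if n.fragile else 1.0)
         for n in truth.nucleosomes]
    )
    mean_w = weights.mean()
    all_chroms: list[str] = []
    all_starts: list[int] = []
    all_ends: list[int] = []
    cut_w = {c: bias.cut_weight_array(v, genome_gc) for c, v in sorted(codes.items())}
    for nuc, w in zip(truth.nucleosomes, weights):
        n_i = rng.poisson(mean_dyads_per_nucleosome * w / mean_w)
        if n_i == 0:
            continue
        sd = nuc.jitter_sd
        jit = np.round(rng.normal(0.0, sd, size=n_i)).astype(np.int64) if sd > 0 \
            else np.zeros(n_i, dtype=np.int64)
        dy = nuc.summit + jit
        fs, fe = dy - 73, dy + 74
        L = lengths[nuc.chrom]
        ok = (fs >= 0) & (fe <= L)
        fs, fe = fs[ok], fe[ok]
        if not bias.is_uniform and len(fs) > 0:
            # sequence-preference thinning at the fragment ends: resample
            # the candidate fragments with probability proportional to
            # the cut weight at both ends (total count preserved — the
            # library is sequenced to depth, the bias shifts composition)
            wc = cut_w[nuc.chrom]
            p = wc[fs] * wc[fe - 1]
            idx = rng.choice(len(fs), size=len(fs), replace=True, p=p / p.sum())
            fs, fe = fs[idx], fe[idx]
        all_chroms.extend([nuc.chrom] * len(fs))
        all_starts.extend(fs.tolist())
        all_ends.extend(fe.tolist())

    n_bg = rng.poisson(
        background_fraction * mean_dyads_per_nucleosome * len(truth.nucleosomes)
    )
    if n_bg > 0:
        # the free-DNA background behaves like naked DNA, but only the
        # accessible (non-nucleosomal) genome is exposed to the enzyme
        access = {c: np.ones(lengths[c]) for c in codes}
        for nuc in truth.nucleosomes:
            lo = max(nuc.summit - 73, 0)
            hi = min(nuc.summit + 74, lengths[nuc.chrom])
            access[nuc.chrom][lo:hi] = nucleosome_protection
        bg_w = {c: cut_w[c] * access[c] for c in sorted(codes)}
        bc, bs, be = _naked_fragments(codes, bias, int(n_bg), size_range,
                                      cut_rate, rng, weights=bg_w)
        all_chroms.extend(bc)
        all_starts.extend(bs.tolist())
        all_ends.extend(be.tolist())

    reads = _fragments_to_reads(
        all_chroms, np.asarray(all_starts, np.int64), np.asarray(all_ends, np.int64),
        read_length, rng,
    )
    return ReadSet(sample_label="chromatin", reads=reads,
                   genome_lengths=dict(lengths)).sorted()


def sample_naked_reads(
    genome: dict[str, str],
    bias: BiasModel,
    n_fragments: int = 20_000,
    size_range: tuple[int, int] = (120, 180),
    read_length: int = 36,
    cut_rate: float = 1.0 / 150.0,
    seed: int = 0,
) -> ReadSet:
    """Sample the naked-DNA arm: cut sites drawn with probability
    proportional to the local cut-preference weight, fragments between
    successive cuts kept only at mononucleosome size, one single-end read
    per kept fragment.  Deterministic under seed."""
    if n_fragments <= 0:
        raise ValueError("n_fragments must be > 0")
    rng = np.random.default_rng(seed)
    codes = {c: _seq_to_codes(s) for c, s in genome.items()}
    chroms, starts, ends = _naked_fragments(codes, bias, n_fragments,
                                            size_range, cut_rate, rng)
    reads = _fragments_to_reads(chroms, starts, ends, read_length, rng)
    return ReadSet(
        sample_label="naked", reads=reads,
        genome_lengths={c: len(s) for c, s in genome.items()},
    ).sorted()
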