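import numpy as np
import pytest

import mnasemap as m


@pytest.fixture(scope="session")
def uniform_experiment():
    """A small bias-free simulated experiment shared across tests:
    genome, truth landscape, chromatin reads, dyads and smoothed track."""
    genome, lengths = m.make_genome(n_chrom=1, length=80_000, gc_fraction=0.38,
                                    seed=5)
    truth = m.make_landscape(genome, n_genes=20, seed=5)
    reads = m.sample_chromatin_reads(
        truth, mean_dyads_per_nucleosome=30, background_fraction=0.0,
        bias=m.BiasModel.uniform(), seed=6,
    )
    dy = m.dyads(reads)
    track = m.smooth(dy, 10.0, truth.genome_lengths)
    return {
        "genome": genome,
        "truth": truth,
        "reads": reads,
        "dyads": dy,
        "track": track,
    }


@pytest.fixture()
def simple_track():
    """One chromosome, one Gaussian bump of height ~5 at position 1000."""
    v = np.zeros(3000)
    x = np.arange(3000)
    v += 5.0 * np.exp(-0.5 * ((x - 1000) / 25.0) ** 2)
    return m.DyadTrack(sample_label="bump", values={"chrI": v})
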