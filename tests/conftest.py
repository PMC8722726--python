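import random

import pytest

from stemfuse.genome_model import GeneModel, GenomeSequence, Interval
from stemfuse.synthetic_data import generate_genome, preset


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def synth():
    """The default small-scale preset fixture genome (seed 7, scale 0.05)."""
    return generate_genome(preset(scale=0.05, seed=7))


@pytest.fixture(scope="session")
def preset_stems(synth):
    """Default-parameter stems on the preset fixture (computed once)."""
    from stemfuse.stem_finder import find_stems

    return find_stems(synth.gene_a, synth.gene_b, synth.genome)


@pytest.fixture(scope="session")
def sense_pair(synth):
    sa = synth.gene_a.sense_sequence(synth.genome["chrA"])
    sb = synth.gene_b.sense_sequence(synth.genome["chrB"])
    return sa, sb


def two_gene_fixture(intron_a: str, intron_b: str, exon_len: int = 60, seed: int = 1):
    """Minimal two-gene genome: each gene is exon–intron–exon on its own
    contig, with the given intron sequences."""
    rng = random.Random(seed)
    exons_a = [random_dna(rng, exon_len) for _ in range(2)]
    exons_b = [random_dna(rng, exon_len) for _ in range(2)]
    contig_a = exons_a[0] + intron_a + exons_a[1]
    contig_b = exons_b[0] + intron_b + exons_b[1]
    gene_a = GeneModel(
        "gA", "cA", "+",
        [Interval("cA", 0, exon_len),
         Interval("cA", exon_len + len(intron_a), len(contig_a))],
    )
    gene_b = GeneModel(
        "gB", "cB", "+",
        [Interval("cB", 0, exon_len),
         Interval("cB", exon_len + len(intron_b), len(contig_b))],
    )
    genome = {
        "cA": GenomeSequence("cA", contig_a),
        "cB": GenomeSequence("cB", contig_b),
    }
    return genome, gene_a, gene_b
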