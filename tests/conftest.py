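import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracles.py

from mitoring.genome_io import CircularGenome
from mitoring.synthetic_data import (GeneSpec, GenomeSpec, RepeatSpec,
                                     generate_mitogenome, random_dna)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_genome():
    """10 kb genome with one planted 60 bp direct pair at 1000/5000."""
    spec = GenomeSpec(
        length=10_000, seed=11,
        repeat_specs=[RepeatSpec(60, "direct", name="R01", positions=[1000, 5000])],
    )
    return generate_mitogenome(spec)


@pytest.fixture
def repeat_free_genome():
    g, _ = generate_mitogenome(GenomeSpec(length=10_000, seed=3))
    return g


@pytest.fixture
def annotated_genome():
    """Small genome with genes on both strands and planted editing sites."""
    from mitoring.synthetic_data import EditingSpec

    spec = GenomeSpec(
        length=8_000, seed=41,
        gene_specs=[GeneSpec("cox1", 900, "+"), GeneSpec("nad1", 600, "-")],
        editing_specs=[EditingSpec("cox1", 1, 0.89), EditingSpec("nad1", 50, 0.5)],
    )
    return generate_mitogenome(spec)


def make_block_genome(rng, repeats: list[tuple[str, int]], blocks: list[int],
                      layout: list[str]) -> tuple[CircularGenome, dict[str, str]]:
    """Circle assembled from named repeat copies and anonymous blocks.

    ``layout`` entries: 'R1', '-R1' (repeat copy fwd/rc) or 'b0', '-b0'
    (block index).  Returns the genome and the repeat sequences by name.
    """
    from mitoring.genome_io import reverse_complement_seq

    reps = {name: random_dna(rng, ln) for name, ln in repeats}
    blks = [random_dna(rng, ln) for ln in blocks]
    parts = []
    for token in layout:
        sign = -1 if token.startswith("-") else 1
        token = token.lstrip("-")
        s = reps[token] if token in reps else blks[int(token[1:])]
        parts.append(reverse_complement_seq(s) if sign == -1 else s)
    return CircularGenome("blocky", "".join(parts)), reps
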