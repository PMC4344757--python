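import numpy as np
import pytest

from pseudoquant import Exon, GeneModel, GenomeSequence


def random_genome(seed: int, length: int, chrom: str = "c1") -> GenomeSequence:
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), length))
    return GenomeSequence([chrom], {chrom: seq})


@pytest.fixture
def small_genome() -> GenomeSequence:
    return random_genome(11, 1200)


@pytest.fixture
def two_exon_gene(small_genome) -> GeneModel:
    return GeneModel(
        gene_id="G1",
        biotype="coding",
        transcripts={"G1.t1": [Exon("c1", 100, 300, "+"), Exon("c1", 500, 700, "+")]},
    )
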