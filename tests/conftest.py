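import io

import numpy as np
import pytest

from utxsplice.gene_model import Exon, ExonModel, load_gene_model
from utxsplice.synthetic_data import synthetic_gene_model

# a tiny hand-written gene: five 20-bp exons on a 200-bp chromosome,
# ASR = exons 2..4, laid out with 10-bp introns starting at position 10
TOY_EXON_STARTS = [10, 40, 70, 100, 130]
TOY_CHROM_LEN = 200


def _toy_chrom(seed: int = 99) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, TOY_CHROM_LEN))


@pytest.fixture(scope="session")
def toy_chrom() -> str:
    return _toy_chrom()


@pytest.fixture(scope="session")
def toy_fasta(toy_chrom) -> str:
    wrapped = "\n".join(toy_chrom[i:i + 60] for i in range(0, len(toy_chrom), 60))
    return f">chrT\n{wrapped}\n"


def toy_bed12(strand: str = "+") -> str:
    sizes = ",".join("20" for _ in TOY_EXON_STARTS)
    offsets = ",".join(str(s - TOY_EXON_STARTS[0]) for s in TOY_EXON_STARTS)
    start, end = TOY_EXON_STARTS[0], TOY_EXON_STARTS[-1] + 20
    return ("\t".join(["chrT", str(start), str(end), "TOY", "0", strand,
                       str(start), str(end), "0,0,0", "5", sizes, offsets]) + "\n")


@pytest.fixture(scope="session")
def toy_model(toy_fasta) -> ExonModel:
    return load_gene_model(io.StringIO(toy_bed12("+")), io.StringIO(toy_fasta),
                           "TOY", (2, 4))


@pytest.fixture(scope="session")
def gene30() -> ExonModel:
    """Thirty-exon synthetic gene with ASR exons 12-17 (the default geometry)."""
    return synthetic_gene_model(seed=1234)
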