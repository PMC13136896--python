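import numpy as np
import pytest

from becontain.assay_quant import DilutionScheme
from becontain.be_screen import EditingWindowSpec
from becontain.genome_model import GeneRecord, Genome


@pytest.fixture
def induced_scheme() -> DilutionScheme:
    return DilutionScheme.induced()


@pytest.fixture
def uninduced_scheme() -> DilutionScheme:
    return DilutionScheme.uninduced()


@pytest.fixture
def window_spec() -> EditingWindowSpec:
    return EditingWindowSpec()


def random_genome(rng: np.random.Generator, length: int,
                  topology: str = "linear") -> Genome:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome(id="rand", sequence=seq, topology=topology)


@pytest.fixture
def make_random_genome():
    return random_genome


def plus_gene_genome(offset: int = 17):
    """A minimal hand-built genome with one "+"-strand ATG gene whose
    antisense PAM sits at the requested window offset.

    Layout (forward strand): the CC dinucleotide at ``start - offset``
    is the reverse-complement reading of the antisense NGG.
    """
    rng = np.random.default_rng(99)
    start = 40
    seq = list("".join(rng.choice(list("AT"), size=120)))  # no C/G background
    seq[start : start + 3] = list("ATG")
    seq[start + 3 : start + 12] = list("AAATTTAAA")
    b = start - offset
    seq[b], seq[b + 1] = "C", "C"
    genome = Genome(id="mini", sequence="".join(seq))
    gene = GeneRecord.from_interval(
        "geneA", start, start + 12, "+", genome, pathway="replication"
    )
    return genome, gene
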