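import numpy as np
import pytest

from nmdscope.synthetic import gen_study_truth, gen_transcriptome, simulate_bulk
from nmdscope.transcript_models import TranscriptModel


def make_model(
    utr5: str,
    cds: str,
    utr3: str,
    cuts: tuple[int, ...] = (),
    transcript_id: str = "t1",
    gene_id: str = "g1",
    strand: str = "+",
) -> TranscriptModel:
    """Assemble a single-contig transcript model from its three segments.

    ``cuts`` are transcript coordinates where exon boundaries fall
    (break between position cut-1 and cut).
    """
    seq = utr5 + cds + utr3
    bounds = [0, *sorted(set(cuts)), len(seq)]
    exons = tuple(
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    )
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_symbol=gene_id,
        strand=strand,
        exons=exons,
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        sequence=seq,
    )


@pytest.fixture(scope="session")
def random_models():
    """1000 synthetic transcripts with planted NIF classes, session-shared."""
    models, truth = gen_transcriptome(
        n_genes=1000,
        nif_fractions={"dej": 0.25, "uorf": 0.25, "long3utr": 0.25},
        seed=11,
    )
    return models, truth


@pytest.fixture(scope="session")
def bulk_run():
    """One simulated bulk experiment with planted stabilization."""
    truth = gen_study_truth(
        n_genes=2000,
        n_upregulated=100,
        n_stabilized=100,
        n_nif=0,
        planted_log2fc=1.0,
        background_nif_frac=0.0,
        seed=21,
    )
    bulk = simulate_bulk(truth, seed=22)
    return truth, bulk
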