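import numpy as np
import pytest

from sltrans import (
    AlignScoring,
    SLDatabase,
    SimConfig,
    run_pipeline,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def db() -> SLDatabase:
    return SLDatabase.celegans()


@pytest.fixture(scope="session")
def scoring() -> AlignScoring:
    return AlignScoring()


@pytest.fixture(scope="session")
def sw_oracle():
    """Independent full Smith-Waterman oracle (biopython PairwiseAligner)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@pytest.fixture(scope="session")
def toy_sim(db):
    """The reference toy simulation: 50 genes, 1,000 SL + 9,000 background
    reads, all emitted as unmapped candidates so the false-positive path is
    exercised."""
    cfg = SimConfig(seed=1, unmapped_background_fraction=1.0)
    return simulate_dataset(cfg, db=db)


@pytest.fixture(scope="session")
def toy_runs(toy_sim, db):
    """Pipeline results on the toy simulation for all three modes."""
    reads = toy_sim.reads.unmapped_reads()
    return {
        mode: run_pipeline(
            reads, toy_sim.genome, db=db, genes=toy_sim.genes, mode=mode
        )
        for mode in ("default", "sensitive", "tourasse")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
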