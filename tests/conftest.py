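import numpy as np
import pandas as pd
import pytest

from hatseq.config import FilterConfig
from hatseq.consensus import load_default_consensus
from hatseq.readproc import parse_contigs
from hatseq.classify import run_cascade
from hatseq.simdata import SyntheticGenome, build_genome, generate_contigs, plan_truth


@pytest.fixture(scope="session")
def consensus():
    return load_default_consensus()


@pytest.fixture(scope="session")
def genome():
    """Two-contig toy genome with planted young-L1 repeats and genes."""
    return build_genome({"chr1": 150_000, "chr2": 150_000},
                        n_l1hs=6, n_older=2, n_genes=3, seed=7)


@pytest.fixture(scope="session")
def sim_library(genome):
    """One simulated library: truth, KNR database, contig table."""
    truth, knr_db = plan_truth(genome, n_kr=2, n_knr=4, n_unk=2, n_somatic=3,
                               n_chimera=4, n_misaligned=1, n_local_sv=1,
                               somatic_cells=3, seed=1)
    contigs = generate_contigs(genome, truth, sample="S1", individual="I1", seed=3)
    return {"truth": truth, "knr_db": knr_db, "contigs": contigs}


@pytest.fixture(scope="session")
def sim_cascade(genome, sim_library, consensus):
    parsed = parse_contigs(sim_library["contigs"], consensus)
    result = run_cascade(parsed, genome, sim_library["knr_db"], FilterConfig(),
                         "S1", "I1")
    return {"parsed": parsed, "result": result}


def bare_genome(sequences: dict[str, str]) -> SyntheticGenome:
    """Genome wrapper around explicit sequences, without annotation."""
    repeats = pd.DataFrame(columns=["chrom", "start", "end", "strand", "family", "name"])
    return SyntheticGenome(sequences=sequences, repeats=repeats, gene_models=[],
                           mappability={c: np.ones(len(s), dtype=np.float32)
                                        for c, s in sequences.items()})
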