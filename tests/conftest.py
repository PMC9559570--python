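from __future__ import annotations

import numpy as np
import pytest

from sscswitch import (
    CircularGenome,
    QuadripartiteStructure,
    SimConfig,
    simulate_genome,
)

TOY_LSC = "CCAGTGCTTAGA"
TOY_IR1 = "AAGGCTAGCT"
TOY_SSC = "GTTTACCA"
TOY_IR2 = "AGCTAGCCTT"  # revcomp(TOY_IR1)
TOY_SEQ = TOY_LSC + TOY_IR1 + TOY_SSC + TOY_IR2


@pytest.fixture
def toy_genome() -> CircularGenome:
    """12/10/8/10 bp quadripartite toy whose planted IR pair is maximal."""
    return CircularGenome("toy", TOY_SEQ)


@pytest.fixture
def toy_structure() -> QuadripartiteStructure:
    return QuadripartiteStructure.from_lengths(12, 10, 8)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic genome shared across tests."""
    cfg = SimConfig(seed=20240901)
    genome, structure = simulate_genome(cfg)
    return cfg, genome, structure


def plant_ir_genome(
    rng: np.random.Generator,
    lsc_len: int,
    ir_len: int,
    ssc_len: int,
    rotate: bool = True,
) -> tuple[str, int]:
    """Random circular sequence with one planted IR pair; returns (seq, rotation)."""
    comp = str.maketrans("ACGT", "TGCA")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def rand(n):
        return bases[rng.integers(0, 4, n)].tobytes().decode()

    lsc, ir1, ssc = rand(lsc_len), rand(ir_len), rand(ssc_len)
    seq = lsc + ir1 + ssc + ir1.translate(comp)[::-1]
    off = int(rng.integers(0, len(seq))) if rotate else 0
    return seq[off:] + seq[:off], off
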