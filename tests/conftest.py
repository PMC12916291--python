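"""Shared fixtures: small random alignments and gene models."""

import numpy as np
import pytest

from ildscan.types import GeneModel, HaplotypeAlignment, encode_sequence


def random_alignment(
    rng: np.random.Generator,
    n_hap: int = 8,
    length: int = 60,
    contig: str = "c1",
    p_minor: float = 0.3,
    n_snvs: int = 10,
) -> HaplotypeAlignment:
    """Alignment with a random backbone and biallelic SNVs at random columns."""
    backbone = rng.integers(0, 4, size=length).astype(np.uint8)
    matrix = np.tile(backbone, (n_hap, 1))
    cols = rng.choice(length, size=min(n_snvs, length), replace=False)
    for c in cols:
        alt = (backbone[c] + 1 + rng.integers(3)) % 4
        carriers = rng.random(n_hap) < p_minor
        if not carriers.any():
            carriers[rng.integers(n_hap)] = True
        if carriers.all():
            carriers[rng.integers(n_hap)] = False
        matrix[carriers, c] = alt
    return HaplotypeAlignment(
        contig_id=contig,
        matrix=matrix,
        haplotype_ids=[f"h{i}" for i in range(n_hap)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_gene_alignment():
    """4 haplotypes over a 12 bp + strand gene; one SYN SNV at codon 3 of GGA."""
    seqs = ["GGAGGGTTTAAA", "GGGGGGTTTAAA", "GGAGGGTTTAAA", "GGGGGGTTTAAA"]
    matrix = np.vstack([encode_sequence(s) for s in seqs])
    aln = HaplotypeAlignment("c1", matrix, ["a", "b", "c", "d"])
    genes = [GeneModel("g1", "c1", 0, 12, "+", 0)]
    return aln, genes
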