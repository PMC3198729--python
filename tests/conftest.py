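import numpy as np
import pytest

from sirnawalk.seqcore import AlleleLocus, Alphabet, NucleotideSequence

# Mutant-allele sense cores reconstructed by reverse complement of the known
# 19-mer guide strands (independent Biopython oracle, frozen):
#   LRRK2 G2019S-like: guides p3/p4/p5 tile AAAGAUUGCUGACUACAGCAU, variant
#   G->A at core position 17.
#   SNCA A30P-like: guide p13 reverse-complements GAAGCACCAGGAAAGACAA, variant
#   G->C at core position 7.
LRRK2_MUT_CORE_DNA = "AAAGATTGCTGACTACAGCAT"
LRRK2_CORE_SNV_OFFSET = 17  # 1-based within core; wt G, mut A
SNCA_MUT_CORE_DNA = "GAAGCACCAGGAAAGACAA"
SNCA_CORE_SNV_OFFSET = 7  # 1-based within core; wt G, mut C


def _embed(core_mut: str, snv_offset: int, wt: str, flank: int, seed: int, tid: str) -> AlleleLocus:
    rng = np.random.default_rng(seed)
    f5 = "".join(rng.choice(list("ACGT"), flank))
    f3 = "".join(rng.choice(list("ACGT"), flank))
    wt_core = core_mut[: snv_offset - 1] + wt + core_mut[snv_offset:]
    seq = f5 + wt_core + f3
    pos = flank + snv_offset
    mut = core_mut[snv_offset - 1]
    return AlleleLocus(tid, NucleotideSequence(seq, Alphabet.DNA), pos, wt, mut)


@pytest.fixture(scope="session")
def lrrk2_locus() -> AlleleLocus:
    """Synthetic transcript carrying the G2019S-like G>A variant (wt G:U wobble)."""
    return _embed(LRRK2_MUT_CORE_DNA, LRRK2_CORE_SNV_OFFSET, "G", 60, seed=11, tid="LRRK2like")


@pytest.fixture(scope="session")
def a30p_locus() -> AlleleLocus:
    """Synthetic transcript carrying the A30P-like G>C variant (wt G:G mismatch)."""
    return _embed(SNCA_MUT_CORE_DNA, SNCA_CORE_SNV_OFFSET, "G", 60, seed=13, tid="SNCAlike")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
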