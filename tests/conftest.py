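import numpy as np
import pytest

from canisom.simulate import CohortConfig, generate_cohort
from canisom.variant_io import Transcript, TranscriptModel, VariantCall


def make_call(
    sample="S1",
    chrom="chr1",
    pos=100,
    ref="C",
    alt="T",
    depth=100,
    alt_depth=50,
    fs=1.0,
    qd=20.0,
    **kwargs,
):
    return VariantCall(sample, chrom, pos, ref, alt, depth, alt_depth, fs, qd, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-dog cohort reused across read-only tests."""
    return generate_cohort(CohortConfig(n_samples=60, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The seeded reference cohort (300 dogs, ~30k calls)."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def toy_transcript_plus():
    """600-codon plus-strand gene with codon 588 = GTG (valine)."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=600 * 3))
    k = 587 * 3
    seq = seq[:k] + "GTG" + seq[k + 3 :]
    tx = Transcript("BRAF", "chr1", "+", ((1001, 1001 + 600 * 3 - 1),), seq)
    return TranscriptModel([tx])


@pytest.fixture()
def toy_transcript_minus():
    """Same CDS on the minus strand of the genome."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=600 * 3))
    k = 587 * 3
    seq = seq[:k] + "GTG" + seq[k + 3 :]
    tx = Transcript("BRAF", "chr1", "-", ((1001, 1001 + 600 * 3 - 1),), seq)
    return TranscriptModel([tx])
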