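import numpy as np
import pytest

from vntrkit.synthetic import LocusSpec, make_locus


@pytest.fixture(scope="session")
def big_locus():
    """The default synthetic locus: 8 x 7380-bp units at 2% divergence,
    GC 0.642, 10-kb flanks, seed 1."""
    spec = LocusSpec(seed=1)
    seq, truth = make_locus(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def big_report(big_locus, tmp_path_factory):
    """Full pipeline report on the default locus fixture."""
    from vntrkit.pipeline import characterize_locus
    from vntrkit.synthetic import write_fasta

    _, seq, truth = big_locus
    d = tmp_path_factory.mktemp("fixture")
    write_fasta(d / "locus.fa", {"locus": seq})
    truth.to_bed(d / "locus.bed", chrom="locus")
    return characterize_locus(d / "locus.fa", annotations_path=d / "locus.bed")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n, gc=0.5):
    at, g = (1 - gc) / 2, gc / 2
    return "".join(rng.choice(list("ACGT"), size=n, p=[at, g, g, at]))
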