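import hypothesis
import pytest

from privar.variant_io import SampleGenotype, VariantSite

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_site(
    gts,
    chrom="chr1",
    pos=100,
    ref="A",
    alts=("G",),
    qual=50.0,
    info=None,
    sample_prefix="s",
):
    """Build a VariantSite from compact genotype tuples.

    Each element of ``gts`` is (allele_indices, depth, allele_depths);
    sample ids are s0, s1, ... by position.
    """
    genotypes = [
        SampleGenotype(f"{sample_prefix}{i}", idx, depth=dp, allele_depths=ad)
        for i, (idx, dp, ad) in enumerate(gts)
    ]
    return VariantSite(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=tuple(alts),
        qual=qual,
        genotypes=genotypes,
        info=dict(info or {}),
    )


@pytest.fixture
def toy_sites():
    """Three biallelic sites over a 3-sample cohort (s0 is the 'case')."""
    return [
        make_site([((0, 1), 30, (15, 15)), ((0, 0), 25, (25, 0)), ((0, 0), 28, (28, 0))], pos=100),
        make_site([((0, 0), 30, (30, 0)), ((0, 1), 25, (12, 13)), ((1, 1), 28, (0, 28))], pos=200),
        make_site([((1, 1), 30, (0, 30)), ((0, 0), 25, (25, 0)), ((0, 0), 28, (28, 0))], pos=300),
    ]
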