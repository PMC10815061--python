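import pytest

from ibdkit import (GenotypeCall, SimConfig, SiteRecord, gwc_like_pedigree,
                    simulate_family)


@pytest.fixture(scope="session")
def gwc():
    """Three-generation pedigree with 4 affected + 1 unaffected sequenced."""
    ped, sequenced = gwc_like_pedigree()
    return ped, sequenced


@pytest.fixture(scope="session")
def small_sim():
    """A 3 Mb family simulation, small enough for per-test reuse."""
    return simulate_family(SimConfig(seed=5, chrom_length_bp=3_000_000))


@pytest.fixture(scope="session")
def default_sim():
    """A full-size (20 Mb, ~13k SNVs, 30x) error-free family simulation."""
    return simulate_family(SimConfig(seed=42))


@pytest.fixture
def mkcall():
    """Factory for genotype calls with sensible read-model defaults."""

    def _make(gt, ad=None, dp="auto", gq=45):
        if gt is not None:
            gt = tuple(gt)
        if dp == "auto":
            dp = sum(ad) if ad is not None else None
        return GenotypeCall(allele_indices=gt, ad=None if ad is None else
                            tuple(ad), dp=dp, gq=gq)

    return _make


@pytest.fixture
def mksites(mkcall):
    """Factory for a sorted site stream over a two-sample pair.

    Takes a list of (pos, gt1, ad1, gt2, ad2) tuples; depths default to
    sum(ad).
    """

    def _make(rows, samples=("A", "B"), chrom="1"):
        records = []
        for pos, gt1, ad1, gt2, ad2 in rows:
            records.append(SiteRecord(
                chrom=chrom, pos=pos, ref="A", alt="G",
                calls={samples[0]: mkcall(gt1, ad1),
                       samples[1]: mkcall(gt2, ad2)}))
        return records

    return _make
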