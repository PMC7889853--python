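import pytest

from loopcraft.synthetic import (
    CDO_LOOP1,
    CDO_LOOP2,
    FixtureSpec,
    make_cdo_like_reference,
    make_cds,
    make_homolog_family,
)


@pytest.fixture(scope="session")
def cdo_ref():
    """Synthetic dioxygenase-like reference carrying the study anchor residues."""
    return make_cdo_like_reference()


@pytest.fixture(scope="session")
def cdo_cds(cdo_ref):
    return make_cds(cdo_ref, seed=11)


@pytest.fixture(scope="session")
def loops():
    return [CDO_LOOP1, CDO_LOOP2]


@pytest.fixture(scope="session")
def family(cdo_ref):
    """Homolog family around the reference, with engineered consensus
    mismatch/gap positions so that every generator has work to do."""
    spec = FixtureSpec(
        seed=7,
        consensus_mismatch_positions=(236, 278),
        consensus_gap_positions=(251,),
    )
    reference, alignment, regions = make_homolog_family(spec, reference=cdo_ref)
    return reference, alignment, regions
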