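import pytest

from trnafrag.io_preprocess import clip_adapter, filter_by_length
from trnafrag.simulate import FixtureSpec, make_toy_references, simulate_trf_reads
from trnafrag.trf_extract import run_trf_workflow

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def toy_refs(fixture_spec):
    return make_toy_references(fixture_spec)


@pytest.fixture(scope="session")
def reference_sets(toy_refs):
    return toy_refs.reference_sets()


@pytest.fixture(scope="session")
def simulated(fixture_spec, toy_refs):
    """(raw reads with adapter, truth table)."""
    return simulate_trf_reads(fixture_spec, toy_refs)


@pytest.fixture(scope="session")
def clipped_reads(fixture_spec, simulated):
    reads, _ = simulated
    return filter_by_length(clip_adapter(reads, fixture_spec.adapter))


@pytest.fixture(scope="session")
def trf_collection(clipped_reads, reference_sets):
    s = reference_sets
    return run_trf_workflow(
        clipped_reads, s["rRNA"], s["snoRNA_CD"], s["snoRNA_HACA"],
        s["non_edited"], s["cca_edited"], seed=FIXTURE_SEED,
    )
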