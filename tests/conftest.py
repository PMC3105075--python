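import pytest

from rumenmt.synthetic_data import (
    default_family_universe,
    default_taxonomy,
    generate_community,
    generate_hit_tables,
    generate_reads,
)


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def family_defs():
    return default_family_universe()


@pytest.fixture(scope="session")
def big_community():
    """A 100k-read zero-noise community at the emulated study conditions:
    ncRNA fraction 18.4%, coding GC 39.2%, ncRNA GC 51%."""
    contigs, truth = generate_community(
        n_contigs=300, gc_target=0.392, seed=42)
    reads, truth = generate_reads(
        contigs, truth, n_reads=100_000, read_len=108,
        ncrna_fraction=0.184, ncrna_gc=0.51, seed=43)
    alignment, domain, flags = generate_hit_tables(truth, seed=44)
    return {
        "contigs": contigs,
        "reads": reads,
        "truth": truth,
        "alignment": alignment,
        "domain": domain,
        "hmm_flags": flags,
    }
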