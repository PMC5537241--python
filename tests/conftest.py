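import warnings

import pytest

from satmethyl import (
    FamilyConfig,
    MethylationConfig,
    MonomerAlignment,
    SeqRecord,
    assign_methylation,
    build_consensus,
    generate_family,
    make_reads,
)

# Biopython 1.88 renamed the end-gap score attributes; the shim in
# methylation._bisulfite_aligner handles both spellings, silence the notice.
warnings.filterwarnings("ignore", message=".*end_gap_score.*")


@pytest.fixture
def toy_alignment() -> MonomerAlignment:
    return MonomerAlignment(
        (
            SeqRecord("SSU_m01", "ACGTACGTAC"),
            SeqRecord("SSU_m02", "ACGTACGTAC"),
            SeqRecord("SSU_m03", "ACGAACGTAC"),
        )
    )


@pytest.fixture(scope="session")
def default_family():
    """A seeded default-parameter family shared across read-only tests."""
    cfg = FamilyConfig(seed=11)
    ancestral, monomers = generate_family(cfg)
    return cfg, ancestral, monomers


@pytest.fixture(scope="session")
def methylated_dataset(default_family):
    """Family + methylation truth + bisulfite reads at default conditions."""
    _, ancestral, monomers = default_family
    mcfg = MethylationConfig(seed=23)
    maps = assign_methylation(monomers, mcfg)
    reads = make_reads(monomers, maps, mcfg)
    consensus = build_consensus(monomers)
    return ancestral, monomers, mcfg, maps, reads, consensus
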