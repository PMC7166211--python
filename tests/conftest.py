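import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from foxyloci.synthetic_locus import (
    build_diploid,
    build_promoter_haplotype,
    canonical_spec,
    simulate_reads,
)


@pytest.fixture(scope="session")
def quartet():
    """The four canonical promoter archetypes on one shared background."""
    return {kind: build_promoter_haplotype(canonical_spec(kind, seed=0))
            for kind in ("caco", "pn40024", "concord", "alba")}


@pytest.fixture(scope="session")
def te_alleles():
    return {kind: build_promoter_haplotype(canonical_spec(kind, seed=0))
            for kind in ("caco", "solo_ltr", "full_trim")}


@pytest.fixture(scope="session")
def het_reads():
    """30x error-free reads from a heterozygous (426-present/absent) diploid."""
    d = build_diploid("het", "concord", "caco", seed=0)
    return d, simulate_reads(d, coverage=30, seed=42)
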