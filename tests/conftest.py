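"""Shared fixtures: a small synthetic study reused across the suite."""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from famscan.profile_hmm import build_profile
from famscan.synth import make_fixture

# both types carry >= 2 groups, as in the real family
SMALL_GENES_PER_GROUP = {"Malpha": 3, "Mbeta": 2, "MIKCstar": 2, "MIKCc": 3}


@pytest.fixture(scope="session")
def study():
    """Reduced-scale study: 2 contigs x 100 kb, 8 family genes per species."""
    return make_fixture(
        seed=7, n_species=3, genes_per_group=SMALL_GENES_PER_GROUP,
        n_contigs=2, contig_length=100_000, decoy_gene_count=8,
        withheld_fraction=0.25,
    )


@pytest.fixture(scope="session")
def study_hmm(study):
    return build_profile(study.seed_alignment)
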