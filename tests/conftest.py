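import pandas as pd
import pytest

from hgcpipe import marker_screen as ms
from hgcpipe import synthetic_community as syn

PROFILE = {"surface": 0.002, "intermediate": 0.015, "deep": 0.30}


@pytest.fixture(scope="session")
def small_fixture():
    """3 carriers + 3 non-carriers over the 7-depth x 2-lifestyle design."""
    taxa = syn.profile_taxa(PROFILE, n_carriers=3, n_noncarriers=3)
    designs = syn.default_designs(genome_equivalents=50.0, noise_cv=0.1)
    return syn.build_community(taxa, designs, seed=11)


@pytest.fixture(scope="session")
def noisefree_fixture():
    """Same design with noise_cv = 0 for exact-recovery checks."""
    taxa = syn.profile_taxa(PROFILE, n_carriers=3, n_noncarriers=3)
    designs = syn.default_designs(genome_equivalents=50.0, noise_cv=0.0)
    return syn.build_community(taxa, designs, seed=11)


@pytest.fixture(scope="session")
def decoy_fixture(small_fixture):
    return syn.plant_decoys(small_fixture, n_paralogs=6, n_fragments=4, seed=12)


def candidates_from_fixture(fixture, evalues=None):
    """Turn a fixture's genes+proteins into CandidateGene objects."""
    evalues = evalues or {}
    return [
        ms.CandidateGene(
            gene_id=row.gene_id,
            contig_id=row.contig_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            aa_sequence=fixture.proteins[row.gene_id],
            evalue=evalues.get(row.gene_id),
        )
        for row in fixture.genes.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def decoy_candidates(decoy_fixture):
    return candidates_from_fixture(decoy_fixture)


def hgcA_truth_ids(fixture) -> set[str]:
    roles = fixture.truth.roles
    return set(roles.loc[roles["is_hgcA"], "gene_id"])
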