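"""Shared fixtures: the synthetic survey scenario, its profile HMM, and the
surveyed locus tables (built once per session — the scan is the slow part)."""

import pytest

from homeodyn.datasets import mammal_tree, table2_matrix
from homeodyn.hmm import HomeodomainAlignment, build_profile
from homeodyn.pipeline import survey_genome
from homeodyn.synthetic import default_fixture


@pytest.fixture(scope="session")
def fixture():
    return default_fixture()


@pytest.fixture(scope="session")
def reference(fixture):
    return fixture.reference


@pytest.fixture(scope="session")
def ref_alignment(reference):
    return HomeodomainAlignment(
        rows=list(reference.families.values()), labels=list(reference.families)
    )


@pytest.fixture(scope="session")
def hmm(ref_alignment):
    return build_profile(ref_alignment)


@pytest.fixture(scope="session")
def surveyed(fixture, hmm, reference):
    """Classified locus tables for all three synthetic species."""
    return {
        sp: survey_genome({sp: genome}, hmm, reference, species=sp)
        for sp, genome in fixture.genomes.items()
    }


@pytest.fixture(scope="session")
def tree():
    return mammal_tree()


@pytest.fixture(scope="session")
def table2():
    return table2_matrix()
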