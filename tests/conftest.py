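import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clockortho.records import SequenceRecord, SpeciesDatabase
from clockortho.simulate import simulate_family

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def prot(gene_id: str, species: str, residues: str) -> SequenceRecord:
    return SequenceRecord(id=gene_id, species=species, moltype="protein",
                          residues=residues)


def cds(gene_id: str, species: str, residues: str) -> SequenceRecord:
    return SequenceRecord(id=gene_id, species=species, moltype="cds",
                          residues=residues, complete=len(residues) % 3 == 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def single_copy_family():
    """Six species, no duplications or losses: every cross-species pair is
    an orthologue."""
    return simulate_family(dup_rate=0.0, loss_rate=0.0, seed=42,
                           root_cds_length=600)


@pytest.fixture(scope="session")
def duplicated_family():
    """A family with at least one duplication event (fixed seed)."""
    for seed in range(100):
        hist, genes = simulate_family(dup_rate=0.6, loss_rate=0.0, seed=seed,
                                      root_cds_length=600)
        if any(ev[0] == "duplication" for ev in hist.events) and len(genes) > 6:
            return hist, genes
    raise RuntimeError("no duplication found in seed range")


def databases_for(genes):
    dbs = {}
    for g in genes:
        dbs.setdefault(g.species, SpeciesDatabase(g.species)).add(g.cds)
    return dbs
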