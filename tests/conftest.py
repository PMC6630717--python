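"""Shared fixtures: one small synthetic study reused across test modules."""

import pytest

from domprof import synthetic_data as sd


@pytest.fixture(scope="session")
def study():
    """A 8-species study at the package's default generator settings."""
    return sd.simulate_study(n_leaves=8, seed=2)


@pytest.fixture(scope="session")
def genomes_and_proteomes(study):
    genomes, proteomes = {}, {}
    for sp in study.species:
        g, p = sd.emit_genome(
            study.repertoires[sp],
            study.vocabulary,
            coding_fraction=study.params["coding_fraction"],
            seed=sd.child_seed(2, "genome:" + sp),
            species_id=sp,
        )
        genomes[sp] = g
        proteomes[sp] = p
    return genomes, proteomes


@pytest.fixture(scope="session")
def small_vocabulary():
    return sd.make_vocabulary(n_domains=20, seed=11)
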