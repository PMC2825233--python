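import pytest

from geoclade.simulate import SimulationParams, simulate_clade


def write_fasta(path, records):
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")
    return path


@pytest.fixture(scope="session")
def small_clade():
    """A 25-family clade at the default study conditions, no transfer."""
    return simulate_clade(SimulationParams(n_families=25, cytochrome_fraction=0.2, seed=11))


@pytest.fixture(scope="session")
def zero_divergence_clade():
    """All branch lengths 0: every family is one identical copy per genome."""
    tree = "(((Gs:0,Gm:0):0,((Gu:0,Gf:0):0,Gb:0):0):0,Gl:0);"
    return simulate_clade(
        SimulationParams(species_tree=tree, n_families=10, cytochrome_fraction=0.2, seed=7)
    )
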