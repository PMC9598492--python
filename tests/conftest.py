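import pathlib

import pytest

from wgdpop import io_formats, synthetic_data


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("toys")
    synthetic_data.make_toy_fixtures(d)
    return d


@pytest.fixture(scope="session")
def small_wgd_sim(tmp_path_factory):
    """A small duplicated genome written to disk and read back."""
    spec = synthetic_data.WGDSimSpec(
        n_chromosomes=3, genes_per_chromosome=30, codons_per_gene=60, seed=2
    )
    sim = synthetic_data.simulate_wgd_genome(spec)
    d = tmp_path_factory.mktemp("wgd_sim")
    paths = sim.write(d)
    genome = io_formats.read_fasta(paths["fasta"])
    catalog = io_formats.read_gff3(paths["gff3"], genome)
    return {"spec": spec, "sim": sim, "paths": paths, "genome": genome, "catalog": catalog}


@pytest.fixture(scope="session")
def pop_sim():
    """The study-scale admixed panel: 85 samples, 2500 loci, two populations."""
    return synthetic_data.simulate_admixed_genotypes(synthetic_data.PopSimSpec(seed=13))
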