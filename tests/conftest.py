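import pytest

from speciesgap import simgen, pairwise


@pytest.fixture(scope="session")
def small_pair():
    """A 100-gene pair at 5% divergence with moderate purifying selection."""
    config = simgen.PairSimConfig(n_genes=100, gene_length_mean=300,
                                  divergence=0.05, omega=0.3, seed=7)
    genome_a, genome_b, truth = simgen.simulate_pair(config)
    return genome_a, genome_b, truth, config


@pytest.fixture(scope="session")
def small_pair_result(small_pair):
    genome_a, genome_b, _truth, _config = small_pair
    return pairwise.compare_genomes(genome_a, genome_b)


@pytest.fixture(scope="session")
def gap_population():
    """12 genomes, 3 species, within-identity >= 97%, between <= 90%."""
    spec = simgen.PopulationSpec(n_species=3, genomes_per_species=4,
                                 within_identity_range=(0.97, 0.995),
                                 between_identity_max=0.90,
                                 n_genes=60, gene_length_mean=300, seed=1)
    return simgen.generate_population(spec), spec


@pytest.fixture(scope="session")
def gap_population_anis(gap_population):
    """Gene-based ANI (percent) for every pair of the gap population."""
    import itertools
    (genomes, _labels, _truth), _spec = gap_population
    params = pairwise.PairwiseParams(codon_alignments=False)
    anis = {}
    for ga, gb in itertools.combinations(genomes, 2):
        res = pairwise.compare_genomes(ga, gb, params)
        key = tuple(sorted((ga.genome_id, gb.genome_id)))
        anis[key] = 100.0 * res.ani if res.ani is not None else 0.0
    return anis
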