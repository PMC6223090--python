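import numpy as np
import pytest

from tfburden.simulate import (
    SimConfig,
    genome_context_cache,
    simulate_genome,
    simulate_pileups,
    simulate_sites_and_mutations,
    simulate_topology_expression,
)


SMALL = dict(
    genome_length=1_500_000,
    n_sites=600,
    n_donors=20,
    n_genes=400,
    background_rate=2.5e-3,
    seed=4,
)


@pytest.fixture(scope="session")
def small_world():
    """One small synthetic study shared across tests: genome, sites with a
    planted 1.25x core enrichment, loops/TADs/genes, and pileups."""
    cfg = SimConfig(**SMALL)
    genome = simulate_genome(cfg)
    sites, mutations, truth = simulate_sites_and_mutations(cfg, genome)
    loops, tads, genes = simulate_topology_expression(cfg, sites, truth, genome)
    pileups, candidates, pileup_truth = simulate_pileups(cfg, truth, mutations)
    return dict(
        config=cfg, genome=genome, sites=sites, mutations=mutations, truth=truth,
        loops=loops, tads=tads, genes=genes, pileups=pileups, candidates=candidates,
    )


@pytest.fixture(scope="session")
def null_world():
    """Same scale but with no planted core enrichment (factor 1.0)."""
    cfg = SimConfig(**{**SMALL, "seed": 9}, core_enrichment=1.0)
    genome = simulate_genome(cfg)
    cache = genome_context_cache(genome)
    sites, mutations, truth = simulate_sites_and_mutations(
        cfg, genome, context_cache=cache
    )
    return dict(config=cfg, genome=genome, sites=sites, mutations=mutations,
                truth=truth, cache=cache)


@pytest.fixture(scope="session")
def small_windows(small_world):
    from tfburden.windows import build_analysis_windows

    return build_analysis_windows(small_world["sites"], flank=1000)
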