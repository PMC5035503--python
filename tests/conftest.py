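"""Shared simulated populations (session-scoped: simulation is the costly part)."""

import numpy as np
import pytest

from flockimpute import simulate as sim
from flockimpute.panels import informative_panels


@pytest.fixture(scope="session")
def multibreed():
    """Default multi-breed population: purebreds, composites, one unrelated
    terminal group; 3 chromosomes x 500 SNPs; nested low/mid/high panels."""
    plan = sim.default_breed_plan(scale=1.0)
    gmap = sim.uniform_genetic_map(3, 500)
    pop = sim.simulate_population(plan, gmap, seed=11)
    panels = informative_panels(pop.marker_map, pop.genotypes,
                                {"low": 150, "mid": 450, "high": 1500})
    return pop, panels


@pytest.fixture(scope="session")
def multibreed_groups(multibreed):
    """Helper index: animals by dominant breed, sorted by (year, id)."""
    pop, _ = multibreed
    ped = pop.pedigree
    dom = ped.dominant_breed()
    years = dict(zip(ped.table["animal"], ped.table["year"]))
    groups = {}
    for a in ped.animals:
        groups.setdefault(dom[a], []).append(a)
    for b in groups:
        groups[b].sort(key=lambda a: (years[a], a))
    return groups


@pytest.fixture(scope="session")
def rare_population():
    """Within-breed rare-allele workflow population: one breed, deep
    pedigree, 5500 animals x 2100 SNPs so union allele counts reach the
    singleton range (MAF 1e-4) needed for the rarest accuracy bin."""
    plan = sim.BreedPlan(
        breeds=["romney"], divergence={"romney": 0.0}, founders={"romney": 500},
        crosses=[[sim.CrossRule("romney", "romney", 1600)],
                 [sim.CrossRule("romney", "romney", 1600)],
                 [sim.CrossRule("romney", "romney", 1800)]])
    gmap = sim.uniform_genetic_map(3, 700)
    pop = sim.simulate_population(plan, gmap, seed=2)
    low, high = informative_panels(pop.marker_map, pop.genotypes,
                                   {"low": 210, "high": 2100})
    years = dict(zip(pop.pedigree.table["animal"], pop.pedigree.table["year"]))
    order = sorted(pop.pedigree.animals, key=lambda a: (years[a], a))
    reference, targets = order[:-1000], order[-1000:]
    return pop, low, high, reference, targets


@pytest.fixture(scope="session")
def pedigree_recovery_population():
    """Two diverged breeds at 10,000 SNPs: parent-offspring pairs within one
    breed, and a weakly related terminal breed for cross-breed contrasts.

    Founders are drawn without the ancestral-pool LD model (``ld=None``):
    the classical pedigree expectations (parent-offspring G of 0.5 against
    an unrelated base) only hold when founders are themselves unrelated."""
    plan = sim.BreedPlan(
        breeds=["romney", "primera"],
        divergence={"romney": 0.05, "primera": 0.3},
        founders={"romney": 40, "primera": 40},
        crosses=[[sim.CrossRule("romney", "romney", 40),
                  sim.CrossRule("primera", "primera", 40)]])
    gmap = sim.uniform_genetic_map(4, 2500)
    return sim.simulate_population(plan, gmap, seed=7, ld=None)


@pytest.fixture(scope="session")
def founder_only_population():
    """Two breeds of unrelated founders, no LD: genotypes are independent
    Hardy-Weinberg draws, so binomial error propagation is exact."""
    plan = sim.BreedPlan(
        breeds=["romney", "coopworth"],
        divergence={"romney": 0.05, "coopworth": 0.05},
        founders={"romney": 150, "coopworth": 150},
        crosses=[])
    gmap = sim.uniform_genetic_map(2, 1000)
    return sim.simulate_population(plan, gmap, seed=5, ld=None)
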