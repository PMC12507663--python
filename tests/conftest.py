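"""Shared fixtures: a small fast cohort for unit tests and the full default
cohort (with its pipeline report) for the end-to-end checks."""

import numpy as np
import pytest

from xenopop.pipeline import PipelineConfig, run_pipeline
from xenopop.synthetic_colonies import (
    CompositionRow,
    SimScenario,
    simulate_scenario,
)
from xenopop.variant_store import CohortMatrix, IndividualMeta, VariantSite


def small_composition():
    return [
        CompositionRow("queen", "ibericus", "none", 6),
        CompositionRow("male", "ibericus", "none", 4),
        CompositionRow("male", "structor", "none", 8),
        CompositionRow("worker", "ibericus", "clonal", 10),
        CompositionRow("worker", "ibericus", "wild", 4),
        CompositionRow("male", "structor", "clonal", 5),
        CompositionRow("egg", "ibericus", "clonal", 2),
        CompositionRow("egg", "ibericus", "clonal", 1, androgenetic=True),
        CompositionRow("spermatheca", "ibericus", "clonal", 1),
    ]


def small_scenario(**overrides):
    """Desk-miniature cohort: short genome, slightly elevated divergence so
    lineages stay separable over 3.6 kb."""
    kw = dict(
        n_genes=20,
        gene_length_codons=60,
        fixed_diff_density=0.02,
        clonal_divergence=0.005,
        composition=small_composition(),
        seed=777,
    )
    kw.update(overrides)
    return SimScenario(**kw)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_scenario(small_scenario())


@pytest.fixture(scope="session")
def small_report(small_sim):
    cfg = PipelineConfig(
        scenario=small_sim.scenario, seed=3, n_bootstrap=50, diversity_bootstrap=50
    )
    return run_pipeline(cfg, sim=small_sim)


@pytest.fixture(scope="session")
def default_sim():
    """The shipped study-scale cohort (164 F1 workers, 127 controls, 24
    clonal + 53 wild males)."""
    return simulate_scenario(SimScenario())


@pytest.fixture(scope="session")
def default_report(default_sim):
    cfg = PipelineConfig(scenario=default_sim.scenario, seed=1)
    return run_pipeline(cfg, sim=default_sim)


def make_cohort(genotypes, depth=30, quality=60, metas=None, sites=None):
    """Hand-built cohort from a (sites x individuals) list of allele pairs;
    None means a missing call."""
    n_sites = len(genotypes)
    n_ind = len(genotypes[0])
    if metas is None:
        metas = [
            IndividualMeta(f"ind{j}", "c1", "queen", "ibericus", 2) for j in range(n_ind)
        ]
    if sites is None:
        sites = [
            VariantSite("chr1", i + 1, "A", ("C",)) for i in range(n_sites)
        ]
    alleles = np.full((n_sites, n_ind, 2), -1, dtype=np.int16)
    for i, row in enumerate(genotypes):
        for j, gt in enumerate(row):
            if gt is not None:
                alleles[i, j] = gt
    dep = np.broadcast_to(np.asarray(depth), (n_sites, n_ind)).astype(np.int32).copy()
    qual = np.broadcast_to(np.asarray(quality, dtype=float), (n_sites, n_ind)).copy()
    return CohortMatrix(sites=sites, individuals=metas, alleles=alleles, depth=dep, quality=qual)
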