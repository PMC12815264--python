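"""Shared fixtures: the default synthetic dataset and derived products.

Everything heavy (sequence simulation, gene clustering, presence calling) is
computed once per session; individual tests consume read-only views.
"""

from __future__ import annotations

import warnings

import pytest

from hgtcooc import association, cooccurrence, detect
from hgtcooc.simulate import simulate_dataset

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def dataset():
    """Default 50-genome fixture with 40 detectable planted transfers."""
    return simulate_dataset(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def genes(dataset):
    return {g.gene_id: g for gm in dataset.genomes for g in gm.genes()}


@pytest.fixture(scope="session")
def taxonomy(dataset):
    return {g.genome_id: g.taxonomy for g in dataset.genomes}


@pytest.fixture(scope="session")
def contig_lengths(dataset):
    return {c.contig_id: c.length for gm in dataset.genomes for c in gm.contigs}


@pytest.fixture(scope="session")
def clusters(dataset, genes):
    return detect.cluster_genes(list(genes.values()))


@pytest.fixture(scope="session")
def rbh_events(clusters, genes, taxonomy, contig_lengths):
    return detect.call_rbh_hgt(clusters, genes, taxonomy, contig_lengths)


@pytest.fixture(scope="session")
def presence_bundle(dataset):
    pres = cooccurrence.call_presence(dataset.samples.breadth, dataset.samples.rpkm)
    retained, empty = cooccurrence.filter_prevalence(pres.present)
    present = cooccurrence.drop_empty_samples(pres.present[retained])
    return pres, retained, present


@pytest.fixture(scope="session")
def cooc_results(presence_bundle):
    _, _, present = presence_bundle
    return cooccurrence.hypergeom_cooccurrence(present)


@pytest.fixture(scope="session")
def pair_table(dataset, rbh_events, presence_bundle, cooc_results, taxonomy):
    pres, retained, present = presence_bundle
    fracs = cooccurrence.classify_size_fraction(
        present, pres.rpkm.loc[present.index, retained], dataset.samples.fractions
    )
    env_medians = association.genome_env_medians(present, dataset.samples.env)
    return association.build_pair_table(
        rbh_events,
        cooc_results,
        dataset.patristic,
        env_medians,
        fracs,
        taxonomy,
        retained_genomes=retained,
    )


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
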