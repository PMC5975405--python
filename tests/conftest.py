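"""Shared fixtures: one small synthetic study reused across test modules."""

from types import SimpleNamespace

import pytest

from spermethyl import digest_annotate, medip_diff, rrbs_diff, simgen


@pytest.fixture(scope="session")
def study():
    """A seeded synthetic study: genome, annotations, latent methylome, RR genome."""
    genome, ann = simgen.generate_genome(seed=1)
    methylome = simgen.plant_methylome(genome, ann, seed=101)
    rr = digest_annotate.build_rr_genome(genome)
    return SimpleNamespace(genome=genome, annotations=ann, methylome=methylome, rr=rr)


@pytest.fixture(scope="session")
def rrbs_study(study):
    """RRBS branch inputs derived from the shared study."""
    counts = simgen.simulate_rrbs_counts(study.methylome, study.rr, seed=201)
    sample_map = simgen.rrbs_sample_map()
    table = rrbs_diff.build_cpg_table(counts, sample_map)
    kept, dropped, over = rrbs_diff.filter_by_coverage(table)
    return SimpleNamespace(
        counts=counts, sample_map=sample_map, table=table,
        kept=kept, dropped=dropped, over=over,
    )


@pytest.fixture(scope="session")
def medip_study(study):
    """MeDIP branch inputs derived from the shared study."""
    probes = simgen.simulate_medip_probes(study.methylome, study.annotations, seed=301)
    tissue_of = simgen.medip_sample_map()
    enrichment = medip_diff.call_enriched_probes(probes, tissue_of)
    regions = medip_diff.find_regions_of_interest(enrichment)
    return SimpleNamespace(
        probes=probes, tissue_of=tissue_of, enrichment=enrichment, regions=regions,
    )
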