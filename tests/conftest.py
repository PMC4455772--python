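import pytest
from hypothesis import settings

from probelift import filters as fl
from probelift import synthetic_data as syn

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

COHORT_SEED = 1
COHORT_N = 400


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic study: 400 probes, 12 samples, seed 1."""
    return syn.generate_cohort(COHORT_SEED, n_probes=COHORT_N)


@pytest.fixture(scope="session")
def annotated(cohort):
    """Annotation records for the default cohort (full pipeline, default
    scoring and filter settings)."""
    return fl.annotate_probe_set(
        cohort.probes,
        cohort.genome,
        ortholog_map=cohort.ortholog_map,
        gene_bed=cohort.gene_bed,
    )


@pytest.fixture(scope="session")
def covered_meth(cohort):
    """Per-sample calls after the >=10x coverage filter, as read_meth_table
    would deliver them."""
    return {
        s: [c for c in calls if c.total_count >= 10]
        for s, calls in cohort.meth.items()
    }
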