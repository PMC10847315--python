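import pytest
from hypothesis import HealthCheck, settings

from hlasplice import junction_classifier as jc
from hlasplice import scenarios as sc
from hlasplice import synthetic_data as sd

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """The four-allele fixture used throughout the suite."""
    return sd.make_fixture_alleles(42)


@pytest.fixture(scope="session")
def sample2_run(bundle):
    """Full sample-2 analog simulation (50k pairs) with classification.

    Shared across the recovery tests; this is the experiment whose per-allele
    and pooled junction profiles must reproduce the installed splice-outcome
    probabilities.
    """
    spec = sc.sample2_spec()
    alleles = {n: bundle.alleles[n] for n in spec.abundances}
    discs = {n: bundle.discriminators[n] for n in spec.abundances}
    pool = sc.recovery_pool(alleles, spec)
    pairs, truth = sd.simulate_read_pairs(pool, spec)
    calls = jc.classify_pairs(pairs, bundle.gene_model, alleles, discriminators=discs)
    pooled_calls = jc.classify_pairs(pairs, bundle.gene_model, alleles)
    return {
        "spec": spec,
        "alleles": alleles,
        "discriminators": discs,
        "pool": pool,
        "pairs": pairs,
        "truth": truth,
        "calls": calls,
        "pooled_calls": pooled_calls,
        "table": jc.tabulate(calls),
        "pooled_table": jc.tabulate(pooled_calls),
    }


def cell(table, allele, exon_end, category):
    """(proportion, n_classifiable) of one junction-table cell."""
    sub = table[
        (table["allele"] == allele)
        & (table["exon_end"] == exon_end)
        & (table["category"] == category)
    ]
    if sub.empty:
        n = table[(table["allele"] == allele) & (table["exon_end"] == exon_end)]
        return 0.0, int(n["n_classifiable"].iloc[0]) if not n.empty else 0
    return float(sub["proportion"].iloc[0]), int(sub["n_classifiable"].iloc[0])
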