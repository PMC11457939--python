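import pandas as pd
import pytest

from utailor import make_reference, wild_type_profile
from utailor.benchmarks import run_srna_pipeline
from utailor.simulate import simulate_srna_reads
from utailor.tailcaller import FeatureLookup, GenomeIndex


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(30, 8, 8, chrom_len=120_000, seed=11)


@pytest.fixture(scope="session")
def genome_index(small_ref):
    return GenomeIndex(small_ref)


@pytest.fixture(scope="session")
def feature_lookup(small_ref):
    return FeatureLookup(small_ref)


@pytest.fixture(scope="session")
def wt_profile():
    return wild_type_profile(
        n_species_per_class={"siRNA": 25, "miRNA": 8, "piRNA": 8},
        reads_per_replicate=6_000,
        n_replicates=3,
        seed=5,
    )


@pytest.fixture(scope="session")
def wt_sim(small_ref, wt_profile):
    return simulate_srna_reads(small_ref, wt_profile)


@pytest.fixture(scope="session")
def wt_calls(small_ref, wt_profile) -> pd.DataFrame:
    calls, _truth = run_srna_pipeline(small_ref, wt_profile)
    return calls
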