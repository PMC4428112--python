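import pytest
from hypothesis import HealthCheck, settings

import discrimer as d

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_index():
    """Two-target toy: T1='ACGTACGT', T2='ACGTTTTT', k=4.

    Discriminative sets are T1:{CGTA,GTAC}, T2:{AACG,AAAC,AAAA}; the shared
    ACGT is removed.
    """
    table = d.TargetTable(labels=["T1", "T2"], seq_to_target={"s1": "T1", "s2": "T2"})
    return d.build_index([("ACGTACGT", "T1"), ("ACGTTTTT", "T2")], table, 4)


@pytest.fixture(scope="session")
def clean_world():
    """10 targets x 100 kb, no shared blocks; 10,000 error-free 100-bp reads; k=31.

    The idealized regime where every read maps uniquely: full-mode
    classification should recover every label with confidence 1.0.
    """
    community = d.make_community(10, 100_000, seed=42)
    table = community.target_table()
    index = d.build_index([(s, l) for l, s in community.genomes], table, 31)
    reads, truth = d.sample_reads(community, 10_000, 100, 0.0, seed=43)
    return {
        "community": community,
        "table": table,
        "index": index,
        "reads": reads,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def clean_world_full_results(clean_world):
    return d.classify_objects(clean_world["reads"], clean_world["index"], "full")
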