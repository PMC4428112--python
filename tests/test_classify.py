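import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracle_utils import brute_discriminative, brute_hits

import discrimer as d
from discrimer.errors import ConfigurationError


def random_community(seed, n_targets=(2, 5), length=(100, 600)):
    rng = random.Random(seed)
    labels = [f"T{i}" for i in range(rng.randint(*n_targets))]
    genomes = [
        (lab, "".join(rng.choice("ACGT") for _ in range(rng.randint(*length))))
        for lab in labels
    ]
    return genomes


class TestFullMode:
    def test_hit_vector_and_confidence_on_toy(self, toy_index):
        r = d.classify_full("CGTACG", toy_index, "obj1")
        assert r.hits == {"T1": 3, "T2": 0}
        assert (r.assignment, r.h1, r.h2, r.confidence) == ("T1", 3, 0, 1.0)
        assert not r.tie

    def test_no_hits_is_unassigned(self, toy_index):
        r = d.classify_full("GGGGGG", toy_index)
        assert r.assignment == d.UNASSIGNED
        assert r.confidence is None and r.h1 == 0
        assert r.hits == {"T1": 0, "T2": 0}

    def test_object_shorter_than_k(self, toy_index):
        r = d.classify_full("AC", toy_index)
        assert r.n_kmers == 0 and r.assignment == d.UNASSIGNED

    def test_confidence_formula(self):
        t = d.TargetTable(labels=["T1", "T2"])
        idx = d.build_index([("AAAA", "T1"), ("CCCC", "T2")], t, 4)
        # read with three T1 windows and one T2 window
        r = d.classify_full("AAAAAACCCC", idx)
        assert (r.h1, r.h2) == (3, 1)
        assert r.confidence == pytest.approx(0.75)

    def test_tie_goes_to_smallest_target_id_at_confidence_half(self):
        t = d.TargetTable(labels=["T2x", "T1x"])
        idx = d.build_index([("AAAA", "T2x"), ("CCCC", "T1x")], t, 4)
        r = d.classify_full("AAAACCCC", idx)
        assert r.tie and r.confidence == 0.5
        assert r.assignment == "T2x"  # first label in the table, smallest id

    def test_rejects_sampled_index(self, toy_index):
        half = d.sample_index(toy_index, "default_half")
        with pytest.raises(ConfigurationError):
            d.classify_full("ACGT", half)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_hit_counts_equal_brute_force(self, seed):
        genomes = random_community(seed)
        k = random.Random(seed + 1).choice([4, 5, 7, 9])
        t = d.TargetTable(labels=[lab for lab, _ in genomes])
        idx = d.build_index([(s, l) for l, s in genomes], t, k)
        disc = brute_discriminative(genomes, k)
        rng = random.Random(seed + 2)
        for _ in range(5):
            lab, seq = genomes[rng.randrange(len(genomes))]
            start = rng.randrange(max(1, len(seq) - 60))
            read = seq[start : start + 60]
            r = d.classify_full(read, idx)
            assert r.hits == brute_hits(read, k, disc)

    def test_strand_invariance(self, toy_index):
        fwd = d.classify_full("CGTACGAA", toy_index)
        rev = d.classify_full(d.revcomp_seq("CGTACGAA"), toy_index)
        assert fwd.hits == rev.hits


class TestDefaultMode:
    def test_early_stop_after_half_of_possible_hits(self, toy_index):
        half = d.sample_index(toy_index, "default_half")
        # T1's half-sampled set keeps CGTA (rank 0); object below has 6 valid
        # windows of which the CGTA windows suffice to reach ceil(6/2)=3
        obj = "CGTACGTACG"  # windows: CGTA GTAC TACG ACGT CGTA GTAC -> canonical CGTA x3
        r = d.classify_default(obj, half)
        assert r.assignment == "T1"
        assert r.h1 >= 3

    def test_requires_half_sampled_index(self, toy_index):
        with pytest.raises(ConfigurationError):
            d.classify_default("ACGT", toy_index)

    def test_empty_hit_object_is_unassigned(self, toy_index):
        half = d.sample_index(toy_index, "default_half")
        r = d.classify_default("GGGGGGGG", half)
        assert r.assignment == d.UNASSIGNED

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_never_contradicts_a_unanimous_full_assignment(self, seed):
        genomes = random_community(seed, n_targets=(2, 4), length=(80, 300))
        k = 5
        t = d.TargetTable(labels=[lab for lab, _ in genomes])
        idx = d.build_index([(s, l) for l, s in genomes], t, k)
        half = d.sample_index(idx, "default_half")
        rng = random.Random(seed + 9)
        for _ in range(5):
            lab, seq = genomes[rng.randrange(len(genomes))]
            start = rng.randrange(max(1, len(seq) - 50))
            read = seq[start : start + 50]
            full = d.classify_full(read, idx)
            fast = d.classify_default(read, half)
            if full.confidence == 1.0:
                assert fast.assignment in (full.assignment, d.UNASSIGNED)


class TestExpressMode:
    def test_queries_only_non_overlapping_positions(self, toy_index):
        # length 8, k=4: only positions 0 and 4 are queried. GTAC sits at
        # positions 1-3 only, so it must not be seen.
        r = d.classify_express("AGTACGGG", toy_index)
        assert r.assignment == d.UNASSIGNED

    def test_first_hit_wins(self, toy_index):
        # position 0 window AACG belongs to T2; T1 k-mers later are ignored
        r = d.classify_express("AACGCGTACGTA", toy_index)
        assert r.assignment == "T2"
        assert (r.h1, r.h2) == (1, 0)
        assert r.confidence is None

    def test_works_on_sampled_indexes(self, toy_index):
        half = d.sample_index(toy_index, "default_half")
        r = d.classify_express("CGTACGTA", half)
        assert r.assignment in ("T1", d.UNASSIGNED)

    def test_at_most_one_target_can_be_hit_from_a_pure_read(self, toy_index):
        # discriminative sets are disjoint, so enumerating every stride
        # window of a read drawn from one target hits at most one target
        for read in ("CGTACGTACGTA", "AACGAAACAAAA"):
            hit_targets = set()
            for pos, code in d.extract_kmers(read, 4):
                if pos % 4 == 0 and code in toy_index.entries:
                    hit_targets.add(toy_index.entries[code][0])
            assert len(hit_targets) <= 1


@pytest.fixture(scope="module")
def light_world():
    rng = random.Random(11)
    genomes = [
        (lab, "".join(rng.choice("ACGT") for _ in range(1000)))
        for lab in ("T1", "T2")
    ]
    t = d.TargetTable(labels=["T1", "T2"])
    pairs = [(s, l) for l, s in genomes]
    idx = d.build_index(pairs, t, 27)
    light = d.sample_index(idx, "light_stride", targets=pairs)
    return genomes, light


class TestLightMode:
    def test_sampled_kmer_is_found(self, light_world):
        genomes, light = light_world
        read = genomes[0][1][0:60]  # covers sampled position 0
        r = d.classify_light(read, light)
        assert r.assignment == "T1"

    def test_read_inside_a_skipped_window_is_unassigned(self, light_world):
        genomes, light = light_world
        # positions 30..95 avoid every sampled start (0, 135, ...)
        read = genomes[0][1][30:96]
        r = d.classify_light(read, light)
        assert r.assignment == d.UNASSIGNED

    def test_requires_light_index(self, toy_index):
        with pytest.raises(ConfigurationError):
            d.classify_light("ACGT" * 10, toy_index)

    def test_empty_object_is_unassigned(self, light_world):
        _genomes, light = light_world
        assert d.classify_light("", light).assignment == d.UNASSIGNED


def make_result(object_id, assignment, confidence):
    h1 = 4 if assignment != d.UNASSIGNED else 0
    return d.ObjectResult(
        object_id=object_id,
        n_kmers=10,
        h1=h1,
        h2=0,
        assignment=assignment,
        confidence=confidence,
        tie=False,
    )


class TestEvaluate:
    def test_precision_sensitivity_assignment_rate(self):
        results = (
            [make_result(f"r{i}", "A", 1.0) for i in range(8)]
            + [make_result("r8", "B", 1.0)]
            + [make_result("r9", d.UNASSIGNED, None)]
        )
        truth = {f"r{i}": "A" for i in range(10)}
        rep = d.evaluate(results, truth)
        assert rep.precision == pytest.approx(8 / 9)
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.assignment_rate == pytest.approx(0.9)
        assert rep.sensitivity == pytest.approx(rep.precision * rep.assignment_rate)

    def test_all_correct(self):
        results = [make_result(f"r{i}", "A", 1.0) for i in range(5)]
        rep = d.evaluate(results, {f"r{i}": "A" for i in range(5)})
        assert rep.precision == rep.sensitivity == 1.0

    def test_confidence_exactly_at_threshold_is_low_confidence(self):
        results = [
            make_result("r0", "A", 0.75),
            make_result("r1", "A", 0.7501),
        ]
        rep = d.evaluate(results, {"r0": "A", "r1": "A"})
        assert rep.high_conf_rate == pytest.approx(0.5)

    def test_zero_assigned_warns_and_reports_nan(self):
        results = [make_result("r0", d.UNASSIGNED, None)]
        with pytest.warns(UserWarning):
            rep = d.evaluate(results, {"r0": "A"})
        assert math.isnan(rep.precision)

    def test_unknown_object_id_is_an_error(self):
        with pytest.raises(KeyError, match="mystery"):
            d.evaluate([make_result("mystery", "A", 1.0)], {"r0": "A"})


class TestSharedRegionBlindness:
    def test_read_inside_a_duplicated_segment_gets_zero_hits(self):
        rng = random.Random(3)
        block = "".join(rng.choice("ACGT") for _ in range(200))
        g1 = "".join(rng.choice("ACGT") for _ in range(300)) + block
        g2 = block + "".join(rng.choice("ACGT") for _ in range(300))
        t = d.TargetTable(labels=["T1", "T2"])
        idx = d.build_index([(g1, "T1"), (g2, "T2")], t, 21)
        read = block[50:150]
        r = d.classify_full(read, idx)
        assert r.assignment == d.UNASSIGNED
        assert r.hits == {"T1": 0, "T2": 0}


class TestWorkers:
    def test_results_independent_of_worker_count(self, toy_index):
        objects = [(f"o{i}", s) for i, s in enumerate(["CGTACG", "GGGG", "AAAAAA", "ACGTTT"])]
        seq_results = d.classify_objects(objects, toy_index, "full", workers=1)
        par_results = d.classify_objects(objects, toy_index, "full", workers=3)
        assert seq_results == par_results
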