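"""Error injection, dereplication, filters and OTU clustering."""

import collections

import numpy as np
import pandas as pd
import pytest

import recurra as r
from recurra.seqsim import (
    ErrorSimConfig,
    dereplicate_by_sample,
    encode_sequences,
    inject_errors_array,
)


@pytest.fixture
def refs():
    return r.simulate_reference_sequences([f"ref{i}" for i in range(5)], 60, 11)


class TestInjectErrors:
    def test_zero_error_reads_match_templates(self, refs):
        cfg = ErrorSimConfig(refs, read_length=60, depth=200, error_rate=0.0, seed=0)
        reads, templates = inject_errors_array(cfg)
        arr = encode_sequences([s[:60] for s in refs.sequences])
        assert (reads == arr[templates]).all()

    def test_mean_mismatches_match_binomial_expectation(self, refs):
        eps, L, depth = 0.005, 60, 20000
        cfg = ErrorSimConfig(refs, read_length=L, depth=depth, error_rate=eps, seed=1)
        reads, templates = inject_errors_array(cfg)
        arr = encode_sequences([s[:L] for s in refs.sequences])
        mism = (reads != arr[templates]).sum(axis=1)
        expect = L * eps
        se = np.sqrt(L * eps * (1 - eps) / depth)
        assert abs(mism.mean() - expect) <= 3 * se

    def test_depth_one(self, refs):
        out = r.inject_errors(ErrorSimConfig(refs, 60, 1, 0.1, seed=2))
        assert len(out) == 1

    def test_invalid_error_rate_rejected(self, refs):
        with pytest.raises(ValueError):
            ErrorSimConfig(refs, 60, 10, 1.0)

    def test_short_reference_rejected(self, refs):
        with pytest.raises(ValueError, match="shorter"):
            ErrorSimConfig(refs, 100, 10, 0.0)

    def test_deterministic_per_seed(self, refs):
        a = r.inject_errors(ErrorSimConfig(refs, 60, 50, 0.01, seed=7))
        b = r.inject_errors(ErrorSimConfig(refs, 60, 50, 0.01, seed=7))
        assert a.sequences == b.sequences


class TestDereplicate:
    def test_copies_collapse_with_count(self):
        s = r.SequenceSet(["a", "b", "c"], ["ACGT"] * 3)
        out = r.dereplicate(s)
        assert len(out) == 1 and out.counts[0] == 3

    def test_all_distinct_is_identity(self):
        seqs = ["AAAA", "CCCC", "GGGG"]
        out = r.dereplicate(r.SequenceSet(list("abc"), seqs))
        assert sorted(out.sequences) == sorted(seqs)
        assert out.total_reads() == 3

    def test_counts_match_hash_tally(self):
        rng = np.random.default_rng(3)
        bases = "ACGT"
        seqs = [
            "".join(rng.choice(list(bases), size=6)) for _ in range(300)
        ]
        out = r.dereplicate(r.SequenceSet([f"r{i}" for i in range(300)], seqs))
        want = collections.Counter(seqs)
        got = dict(zip(out.sequences, out.counts))
        assert {k: int(v) for k, v in got.items()} == dict(want)
        assert out.total_reads() == 300

    def test_per_sample_table(self):
        s = r.SequenceSet(
            ["r1", "r2", "r3", "r4"],
            ["AAAA", "AAAA", "CCCC", "AAAA"],
            sample_ids=["s1", "s2", "s1", "s1"],
        )
        uniques, table = dereplicate_by_sample(s)
        assert table.shape == (2, 2)
        assert table.to_numpy().sum() == 4


class TestRetentionFilter:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["s1", "s2", "s3"])

    @pytest.mark.parametrize(
        "row,kept",
        [
            ([12, 0, 0], False),   # one sample, 12 copies: fails 2-sample rule
            ([3, 3, 3], False),    # three samples, total 9: fails 10-copy rule
            ([5, 5, 0], True),     # two samples, total 10: boundary kept
            ([1, 9, 0], True),
            ([10, 0, 0], False),
        ],
    )
    def test_boundary_rules(self, row, kept):
        out = r.retention_filter(self._table([row]))
        assert (len(out) == 1) == kept

    def test_output_is_subset(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.integers(0, 8, size=(40, 3)))
        out = r.retention_filter(table)
        assert set(out.index) <= set(table.index)


class TestContaminantFilter:
    def _sets(self):
        reads = r.SequenceSet(
            ["both", "contam_only", "neither"],
            ["AAACCC", "GGGTTT", "ACACAC"],
            np.array([2, 3, 5]),
        )
        contam = r.SequenceSet(["h1"], ["TTAAACCCTTGGGTTTAA"])
        allowed = r.SequenceSet(["g1"], ["CCAAACCCGG"])
        return reads, contam, allowed

    def test_truth_table(self):
        reads, contam, allowed = self._sets()
        kept, frac = r.contaminant_filter(reads, contam, allowed)
        assert kept.ids == ["both", "neither"]  # only contaminant-only removed
        assert frac == pytest.approx(3 / 10)

    def test_empty_reference_rejected(self):
        reads, contam, allowed = self._sets()
        with pytest.raises(ValueError):
            r.contaminant_filter(reads, r.SequenceSet([], []), allowed)


def brute_greedy_cluster(seqs, counts, threshold):
    """Independent re-implementation of the greedy rule on raw strings."""
    L = len(seqs[0])
    max_mm = int(np.floor((1 - threshold) * L + 1e-9))
    order = sorted(range(len(seqs)), key=lambda i: (-counts[i], seqs[i]))
    centroids = []
    assign = {}
    for i in order:
        placed = False
        for c, cent in enumerate(centroids):
            if sum(a != b for a, b in zip(seqs[i], cent)) <= max_mm:
                assign[i] = c
                placed = True
                break
        if not placed:
            assign[i] = len(centroids)
            centroids.append(seqs[i])
    return centroids, assign


class TestClusterOtus:
    def test_identical_reads_one_otu(self):
        s = r.dereplicate(r.SequenceSet(["a", "b"], ["ACGTACGTAC"] * 2))
        assert r.cluster_otus(s).n_otus == 1

    def test_five_mismatches_in_hundred_split(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=100))
        mutated = list(base)
        for pos in [3, 20, 40, 60, 90]:
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        s = r.SequenceSet(["a", "b"], [base, "".join(mutated)], np.array([5, 3]))
        assert r.cluster_otus(s, threshold=0.97).n_otus == 2

    def test_three_mismatches_in_hundred_merge(self):
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list("ACGT"), size=100))
        mutated = list(base)
        for pos in [3, 20, 40]:
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        s = r.SequenceSet(["a", "b"], [base, "".join(mutated)], np.array([5, 3]))
        assert r.cluster_otus(s, threshold=0.97).n_otus == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_greedy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 16))
        L = 12
        # clustered-ish sequences: perturb a few templates
        templates = ["".join(rng.choice(list("ACGT"), size=L)) for _ in range(3)]
        seqs, counts = [], []
        seen = set()
        for _ in range(n):
            t = list(templates[rng.integers(0, 3)])
            for _ in range(int(rng.integers(0, 4))):
                t[rng.integers(0, L)] = "ACGT"[rng.integers(0, 4)]
            s = "".join(t)
            if s in seen:
                continue
            seen.add(s)
            seqs.append(s)
            counts.append(int(rng.integers(1, 50)))
        s = r.SequenceSet([f"u{i}" for i in range(len(seqs))], seqs,
                          np.array(counts))
        got = r.cluster_otus(s, threshold=0.8)
        cents, assign = brute_greedy_cluster(seqs, counts, 0.8)
        assert got.n_otus == len(cents)
        assert got.centroid_sequences == cents
        assert [got.assignments[i] for i in range(len(seqs))] == [
            assign[i] for i in range(len(seqs))
        ]
        assert got.check_radius(seqs)
        assert got.member_counts.sum() == s.total_reads()

    def test_unequal_lengths_rejected(self):
        s = r.SequenceSet(["a", "b"], ["ACGT", "ACGTA"])
        with pytest.raises(ValueError, match="unequal"):
            r.cluster_otus(s)


class TestInflation:
    def test_zero_error_equals_reference_clustering(self, refs):
        ref_otus = r.cluster_otus(
            r.SequenceSet(refs.ids, [s[:60] for s in refs.sequences])
        ).n_otus
        tab = r.inflation_experiment(refs, 60, depths=[5000], error_rates=[0.0], seed=1)
        assert tab.loc[0, "n_otus"] == ref_otus

    def test_monotone_in_error_rate_and_depth(self, refs):
        tab = r.inflation_experiment(
            refs, 60, depths=[1000, 5000], error_rates=[0.0, 0.002, 0.01], seed=2
        )
        for d in [1000, 5000]:
            col = tab[tab["depth"] == d].sort_values("error_rate")["n_otus"]
            assert (np.diff(col) >= 0).all()
        col = tab[tab["error_rate"] == 0.01].sort_values("depth")["n_otus"]
        assert (np.diff(col) >= 0).all()

    def test_empty_grid_rejected(self, refs):
        with pytest.raises(ValueError):
            r.inflation_experiment(refs, 60, depths=[], error_rates=[0.1])
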