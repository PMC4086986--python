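import numpy as np
import pandas as pd
import pytest

import barcodegap as bg
from barcodegap.congruence import (
    conflict_cases,
    cryptic_species,
    partition_similarity,
    resolve_consensus,
    shared_clusters,
    sympatry_status,
)
from barcodegap.errors import InputError
from barcodegap.klee import KleeMatrix


def P(assignment):
    return bg.Partition(assignment)


class TestSharedClusters:
    def test_identical_partitions_share_everything(self):
        p = P({"a": "1", "b": "1", "c": "2"})
        n, clusters = shared_clusters({"m1": p, "m2": p, "m3": p})
        assert n == 2
        assert {frozenset(c) for c in clusters} == {
            frozenset({"a", "b"}), frozenset({"c"})
        }

    def test_specimen_set_mismatch_rejected(self):
        with pytest.raises(InputError):
            shared_clusters(
                {"m1": P({"a": "1"}), "m2": P({"a": "1", "b": "2"})}
            )

    def test_adding_a_partition_never_increases_shared(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(30)]
        parts = {
            f"m{k}": P({s: f"c{rng.integers(0, 6)}" for s in ids})
            for k in range(4)
        }
        subsets = list(parts)
        prev = None
        for k in range(1, 5):
            n, _ = shared_clusters({m: parts[m] for m in subsets[:k]})
            if prev is not None:
                assert n <= prev
            prev = n


class TestConflictCases:
    def test_identical_partitions_have_no_cases(self):
        p = P({"a": "1", "b": "2"})
        cases, exceptions = conflict_cases(p, p)
        assert cases == [] and exceptions == []

    def test_one_lumper_three_splitter(self):
        lum = P({"a": "L", "b": "L", "c": "L", "d": "X"})
        spl = P({"a": "1", "b": "2", "c": "3", "d": "4"})
        cases, _ = conflict_cases(lum, spl)
        assert len(cases) == 1
        assert set(cases[0].splitter_labels) == {"1", "2", "3"}

    def test_non_refinement_reported_not_fixed(self):
        lum = P({"a": "L1", "b": "L2"})
        spl = P({"a": "s", "b": "s"})
        cases, exceptions = conflict_cases(lum, spl)
        assert len(exceptions) == 1 and "spans" in exceptions[0]


def toy_setup(cross_corr):
    """One lumper PSH split in two splitter PSHs with a given correlation."""
    lum = P({"a1": "L", "a2": "L", "b1": "L", "b2": "L", "z": "Z"})
    spl = P({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "z": "Zs"})
    km = KleeMatrix(
        psh_labels=("A", "B", "Zs"),
        representatives={"A": "a1", "B": "b1", "Zs": "z"},
        values=np.array(
            [
                [1.0, cross_corr, 0.1],
                [cross_corr, 1.0, 0.1],
                [0.1, 0.1, 1.0],
            ]
        ),
        block_order=(("L", ("A", "B")), ("Z", ("Zs",))),
    )
    cases, _ = conflict_cases(lum, spl)
    return lum, spl, km, cases


class TestResolveConsensus:
    def test_high_correlation_keeps_lumper(self):
        lum, spl, km, cases = toy_setup(0.95)
        trees = {"gmyc_single": P({s: s for s in lum.assignment})}
        rep = resolve_consensus(cases, km, trees, lum, spl)
        assert rep.cases[0].resolution == "keep_lumper"
        assert rep.n_consensus == 2  # L kept whole + Z

    def test_corroborated_split_accepted(self):
        lum, spl, km, cases = toy_setup(0.5)
        # GMYC single separates A from B
        trees = {
            "gmyc_single": P(
                {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2", "z": "g3"}
            )
        }
        rep = resolve_consensus(cases, km, trees, lum, spl)
        assert rep.cases[0].resolution == "accept_split"
        assert rep.n_consensus == 3
        assert rep.cases[0].corroboration["gmyc_single"] is True

    def test_uncorroborated_split_merges_back(self):
        lum, spl, km, cases = toy_setup(0.5)
        # no tree method separates the two Klee components
        trees = {
            "gmyc_single": P({s: "one" for s in lum.assignment}),
            "ptp": P({s: "one" for s in lum.assignment}),
        }
        rep = resolve_consensus(cases, km, trees, lum, spl)
        assert rep.cases[0].resolution == "partial_split"
        assert len(rep.cases[0].final_clusters) == 1
        assert rep.n_consensus == 2

    def test_klee_only_fallback_accepts_components(self):
        lum, spl, km, cases = toy_setup(0.5)
        rep = resolve_consensus(cases, km, {}, lum, spl)
        assert rep.klee_only
        assert rep.n_consensus == 3

    def test_consensus_between_splitter_and_lumper(self, benchmark_analysis):
        """Every consensus cluster is a union of splitter clusters and a
        subset of one lumper cluster."""
        res = benchmark_analysis
        consensus = res.report.consensus
        assert consensus.refines(res.lumper)
        assert res.splitter.refines(consensus)

    def test_missing_representative_rejected(self):
        lum, spl, km, cases = toy_setup(0.5)
        km_missing = KleeMatrix(
            psh_labels=("A",),
            representatives={"A": "a1"},
            values=np.array([[1.0]]),
            block_order=(("L", ("A",)),),
        )
        with pytest.raises(InputError):
            resolve_consensus(cases, km_missing, {}, lum, spl)


def table_from(morpho, locality=None):
    df = pd.DataFrame(
        {
            "specimen_id": list(morpho),
            "morphospecies": list(morpho.values()),
            "locality": [
                (locality or {}).get(s) for s in morpho
            ],
        }
    ).set_index("specimen_id")
    return bg.SpecimenTable(
        df=df, morpho_col="morphospecies", locality_col="locality"
    )


class TestCrypticSpecies:
    def test_consensus_equal_morphospecies_gives_zero(self):
        consensus = P({"a": "1", "b": "1", "c": "2"})
        table = table_from({"a": "m1", "b": "m1", "c": "m2"})
        res = cryptic_species(consensus, table)
        assert res.count == 0
        assert res.difference == 0
        assert res.merged_morphospecies.empty

    def test_split_morphospecies_counted_k_minus_one(self):
        consensus = P({"a": "1", "b": "2", "c": "3", "d": "4"})
        table = table_from({"a": "m1", "b": "m1", "c": "m1", "d": "m2"})
        res = cryptic_species(consensus, table)
        assert res.count == 2  # m1 in 3 PSHs
        assert res.difference == 4 - 2

    def test_merged_morphospecies_reported(self):
        consensus = P({"a": "1", "b": "1"})
        table = table_from({"a": "m1", "b": "m2"})
        res = cryptic_species(consensus, table)
        assert len(res.merged_morphospecies) == 1

    def test_unlabeled_specimen_rejected(self):
        consensus = P({"a": "1", "b": "1"})
        table = table_from({"a": "m1", "b": None})
        with pytest.raises(InputError):
            cryptic_species(consensus, table)


class TestSympatry:
    def test_shared_locality_is_sympatric(self):
        consensus = P({"a": "1", "b": "2"})
        table = table_from(
            {"a": "m", "b": "m"}, {"a": "Vanuatu", "b": " vanuatu "}
        )
        out = sympatry_status(consensus, table)
        assert list(out["status"]) == ["sympatric"]

    def test_disjoint_localities_are_allopatric(self):
        consensus = P({"a": "1", "b": "2"})
        table = table_from(
            {"a": "m", "b": "m"}, {"a": "Vanuatu", "b": "West Africa"}
        )
        assert list(sympatry_status(consensus, table)["status"]) == [
            "allopatric"
        ]

    def test_empty_locality_set_is_unknown(self):
        consensus = P({"a": "1", "b": "2"})
        table = table_from({"a": "m", "b": "m"}, {"a": "Vanuatu"})
        assert list(sympatry_status(consensus, table)["status"]) == ["unknown"]


class TestPartitionSimilarity:
    def test_identical_partitions_score_one(self):
        a = P({"x": "1", "y": "1", "z": "2"})
        b = P({"x": "A", "y": "A", "z": "B"})
        assert partition_similarity(a, b) == 1.0

    def test_singletons_vs_single_cluster_scores_zero(self):
        a = P({f"s{i}": f"c{i}" for i in range(4)})
        b = P({f"s{i}": "one" for i in range(4)})
        assert partition_similarity(a, b) == pytest.approx(0.0)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(20)]
        a = P({s: f"c{rng.integers(0, 4)}" for s in ids})
        b = P({s: f"d{rng.integers(0, 4)}" for s in ids})
        relabel = {"d0": "q3", "d1": "q2", "d2": "q1", "d3": "q0"}
        b2 = P({s: relabel[b.assignment[s]] for s in ids})
        assert partition_similarity(a, b) == pytest.approx(
            partition_similarity(a, b2)
        )

    def test_specimen_mismatch_rejected(self):
        with pytest.raises(InputError):
            partition_similarity(P({"a": "1"}), P({"b": "1"}))
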