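import numpy as np
import pytest

import barcodegap as bg
from barcodegap.distances import DistMatrix
from barcodegap.errors import InputError
from barcodegap.klee import (
    KleeMatrix,
    correlation,
    indicator_vector,
    klee_matrix,
    merge_candidates,
    render_klee,
    representatives,
)


def dist_from(values, ids):
    values = np.asarray(values, dtype=float)
    n = len(ids)
    return DistMatrix(
        ids=tuple(ids),
        values=values,
        model="p",
        comparable_sites=np.full((n, n), 10, dtype=np.int64),
        saturated=np.zeros((n, n), dtype=bool),
    )


class TestIndicatorVector:
    def test_self_correlation_is_one(self):
        iv = indicator_vector("ACGTACGT")
        assert correlation(iv, iv) == pytest.approx(1.0)

    def test_disjoint_channels_correlate_zero(self):
        assert correlation(
            indicator_vector("AAAA"), indicator_vector("CCCC")
        ) == pytest.approx(0.0)

    def test_three_of_four_shared_columns(self):
        assert correlation(
            indicator_vector("ACGT"), indicator_vector("ACGA")
        ) == pytest.approx(0.75)

    def test_gaps_and_ambiguity_contribute_zero(self):
        iv = indicator_vector("AC-NR")
        assert iv.support == 2
        assert np.linalg.norm(iv.vector) == pytest.approx(1.0)

    def test_all_gap_sequence_is_empty_flagged(self):
        iv = indicator_vector("----")
        assert iv.empty
        assert np.isnan(correlation(iv, indicator_vector("ACGT")))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            correlation(indicator_vector("ACGT"), indicator_vector("ACG"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_channel_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT-N"), size=50))
        b = "".join(rng.choice(list("ACGT-N"), size=50))
        got = correlation(indicator_vector(a), indicator_vector(b))
        # brute force: count columns where both are the same plain base
        shared = sum(
            1 for x, y in zip(a, b) if x == y and x in "ACGT"
        )
        na = sum(1 for x in a if x in "ACGT")
        nb = sum(1 for x in b if x in "ACGT")
        expect = shared / np.sqrt(na * nb)
        assert got == pytest.approx(expect, abs=1e-12)


class TestRepresentatives:
    def test_singleton_cluster_is_its_member(self):
        part = bg.Partition({"a": "c1"})
        d = dist_from([[0.0]], ["a"])
        assert representatives(part, d) == {"c1": "a"}

    def test_medoid_minimises_mean_distance(self):
        vals = [
            [0.00, 0.01, 0.02],
            [0.01, 0.00, 0.03],
            [0.02, 0.03, 0.00],
        ]
        part = bg.Partition({"a": "c", "b": "c", "x": "c"})
        d = dist_from(vals, ["a", "b", "x"])
        assert representatives(part, d)["c"] == "a"

    def test_equidistant_tie_broken_by_input_order(self):
        vals = np.full((3, 3), 0.05)
        np.fill_diagonal(vals, 0.0)
        part = bg.Partition({"a": "c", "b": "c", "x": "c"})
        d = dist_from(vals, ["a", "b", "x"])
        assert representatives(part, d)["c"] == "a"


def toy_klee(values, labels, blocks):
    return KleeMatrix(
        psh_labels=tuple(labels),
        representatives={l: l for l in labels},
        values=np.asarray(values, dtype=float),
        block_order=tuple(
            (lum, tuple(members)) for lum, members in blocks
        ),
    )


class TestKleeMatrix:
    def test_splitter_equal_lumper_gives_unit_diagonal(self):
        aln = bg.AlignedSeqSet(
            ids=("a", "b", "c"), seqs=("AAAA", "CCCC", "GGGG")
        )
        part = bg.Partition({"a": "1", "b": "2", "c": "3"})
        d = bg.pairwise_distances(aln, model="p")
        km = klee_matrix(aln, part, part, d)
        assert km.values.shape == (3, 3)
        np.testing.assert_allclose(np.diag(km.values), 1.0)
        np.testing.assert_allclose(km.values, km.values.T)
        assert ((km.values >= 0) & (km.values <= 1)).all()

    def test_non_refining_splitter_rejected(self):
        aln = bg.AlignedSeqSet(ids=("a", "b"), seqs=("AAAA", "CCCC"))
        d = bg.pairwise_distances(aln, model="p")
        splitter = bg.Partition({"a": "1", "b": "1"})
        lumper = bg.Partition({"a": "x", "b": "y"})
        with pytest.raises(InputError):
            klee_matrix(aln, splitter, lumper, d)

    @pytest.mark.parametrize("seed", range(20))
    def test_two_species_blocks_separate(self, seed):
        """Cross-species correlation sits below within-species levels."""
        aln, truth, _ = bg.simulate(
            bg.SimSpec(
                n_species=2, n_per_species=5, intra=0.01, inter=0.4, seed=seed
            )
        )
        d = bg.pairwise_distances(aln)
        # splitter: split each species in half; lumper: truth
        ids = list(aln.ids)
        splitter = bg.Partition(
            {s: f"{truth.assignment[s]}_{i % 2}" for i, s in enumerate(ids)}
        )
        km = klee_matrix(aln, splitter, truth, d)
        within = [
            km.value(a, b)
            for _, ms in km.block_order
            for i, a in enumerate(ms)
            for b in ms[i + 1:]
        ]
        labels_by_block = [ms for _, ms in km.block_order]
        across = [
            km.value(a, b)
            for a in labels_by_block[0]
            for b in labels_by_block[1]
        ]
        assert max(across) < min(within)


class TestMergeCandidates:
    def test_high_correlation_block_is_single_component(self):
        km = toy_klee(
            [[1.0, 0.95, 0.96], [0.95, 1.0, 0.97], [0.96, 0.97, 1.0]],
            ["a", "b", "c"],
            [("L1", ["a", "b", "c"])],
        )
        assert merge_candidates(km) == {"L1": [["a", "b", "c"]]}

    def test_low_correlation_block_has_no_merges(self):
        km = toy_klee(
            [[1.0, 0.5, 0.6], [0.5, 1.0, 0.4], [0.6, 0.4, 1.0]],
            ["a", "b", "c"],
            [("L1", ["a", "b", "c"])],
        )
        comps = merge_candidates(km)["L1"]
        assert sorted(map(len, comps)) == [1, 1, 1]

    def test_partial_chain_joins_transitively(self):
        km = toy_klee(
            [[1.0, 0.92, 0.85], [0.92, 1.0, 0.91], [0.85, 0.91, 1.0]],
            ["a", "b", "c"],
            [("L1", ["a", "b", "c"])],
        )
        assert merge_candidates(km) == {"L1": [["a", "b", "c"]]}

    def test_merges_confined_to_lumper_blocks(self):
        km = toy_klee(
            [[1.0, 0.99], [0.99, 1.0]],
            ["a", "b"],
            [("L1", ["a"]), ("L2", ["b"])],
        )
        comps = merge_candidates(km)
        assert comps == {"L1": [["a"]], "L2": [["b"]]}

    def test_label_permutation_invariance(self):
        vals = [[1.0, 0.95, 0.2], [0.95, 1.0, 0.3], [0.2, 0.3, 1.0]]
        km1 = toy_klee(vals, ["a", "b", "c"], [("L", ["a", "b", "c"])])
        perm = [2, 0, 1]
        vals2 = np.asarray(vals)[np.ix_(perm, perm)]
        km2 = toy_klee(vals2, ["c", "a", "b"], [("L", ["c", "a", "b"])])
        as_sets = lambda m: {
            frozenset(c) for comps in merge_candidates(m).values() for c in comps
        }
        assert as_sets(km1) == as_sets(km2)

    @pytest.mark.parametrize("seed", range(10))
    def test_raising_threshold_refines_components(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        v = rng.uniform(0.5, 1.0, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        labels = [f"p{i}" for i in range(n)]
        km = toy_klee(v, labels, [("L", labels)])
        lo = merge_candidates(km, threshold=0.7)["L"]
        hi = merge_candidates(km, threshold=0.9)["L"]
        lo_map = {lab: i for i, comp in enumerate(lo) for lab in comp}
        for comp in hi:
            assert len({lo_map[lab] for lab in comp}) == 1  # hi refines lo


def test_render_klee_writes_png_and_exact_csv(tmp_path, benchmark_analysis):
    import pandas as pd

    km = benchmark_analysis.km
    png = tmp_path / "klee.png"
    csv = tmp_path / "klee.csv"
    render_klee(km, png, csv)
    assert png.exists() and png.stat().st_size > 0
    back = pd.read_csv(csv, index_col=0, float_precision="round_trip")
    np.testing.assert_array_equal(back.to_numpy(), km.values)
    assert list(back.columns) == list(km.psh_labels)
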