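"""Quantification: mapping with a mismatch cap, TPM EM, zero replacement,
clr, class aggregation, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from conftest import make_merged, random_dna
from venomgland import quantify as qt
from venomgland._seq import revcomp


class FakeTranscript:
    def __init__(self, tid, sequence, cds=None):
        self.id = tid
        self.sequence = sequence
        self.cds = cds if cds is not None else (0, len(sequence))


def edit_distance_oracle(a, b):
    """Naive O(nm) DP edit distance of ``a`` against any substring of ``b``
    (infix alignment), independent of edlib."""
    n, m = len(a), len(b)
    prev = [0] * (m + 1)  # free start in b
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return min(prev)


class TestMapReads:
    def test_four_mismatches_everywhere_unaligned(self):
        t = FakeTranscript("t1", random_dna(300, seed=70))
        s = list(t.sequence[50:200])
        for p in (10, 40, 80, 120):
            s[p] = "A" if s[p] != "A" else "C"
        aln, profiles = qt.map_reads([make_merged("".join(s))], [t])
        assert aln.candidates[0] == []
        assert profiles["t1"].depth.sum() == 0

    def test_exact_match_on_two_paralogs_gives_two_candidates(self):
        s = random_dna(300, seed=71)
        t1, t2 = FakeTranscript("a", s), FakeTranscript("b", s)
        aln, _ = qt.map_reads([make_merged(s[100:220])], [t1, t2])
        assert {c[0] for c in aln.candidates[0]} == {0, 1}

    def test_candidate_set_matches_dp_oracle(self):
        rng = np.random.default_rng(72)
        transcripts = [FakeTranscript(f"t{i}", random_dna(250, seed=73 + i))
                       for i in range(4)]
        # reads: exact, 2-mismatch, 5-mismatch, random
        base = transcripts[1].sequence[60:180]
        two = list(base)
        two[10] = "A" if two[10] != "A" else "C"
        two[90] = "G" if two[90] != "G" else "T"
        five = list(base)
        for p in (5, 30, 55, 80, 110):
            five[p] = "A" if five[p] != "A" else "C"
        reads = [make_merged(q, rid=f"r{k}") for k, q in enumerate(
            [base, "".join(two), "".join(five), random_dna(120, seed=99)])]
        aln, _ = qt.map_reads(reads, transcripts, max_mismatches=3)
        for r_idx, read in enumerate(reads):
            got = {c[0] for c in aln.candidates[r_idx]}
            want = set()
            for t_idx, t in enumerate(transcripts):
                d = min(edit_distance_oracle(read.sequence, t.sequence),
                        edit_distance_oracle(revcomp(read.sequence), t.sequence))
                if d <= 3:
                    want.add(t_idx)
            assert got == want


def alignments(tids, cands):
    return qt.ReadAlignments(transcript_ids=list(tids),
                             candidates=[list(c) for c in cands],
                             n_reads=len(cands))


class TestEstimateTpm:
    def test_all_reads_on_one_transcript(self):
        aln = alignments(["a", "b"], [[(0, 0, 50, 0)]] * 20)
        res = qt.estimate_tpm(aln, {"a": 500, "b": 500})
        assert res.tpm["a"] == pytest.approx(1e6)
        assert res.tpm["b"] == 0.0

    def test_equal_unique_counts_equal_lengths_split_evenly(self):
        cands = [[(0, 0, 50, 0)]] * 10 + [[(1, 0, 50, 0)]] * 10
        res = qt.estimate_tpm(alignments(["a", "b"], cands), {"a": 400, "b": 400})
        assert res.tpm["a"] == pytest.approx(5e5)
        assert res.tpm["b"] == pytest.approx(5e5)

    def test_em_matches_grid_search_likelihood_oracle(self):
        # 3 transcripts, multi-mapping reads; oracle: coarse simplex grid
        lens = {"a": 100.0, "b": 100.0, "c": 100.0}
        cands = (
            [[(0, 0, 50, 0)]] * 8
            + [[(0, 0, 50, 0), (1, 0, 50, 0)]] * 6
            + [[(1, 0, 50, 0), (2, 0, 50, 0)]] * 4
            + [[(2, 0, 50, 0)]] * 2
        )
        res = qt.estimate_tpm(alignments(list(lens), cands), lens, em_iters=500)

        groups = [({0}, 8), ({0, 1}, 6), ({1, 2}, 4), ({2}, 2)]

        def loglik(theta):
            return sum(
                w * np.log(sum(theta[i] for i in idx)) for idx, w in groups
            )

        best, best_ll = None, -np.inf
        step = 0.01
        for i in np.arange(step, 1.0, step):
            for j in np.arange(step, 1.0 - i, step):
                k = 1.0 - i - j
                if k <= 0:
                    continue
                ll = loglik([i, j, k])
                if ll > best_ll:
                    best, best_ll = (i, j, k), ll
        em_theta = (res.counts / res.counts.sum()).to_numpy()
        assert np.abs(em_theta - np.array(best)).max() < 0.02
        assert loglik(em_theta) >= best_ll - 1e-3

    def test_em_loglik_monotone(self):
        cands = [[(0, 0, 50, 0), (1, 0, 50, 0)]] * 10 + [[(0, 0, 50, 0)]] * 3
        res = qt.estimate_tpm(alignments(["a", "b"], cands), {"a": 200, "b": 300})
        diffs = np.diff(res.log_likelihoods)
        assert (diffs >= -1e-9).all()

    def test_no_aligned_reads_is_an_error(self):
        with pytest.raises(ValueError):
            qt.estimate_tpm(alignments(["a"], [[]]), {"a": 100})


class TestReplaceZeros:
    def test_no_zeros_passes_through(self):
        df = pd.DataFrame({"I1": [1.0, 2.0, 3.0]})
        out = qt.replace_zeros(df)
        assert np.allclose(out["I1"], df["I1"], atol=1e-12)

    def test_single_zero_delta_and_sum_preservation(self):
        df = pd.DataFrame({"I1": [0.0, 10.0, 90.0]})
        out = qt.replace_zeros(df)
        assert out["I1"].iloc[0] == pytest.approx(0.65 * 10.0)
        assert out["I1"].sum() == pytest.approx(100.0)

    def test_all_zero_column_is_an_error(self):
        with pytest.raises(ValueError):
            qt.replace_zeros(pd.DataFrame({"I1": [0.0, 0.0]}))

    def test_rank_preserved_for_nonzero_entries(self):
        df = pd.DataFrame({"I1": [0.0, 5.0, 1.0, 40.0]})
        out = qt.replace_zeros(df)
        orig = df["I1"][df["I1"] > 0].rank()
        new = out["I1"][df["I1"] > 0].rank()
        assert (orig == new).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2,
                    max_size=30).filter(lambda v: sum(v) > 0))
    def test_output_strictly_positive_and_sum_preserved(self, values):
        df = pd.DataFrame({"c": [float(v) for v in values]})
        out = qt.replace_zeros(df)
        assert (out["c"] > 0).all()
        assert out["c"].sum() == pytest.approx(df["c"].sum())


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        assert np.allclose(qt.clr([1.0, 1.0, 1.0, 1.0]), 0.0)

    def test_two_part_geometric_mean_arithmetic(self):
        out = qt.clr([2.0, 8.0])
        assert out == pytest.approx([-np.log(2.0), np.log(2.0)])

    def test_output_sums_to_zero(self):
        rng = np.random.default_rng(74)
        x = rng.uniform(0.1, 100, 50)
        assert qt.clr(x).sum() == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_entry_is_an_error(self):
        with pytest.raises(ValueError):
            qt.clr([1.0, 0.0])


class TestSumByClass:
    def test_family_rows_sum_and_conserve_totals(self):
        expr = pd.DataFrame(
            {"I1": [1.0, 2.0, 3.0], "I2": [4.0, 5.0, 6.0]},
            index=["SVMP-1", "SVMP-2", "PLA2-1"],
        )
        fams = {"SVMP-1": "SVMP", "SVMP-2": "SVMP", "PLA2-1": "PLA2"}
        out = qt.sum_by_class(expr, fams)
        assert out.loc["SVMP", "I1"] == 3.0
        assert np.allclose(out.sum(axis=0), expr.sum(axis=0))

    def test_single_member_family_unchanged(self):
        expr = pd.DataFrame({"I1": [7.0]}, index=["PLA2-1"])
        out = qt.sum_by_class(expr, {"PLA2-1": "PLA2"})
        assert out.loc["PLA2", "I1"] == 7.0

    def test_unannotated_row_is_an_error(self):
        expr = pd.DataFrame({"I1": [1.0]}, index=["x"])
        with pytest.raises(ValueError):
            qt.sum_by_class(expr, {})


class TestExpressionCluster:
    def test_identical_individuals_merge_first_at_zero(self):
        rng = np.random.default_rng(75)
        x = rng.normal(0, 1, 20)
        df = pd.DataFrame({"I1": x, "I2": x, "I3": x + 5.0})
        res = qt.expression_cluster(df)
        assert res.linkage_cols[0, 2] == pytest.approx(0.0)
        first = sorted(res.linkage_cols[0, :2].astype(int))
        assert [df.columns.sort_values()[i] for i in first] == ["I1", "I2"]

    def test_outlier_joins_last(self):
        rng = np.random.default_rng(76)
        base = rng.normal(0, 1, 30)
        df = pd.DataFrame({
            "I1": base + rng.normal(0, 0.05, 30),
            "I2": base + rng.normal(0, 0.05, 30),
            "I3": base + rng.normal(0, 0.05, 30),
            "OUT": rng.normal(8, 1, 30),
        })
        res = qt.expression_cluster(df)
        order = res.col_order
        assert order.index("OUT") in (0, len(order) - 1)

    def test_cophenetic_matches_brute_force_average_linkage(self):
        rng = np.random.default_rng(77)
        df = pd.DataFrame(rng.normal(0, 1, (6, 5)),
                          columns=[f"I{i}" for i in range(5)])
        res = qt.expression_cluster(df)

        # independent brute-force average-linkage on the 5 columns
        pts = {(i,): df.iloc[:, i].to_numpy() for i in range(5)}
        import itertools

        def avg_dist(ca, cb):
            return np.mean(
                [np.linalg.norm(pts[(i,)] - pts[(j,)]) for i in ca for j in cb]
            )

        clusters = [(i,) for i in range(5)]
        merges = []
        while len(clusters) > 1:
            pairs = list(itertools.combinations(clusters, 2))
            ca, cb = min(pairs, key=lambda p: avg_dist(p[0], p[1]))
            merges.append(avg_dist(ca, cb))
            clusters = [c for c in clusters if c not in (ca, cb)] + [
                tuple(sorted(ca + cb))
            ]
        assert np.allclose(sorted(res.linkage_cols[:, 2]), sorted(merges))

    def test_fewer_than_two_columns_is_an_error(self):
        with pytest.raises(ValueError):
            qt.expression_cluster(pd.DataFrame({"I1": [1.0, 2.0]}))

    def test_order_invariant_under_permutation(self):
        rng = np.random.default_rng(78)
        df = pd.DataFrame(rng.normal(0, 1, (8, 4)),
                          columns=["I1", "I2", "I3", "I4"])
        a = qt.expression_cluster(df)
        b = qt.expression_cluster(df[["I3", "I1", "I4", "I2"]])
        assert a.col_order == b.col_order


def test_linkage_to_newick_roundtrips_labels():
    rng = np.random.default_rng(79)
    df = pd.DataFrame(rng.normal(0, 1, (6, 4)), columns=list("abcd"))
    res = qt.expression_cluster(df)
    nwk = qt.linkage_to_newick(res.linkage_cols, sorted(df.columns))
    import dendropy

    tree = dendropy.Tree.get(data=nwk, schema="newick")
    assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == list("abcd")
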