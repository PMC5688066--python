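"""RPKM computation, aggregation, dereplication and marker clustering."""

import numpy as np
import pandas as pd
import pytest

from marinibin import expression as ex
from marinibin import synthio as sy
from marinibin.recruitment import classify_samples


def bfs_components(ids, pairs, threshold):
    """Brute-force oracle: connected components via breadth-first search."""
    adj = {i: set() for i in ids}
    for (a, b), v in pairs.items():
        if v >= threshold:
            adj[a].add(b)
            adj[b].add(a)
    seen, comps = set(), []
    for i in ids:
        if i in seen:
            continue
        comp, queue = [], [i]
        while queue:
            x = queue.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            queue.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return sorted(comps)


class TestRpkm:
    def test_closed_form(self):
        assert ex.rpkm(10, 1_000, 1_000_000) == pytest.approx(10.0)

    def test_zero_reads(self):
        assert ex.rpkm(0, 500, 10**7) == 0.0

    def test_doubling_total_halves_value(self):
        assert ex.rpkm(7, 800, 2_000_000) == pytest.approx(
            ex.rpkm(7, 800, 1_000_000) / 2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            ex.rpkm(1, 0, 10**6)
        with pytest.raises(ValueError):
            ex.rpkm(1, 100, 0)

    def test_vectorised_matches_scalar(self, rng):
        df = pd.DataFrame({
            "count": rng.integers(0, 100, 20),
            "gene_length": rng.integers(100, 2_000, 20),
            "total_mapped": rng.integers(10**5, 10**7, 20),
        })
        out = ex.add_rpkm(df)
        for row in out.itertuples(index=False):
            assert row.rpkm == pytest.approx(
                ex.rpkm(row.count, row.gene_length, row.total_mapped))


class TestDereplicate:
    def test_single_linkage_transitivity(self):
        pairs = {("a", "b"): 80.0, ("b", "c"): 80.0, ("a", "c"): 60.0}
        assert ex.dereplicate_copies(pairs) == [["a", "b", "c"]]

    def test_all_below_threshold_singletons(self):
        pairs = {("a", "b"): 50.0, ("b", "c"): 74.9}
        assert ex.dereplicate_copies(pairs) == [["a"], ["b"], ["c"]]

    def test_matches_bfs_oracle_on_planted_groups(self, rng):
        """10 genes with 2 planted groups, plus random sub-threshold noise,
        recovered exactly; checked against a brute-force BFS oracle."""
        ids = [f"g{i}" for i in range(10)]
        groups = [ids[:4], ids[4:]]
        pairs = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                same = any(a in g and b in g for g in groups)
                pairs[(a, b)] = float(rng.uniform(80, 95)) if same else float(
                    rng.uniform(30, 70))
        got = ex.dereplicate_copies(pairs, threshold=75)
        assert got == [sorted(groups[0]), sorted(groups[1])]
        assert got == bfs_components(ids, pairs, 75)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(10):
            ids = [f"g{i}" for i in range(8)]
            pairs = {
                (a, b): float(rng.uniform(50, 100))
                for i, a in enumerate(ids) for b in ids[i + 1:]
            }
            assert ex.dereplicate_copies(pairs, 75) == bfs_components(ids, pairs, 75)

    def test_conflicting_asymmetric_entries_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            ex.dereplicate_copies({("a", "b"): 80.0, ("b", "a"): 70.0})


class TestAggregate:
    def test_sum_within_group(self):
        recs = pd.DataFrame({
            "bin_id": ["b", "b"], "function": ["nosZ", "nosZ"],
            "sample_id": ["s1", "s1"], "rpkm": [3.0, 4.5],
        })
        out = ex.aggregate_function_rpkm(recs)
        assert out["rpkm"].tolist() == [7.5]

    def test_empty_input(self):
        out = ex.aggregate_function_rpkm(pd.DataFrame())
        assert len(out) == 0

    def test_partition_identity(self, rng):
        """Sum over (bin, function) groups equals the plain per-sample ORF
        sum — grouping never loses or duplicates signal."""
        n = 60
        recs = pd.DataFrame({
            "bin_id": rng.choice(["b1", "b2"], n),
            "function": rng.choice(["f1", "f2", "f3"], n),
            "sample_id": rng.choice(["s1", "s2"], n),
            "rpkm": rng.uniform(0, 5, n),
        })
        agg = ex.aggregate_function_rpkm(recs)
        for s in ("s1", "s2"):
            assert agg.loc[agg.sample_id == s, "rpkm"].sum() == pytest.approx(
                recs.loc[recs.sample_id == s, "rpkm"].sum())

    def test_associativity(self, rng):
        """Grouping by bin then summing functions equals one grouped sum."""
        n = 40
        recs = pd.DataFrame({
            "bin_id": rng.choice(["b1", "b2"], n),
            "function": rng.choice(["f1", "f2"], n),
            "sample_id": rng.choice(["s1", "s2"], n),
            "rpkm": rng.uniform(0, 5, n),
        })
        direct = ex.aggregate_function_rpkm(recs)
        two_step = ex.aggregate_function_rpkm(
            direct, by=("bin_id", "function", "sample_id"))
        pd.testing.assert_frame_equal(direct, two_step)


class TestProfileByRedox:
    def test_mean_with_zero_sample(self):
        vals = {"a": 2.0, "b": 0.0, "c": 4.0}
        classes = {"a": "anoxic", "b": "anoxic", "c": "anoxic"}
        assert ex.profile_by_redox(vals, classes) == {"anoxic": pytest.approx(2.0)}

    def test_single_sample_class(self):
        got = ex.profile_by_redox({"a": 3.5}, {"a": "oxic"})
        assert got == {"oxic": pytest.approx(3.5)}

    def test_absent_sample_counts_in_denominator(self):
        got = ex.profile_by_redox({"a": 6.0}, {"a": "oxic", "b": "oxic"})
        assert got == {"oxic": pytest.approx(3.0)}

    def test_empty_class_missing_not_zero(self):
        got = ex.profile_by_redox({"a": 1.0}, {"a": "oxic"})
        assert "anoxic" not in got

    def test_unclassified_sample_rejected(self):
        with pytest.raises(ValueError, match="redox class"):
            ex.profile_by_redox({"a": 1.0, "zz": 2.0}, {"a": "oxic"})

    def test_anoxic_induced_marker_elevated(self, fixture1):
        """The simulated 10x anoxic induction of nosZ shows up as a higher
        anoxic-class than oxic-class mean RPKM."""
        orfs = fixture1.truth.orfs.set_index("orf_id")
        recs = fixture1.counts.merge(
            orfs[["gene_length", "function", "clade_id"]],
            left_on="orf_id", right_index=True)
        recs = ex.add_rpkm(recs)
        nosz = recs[recs["function"] == "nosZ"]
        per_sample = nosz.groupby("sample_id")["rpkm"].sum()
        classes = classify_samples(fixture1.samples)
        prof = ex.profile_by_redox(per_sample, classes)
        assert prof["anoxic"] > prof["oxic"]


class TestGreedyClusterMarkers:
    def test_identical_sequences_one_cluster(self):
        clusters = ex.greedy_cluster_markers(
            {"a": 100, "b": 100}, {("a", "b"): 100.0})
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["a", "b"]

    def test_all_distant_singletons(self):
        pairs = {("a", "b"): 90.0, ("a", "c"): 80.0, ("b", "c"): 85.0}
        clusters = ex.greedy_cluster_markers({"a": 90, "b": 80, "c": 70}, pairs)
        assert [c.members for c in clusters] == [["a"], ["b"], ["c"]]

    def test_hand_traced_example(self):
        """Lengths 1>2>3, identities (1,2)=96, (1,3)=96, (2,3)=90: one
        cluster centred on the longest sequence."""
        pairs = {("m1", "m2"): 96.0, ("m1", "m3"): 96.0, ("m2", "m3"): 90.0}
        clusters = ex.greedy_cluster_markers({"m1": 300, "m2": 200, "m3": 100},
                                             pairs)
        assert len(clusters) == 1
        assert clusters[0].centroid == "m1"
        assert clusters[0].members == ["m1", "m2", "m3"]

    def test_length_tie_breaks_lexicographically(self):
        pairs = {("a", "b"): 10.0}
        clusters = ex.greedy_cluster_markers({"b": 100, "a": 100}, pairs)
        assert clusters[0].centroid == "a"

    def test_missing_identity_rejected(self):
        with pytest.raises(KeyError, match="missing"):
            ex.greedy_cluster_markers({"a": 100, "b": 90}, {})

    def test_nosz_style_clustering(self):
        """Two markers at 65% identity with a close variant of the first:
        greedy clustering at 95% yields two clusters, mirroring the split of
        nitrous-oxide-reductase variants between distinct clades."""
        lengths = {"shbh_1": 1_800, "shbh_2": 1_750, "za_1": 1_820}
        pairs = {("shbh_1", "shbh_2"): 97.0, ("shbh_1", "za_1"): 65.0,
                 ("shbh_2", "za_1"): 64.0}
        clusters = ex.greedy_cluster_markers(lengths, pairs)
        got = sorted(sorted(c.members) for c in clusters)
        assert got == [["shbh_1", "shbh_2"], ["za_1"]]
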