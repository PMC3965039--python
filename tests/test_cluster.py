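"""Distance bins, complete linkage vs naive oracle, OTU/BIOM conversion."""
import io
import json

import numpy as np
import pytest

from ampliconkit.cluster import (ClusterError, DistanceBins, Merge,
                                 clusters_at, complete_linkage, dereplicate,
                                 distance_lookup, from_biom,
                                 pairwise_distances, partition_indices,
                                 read_cluster_file, representative_seqs,
                                 to_biom, to_otu_table, write_cluster_file)
from ampliconkit.seqio import ModelAlignment


def naive_complete_linkage(dist: np.ndarray, cutoff: float) -> list[list[int]]:
    """Textbook complete linkage: repeatedly merge the min-max pair."""
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    d = dist.astype(float).copy()
    active = list(range(n))
    cd = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    while True:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = cd[(min(a, b), max(a, b))]
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None or best[0] > cutoff:
            break
        _, a, b = best
        for c in active:
            if c in (a, b):
                continue
            cd[(min(a, c), max(a, c))] = max(cd[(min(a, c), max(a, c))],
                                             cd[(min(b, c), max(b, c))])
        clusters[a] = clusters[a] + clusters[b]
        clusters[b] = []
        active.remove(b)
    return sorted([sorted(c) for c in clusters if c], key=lambda c: c[0])


def random_bins(rng, n, step=0.0025, cutoff=1.0):
    """Random symmetric distances, distinct after quantization (tie-free)."""
    levels = rng.choice(np.arange(1, 4000), size=n * (n - 1) // 2, replace=False)
    dist = np.zeros((n, n))
    bins = DistanceBins(n, step, cutoff)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(levels[k]) * step
            dist[i, j] = dist[j, i] = d
            bins.add(i, j, d)
            k += 1
    return dist, bins


ALN = ModelAlignment(records=[
    ("a", "ACGTACGTACGTACGTACGTACGTACGTAC"),
    ("b", "ACGTACGTACGTACGTACGTACGTACGTAC"),
    ("c", "ACGTACGTACGTACGTACGTACGTACGTAA"),
    ("d", "ACGTACGTACGTACGTACGTACGTACGTAG"),
])


def test_distance_examples():
    bins = pairwise_distances(ALN, cutoff=0.5, step=0.0025)
    d = bins.distances()
    assert d[(0, 1)] == 0.0
    # 1 mismatch over 30 comparable columns
    assert d[(0, 2)] == pytest.approx(round((1 / 30) / 0.0025) * 0.0025)


def test_gap_columns_excluded_and_short_overlap_skipped():
    aln = ModelAlignment(records=[
        ("a", "ACGT" * 10),
        ("b", "ACGT" * 10),
        ("c", "-" * 20 + "ACGT" * 5),   # only 20 comparable columns vs a
    ])
    bins = pairwise_distances(aln, cutoff=0.5)
    d = bins.distances()
    assert (0, 1) in d
    assert (0, 2) not in d  # below the 25-comparable-column floor


def test_one_mismatch_in_hundred_columns():
    base = "ACGT" * 25
    aln = ModelAlignment(records=[("a", base), ("b", base[:-1] + "A")])
    d = pairwise_distances(aln, cutoff=0.5).distances()
    assert d[(0, 1)] == pytest.approx(0.01)


def test_bins_match_naive_full_matrix(rng):
    for _ in range(5):
        n = 12
        rows = []
        base = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        for i in range(n):
            s = list(base)
            for pos in rng.choice(60, size=int(rng.integers(0, 12)), replace=False):
                s[pos] = "ACGT"[int(rng.integers(4))]
            rows.append((f"s{i}", "".join(s)))
        aln = ModelAlignment(records=rows)
        bins = pairwise_distances(aln, cutoff=1.0)
        got = bins.distances()
        for i in range(n):
            for j in range(i + 1, n):
                a, b = rows[i][1], rows[j][1]
                mism = sum(x != y for x, y in zip(a, b))
                assert got[(i, j)] == pytest.approx(
                    round((mism / 60) / 0.0025) * 0.0025)


def test_partitioned_runs_concatenate_to_full(rng):
    bins_full = pairwise_distances(ALN, cutoff=0.5)
    parts = [pairwise_distances(ALN, cutoff=0.5, row_range=(0, 2)),
             pairwise_distances(ALN, cutoff=0.5, row_range=(2, 4))]
    combined = DistanceBins.concatenate(parts)
    assert {lvl: sorted(p) for lvl, p in combined.bins.items()} == \
           {lvl: sorted(p) for lvl, p in bins_full.bins.items()}


def test_dereplicate_counts_conserved():
    aln = ModelAlignment(records=[("a", "ACGT"), ("b", "ACGT"), ("c", "ACGA")])
    unique, members = dereplicate(aln, ["s1", "s2", "s1"])
    assert len(unique.records) == 2
    assert members[0] == {"s1": ["a"], "s2": ["b"]}
    assert sum(len(ids) for m in members for ids in m.values()) == 3


def test_spec_example_merge_order():
    # d(1,2)=0.00, d(3,4)=0.01, cross distances 0.03/0.05
    bins = DistanceBins(4, 0.0025, 1.0)
    bins.add(0, 1, 0.0)
    bins.add(2, 3, 0.01)
    bins.add(0, 2, 0.03)
    bins.add(0, 3, 0.03)
    bins.add(1, 2, 0.03)
    bins.add(1, 3, 0.05)
    merges = complete_linkage(bins)
    assert [(m.distance, m.a, m.b) for m in merges] == \
        [(0.0, 0, 1), (0.01, 2, 3), (0.05, 0, 2)]


def test_two_points_single_merge():
    bins = DistanceBins(2, 0.0025, 1.0)
    bins.add(0, 1, 0.0525)
    merges = complete_linkage(bins)
    assert len(merges) == 1 and merges[0].distance == pytest.approx(0.0525)


def test_complete_linkage_matches_naive_oracle(rng):
    for _ in range(20):
        n = int(rng.integers(5, 25))
        dist, bins = random_bins(rng, n)
        merges = complete_linkage(bins)
        for cutoff in (0.05, 0.5, 1.0, 5.0):
            got = partition_indices(merges, n, cutoff)
            want = naive_complete_linkage(dist, cutoff)
            assert got == want


def test_partitions_nest_with_cutoff(rng):
    n = 20
    _, bins = random_bins(rng, n)
    merges = complete_linkage(bins)
    prev = None
    for cutoff in (0.0, 0.1, 0.5, 1.0, 5.0, 10.0):
        part = partition_indices(merges, n, cutoff)
        if prev is not None:
            # every earlier cluster is contained in one later cluster
            lookup = {i: k for k, grp in enumerate(part) for i in grp}
            for grp in prev:
                assert len({lookup[i] for i in grp}) == 1
        prev = part


def test_clusters_at_expansion_and_cutoff_guard():
    aln = ModelAlignment(records=[("a", "ACGT" * 10), ("b", "ACGT" * 10),
                                  ("c", "TTTT" * 10)])
    unique, members = dereplicate(aln, ["s1", "s2", "s1"])
    bins = pairwise_distances(unique, cutoff=0.15)
    merges = complete_linkage(bins)
    cs = clusters_at(merges, [0.0], members, max_cutoff=0.15)
    clusters = cs.clusters(0.0)
    assert len(clusters) == 2  # dereplicated groups at cutoff 0
    assert {"a"} == set(clusters[0]["s1"]) and {"b"} == set(clusters[0]["s2"])
    with pytest.raises(ClusterError):
        clusters_at(merges, [0.2], members, max_cutoff=0.15)


def test_representative_hand_example_and_oracle(rng):
    bins = DistanceBins(3, 0.0025, 1.0)
    bins.add(0, 1, 0.01)
    bins.add(0, 2, 0.02)
    bins.add(1, 2, 0.03)
    reps = representative_seqs([[0, 1, 2]], distance_lookup(bins), ["a", "b", "c"])
    assert reps == ["a"]  # 5e-4 < 1e-3 < 1.3e-3
    # exhaustive argmin on random clusters
    for _ in range(10):
        n = 8
        dist, bins = random_bins(rng, n, step=0.0001)
        lookup = distance_lookup(bins)
        got = representative_seqs([list(range(n))], lookup,
                                  [f"s{i}" for i in range(n)])
        ss = [sum(dist[i, j] ** 2 for j in range(n) if j != i) for i in range(n)]
        assert got == [f"s{int(np.argmin(ss))}"]
    # singleton is its own representative
    assert representative_seqs([[2]], distance_lookup(bins), ["x", "y", "z"]) == ["z"]


def test_otu_table_and_biom_round_trip():
    clusters = [{"s1": ["a", "b", "c"], "s2": ["d"]}, {"s2": ["e"]}]
    table = to_otu_table(clusters)
    assert table.counts.tolist() == [[3, 1], [0, 1]]
    assert table.total == 5  # grand total conserves clustered reads
    back = from_biom(json.dumps(to_biom(table)))
    assert back.cluster_ids == table.cluster_ids
    assert back.sample_ids == table.sample_ids
    assert (back.counts == table.counts).all()


def test_cluster_file_round_trip():
    clusters = [{"s1": ["a", "b"], "s2": ["c"]}, {"s1": ["d"]}]
    from ampliconkit.cluster import ClusterSet
    cs = ClusterSet([0.03], [clusters])
    buf = io.StringIO()
    write_cluster_file(cs, buf)
    buf.seek(0)
    back = read_cluster_file(buf)
    assert back.cutoffs == [0.03]
    assert back.partitions == [clusters]
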