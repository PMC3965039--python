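"""Complete-linkage OTU clustering over quantized pairwise distances.

Distances are computed on model columns of an alignment (mismatches /
comparable columns, comparing only columns where both records have a
non-gap base; pairs with fewer than 25 comparable columns are skipped).
Distances above the cutoff are dropped and the remainder is bucketed by
a quantization step (default 0.0025) — a counting sort over bounded
bins that replaces the O(n^2 log n^2) comparison sort of an on-disk
edge list and keeps the whole procedure O(n^2).  Row-range partitions
of the distance computation concatenate exactly, so the matrix can be
computed in independent chunks.

Complete linkage then processes bins in ascending order, counting
cross-cluster edges: two clusters merge at quantized distance d exactly
when every cross pair has been seen at <= d.  Identical sequences are
dereplicated first (uniqueness is the unit of clustering), cluster
partitions at any cutoff expand back through the dereplication mapping
to per-sample member lists, and the result converts to an OTU table or
BIOM 1.0 JSON.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence as _Seq

import numpy as np
import pandas as pd

from .seqio import ModelAlignment

DEFAULT_STEP = 0.0025
DEFAULT_CUTOFF = 0.15
MIN_COMPARABLE_COLUMNS = 25

_GAP_CODE = 255


class ClusterError(ValueError):
    pass


@dataclass
class DistanceBins:
    """Quantized pairwise-distance edge lists bucketed by distance level."""

    n: int
    step: float
    cutoff: float
    bins: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def add(self, i: int, j: int, distance: float) -> None:
        level = round(distance / self.step)
        self.bins.setdefault(level, []).append((min(i, j), max(i, j)))

    def n_edges(self) -> int:
        return sum(len(v) for v in self.bins.values())

    def distances(self) -> dict[tuple[int, int], float]:
        return {pair: level * self.step
                for level, pairs in self.bins.items() for pair in pairs}

    @classmethod
    def concatenate(cls, parts: Iterable["DistanceBins"]) -> "DistanceBins":
        """Combine row-range partitions into the full edge set."""
        parts = list(parts)
        if not parts:
            raise ClusterError("no partitions to concatenate")
        first = parts[0]
        out = cls(first.n, first.step, first.cutoff)
        for p in parts:
            if (p.n, p.step, p.cutoff) != (first.n, first.step, first.cutoff):
                raise ClusterError("partitions disagree on n/step/cutoff")
            for level, pairs in p.bins.items():
                out.bins.setdefault(level, []).extend(pairs)
        return out


def _model_matrix(alignment: ModelAlignment) -> np.ndarray:
    rows = []
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    other: dict[str, int] = {}
    for idx in range(len(alignment.records)):
        row = alignment.model_row(idx).upper()
        codes = np.empty(len(row), dtype=np.uint8)
        for c, ch in enumerate(row):
            if ch in base_code:
                codes[c] = base_code[ch]
            elif ch in "-.":
                codes[c] = _GAP_CODE
            else:
                codes[c] = other.setdefault(ch, 4 + len(other))
        rows.append(codes)
    return np.vstack(rows)


def pairwise_distances(alignment: ModelAlignment, cutoff: float = DEFAULT_CUTOFF,
                       step: float = DEFAULT_STEP,
                       row_range: tuple[int, int] | None = None) -> DistanceBins:
    """Quantized distances between aligned records (model columns only).

    ``row_range=(lo, hi)`` restricts the outer loop to rows lo..hi-1;
    disjoint ranges covering all rows concatenate to the full matrix.
    """
    n = len(alignment.records)
    if n < 2:
        raise ClusterError("need at least 2 records")
    mat = _model_matrix(alignment)
    bins = DistanceBins(n, step, cutoff)
    lo, hi = row_range if row_range is not None else (0, n)
    for i in range(lo, min(hi, n - 1)):
        x = mat[i]
        y = mat[i + 1:]
        comparable = (x[None, :] != _GAP_CODE) & (y != _GAP_CODE)
        comp = comparable.sum(axis=1)
        mism = (comparable & (x[None, :] != y)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(comp > 0, mism / np.maximum(comp, 1), np.inf)
        keep = (comp >= MIN_COMPARABLE_COLUMNS) & (d <= cutoff)
        for off in np.nonzero(keep)[0]:
            bins.add(i, i + 1 + int(off), float(d[off]))
    return bins


def dereplicate(alignment: ModelAlignment, samples: _Seq[str]
                ) -> tuple[ModelAlignment, list[dict[str, list[str]]]]:
    """Collapse records with identical model-column strings.

    Returns the unique-record alignment (first-seen representative ids)
    and, per unique record, the member ids grouped by sample label.
    """
    if len(samples) != len(alignment.records):
        raise ClusterError("one sample label per record required")
    seen: dict[str, int] = {}
    unique_records: list[tuple[str, str]] = []
    members: list[dict[str, list[str]]] = []
    for (rid, row), sample in zip(alignment.records, samples):
        key = alignment_model_key(alignment, rid, row)
        if key not in seen:
            seen[key] = len(unique_records)
            unique_records.append((rid, row))
            members.append({})
        members[seen[key]].setdefault(sample, []).append(rid)
    return ModelAlignment(records=unique_records), members


def alignment_model_key(alignment: ModelAlignment, rid: str, row: str) -> str:
    return "".join(row[c].upper() for c in alignment.model_columns)


@dataclass(frozen=True)
class Merge:
    distance: float
    a: int  # smallest member index of one cluster
    b: int  # smallest member index of the other


def complete_linkage(bins: DistanceBins) -> list[Merge]:
    """Edge-counting complete linkage over ascending distance bins.

    Two clusters A and B merge at level d the moment the number of
    cross edges seen at <= d reaches |A| * |B|; merges cascade within a
    level because combining neighbor counters can complete other pairs.
    """
    n = bins.n
    parent = list(range(n))
    size = [1] * n
    low = list(range(n))  # smallest member index per root, for stable labels

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # neighbor[root]: cross-edge counts keyed by the other cluster's
    # current root; mirrors are rewritten on every merge so keys stay live
    neighbor: list[dict[int, int]] = [dict() for _ in range(n)]
    merges: list[Merge] = []

    def absorb(ra: int, rb: int, dist: float) -> int:
        """Fold cluster rb into ra, combining neighbor counters."""
        merges.append(Merge(dist, min(low[ra], low[rb]), max(low[ra], low[rb])))
        parent[rb] = ra
        size[ra] += size[rb]
        low[ra] = min(low[ra], low[rb])
        counts = neighbor[ra]
        counts.pop(rb, None)
        for other, c in neighbor[rb].items():
            if other == ra:
                continue
            counts[other] = counts.get(other, 0) + c
            mirror = neighbor[other]
            mirror.pop(rb, None)
            mirror[ra] = counts[other]
        neighbor[rb] = {}
        return ra

    for level in sorted(bins.bins):
        dist = level * bins.step
        pending: list[tuple[int, int]] = []
        for i, j in bins.bins[level]:
            ra, rb = find(i), find(j)
            if ra == rb:
                continue
            c = neighbor[ra].get(rb, 0) + 1
            neighbor[ra][rb] = c
            neighbor[rb][ra] = c
            if c == size[ra] * size[rb]:
                pending.append((ra, rb))
        # merges cascade within a level: combined counters can complete
        # other cluster pairs at the same distance
        while pending:
            a, b = pending.pop()
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            if neighbor[ra].get(rb, 0) != size[ra] * size[rb]:
                continue
            root = absorb(ra, rb, dist) if size[ra] >= size[rb] \
                else absorb(rb, ra, dist)
            for other, c in neighbor[root].items():
                if c == size[root] * size[other]:
                    pending.append((root, other))
    return merges


@dataclass
class ClusterSet:
    """Partitions of record ids at each cutoff, with per-sample members."""

    cutoffs: list[float]
    # per cutoff: list of clusters; each cluster maps sample -> member ids
    partitions: list[list[dict[str, list[str]]]]

    def clusters(self, cutoff: float) -> list[dict[str, list[str]]]:
        return self.partitions[self.cutoffs.index(cutoff)]


def partition_indices(merges: list[Merge], n: int, cutoff: float) -> list[list[int]]:
    """Unique-record index partition induced by merges at <= cutoff."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    eps = 1e-9
    for m in merges:
        if m.distance <= cutoff + eps:
            ra, rb = find(m.a), find(m.b)
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: g[0])]


def clusters_at(merges: list[Merge], cutoffs: _Seq[float],
                members: _Seq[Mapping[str, list[str]]],
                max_cutoff: float = DEFAULT_CUTOFF) -> ClusterSet:
    """Expand merge lists into per-cutoff, per-sample cluster membership.

    ``members`` is the dereplication mapping (per unique record, sample
    -> original ids).  Cutoffs beyond the distance cutoff used for the
    bins cannot be answered and raise.
    """
    n = len(members)
    partitions = []
    for cutoff in cutoffs:
        if cutoff < 0:
            raise ClusterError("negative cutoff")
        if cutoff > max_cutoff:
            raise ClusterError(
                f"cutoff {cutoff} exceeds computed distance cutoff {max_cutoff}; "
                "recompute distances with a larger cutoff")
        clusters = []
        for group in partition_indices(merges, n, cutoff):
            by_sample: dict[str, list[str]] = {}
            for idx in group:
                for sample, ids in members[idx].items():
                    by_sample.setdefault(sample, []).extend(ids)
            clusters.append(by_sample)
        partitions.append(clusters)
    return ClusterSet(list(cutoffs), partitions)


def representative_seqs(clusters: list[list[int]],
                        distance: Callable[[int, int], float],
                        ids: _Seq[str]) -> list[str]:
    """Per cluster, the member with least sum of squared distances to the
    rest (ties to the lexicographically smallest id)."""
    reps = []
    for group in clusters:
        best_id, best_ss = None, None
        for i in group:
            ss = sum(distance(i, j) ** 2 for j in group if j != i)
            if best_ss is None or ss < best_ss - 1e-15 or (
                    abs(ss - best_ss) <= 1e-15 and ids[i] < best_id):
                best_id, best_ss = ids[i], ss
        reps.append(best_id)
    return reps


def distance_lookup(bins: DistanceBins, default: float = np.inf
                    ) -> Callable[[int, int], float]:
    table = bins.distances()

    def lookup(i: int, j: int) -> float:
        if i == j:
            return 0.0
        return table.get((min(i, j), max(i, j)), default)

    return lookup


# ---------------------------------------------------------------------------
# OTU tables and formats
# ---------------------------------------------------------------------------

@dataclass
class OTUTable:
    cluster_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # clusters x samples, non-negative ints

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cluster_ids,
                            columns=self.sample_ids)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def to_otu_table(clusters: list[dict[str, list[str]]],
                 sample_ids: _Seq[str] | None = None) -> OTUTable:
    """OTU table (rows clusters, columns samples) from one cutoff's
    partition."""
    if sample_ids is None:
        seen: list[str] = []
        for cl in clusters:
            for s in cl:
                if s not in seen:
                    seen.append(s)
        sample_ids = sorted(seen)
    counts = np.zeros((len(clusters), len(sample_ids)), dtype=np.int64)
    for r, cl in enumerate(clusters):
        for c, s in enumerate(sample_ids):
            counts[r, c] = len(cl.get(s, []))
    names = [f"OTU_{r + 1}" for r in range(len(clusters))]
    return OTUTable(names, list(sample_ids), counts)


def to_biom(table: OTUTable, table_id: str = "ampliconkit OTU table") -> dict:
    """Sparse BIOM 1.0 JSON object."""
    rows, cols = np.nonzero(table.counts)
    data = [[int(r), int(c), int(table.counts[r, c])] for r, c in zip(rows, cols)]
    return {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "ampliconkit",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [len(table.cluster_ids), len(table.sample_ids)],
        "rows": [{"id": cid, "metadata": None} for cid in table.cluster_ids],
        "columns": [{"id": sid, "metadata": None} for sid in table.sample_ids],
        "data": data,
    }


def from_biom(obj: dict | str) -> OTUTable:
    if isinstance(obj, str):
        obj = json.loads(obj)
    shape = obj["shape"]
    counts = np.zeros(shape, dtype=np.int64)
    if obj["matrix_type"] == "sparse":
        for r, c, v in obj["data"]:
            counts[r, c] = v
    else:
        counts[:] = np.asarray(obj["data"], dtype=np.int64)
    return OTUTable([r["id"] for r in obj["rows"]],
                    [c["id"] for c in obj["columns"]], counts)


def write_cluster_file(cluster_set: ClusterSet, dest) -> None:
    """TSV dialect: per cutoff a ``#cutoff<TAB>k`` header, then rows
    ``cutoff, cluster_id, sample, count, comma-separated ids``."""
    own = not hasattr(dest, "write")
    handle = open(dest, "w") if own else dest
    try:
        for cutoff, clusters in zip(cluster_set.cutoffs, cluster_set.partitions):
            handle.write(f"#cutoff\t{len(clusters)}\n")
            for cid, cl in enumerate(clusters, start=1):
                for sample in sorted(cl):
                    ids = ",".join(cl[sample])
                    handle.write(f"{cutoff:g}\t{cid}\t{sample}\t{len(cl[sample])}\t{ids}\n")
    finally:
        if own:
            handle.close()


def read_cluster_file(source) -> ClusterSet:
    own = not hasattr(source, "read")
    handle = open(source) if own else source
    try:
        cutoffs: list[float] = []
        partitions: list[list[dict[str, list[str]]]] = []
        current: dict[int, dict[str, list[str]]] = {}
        cur_cutoff: float | None = None

        def flush() -> None:
            nonlocal current, cur_cutoff
            if cur_cutoff is not None:
                cutoffs.append(cur_cutoff)
                partitions.append([current[k] for k in sorted(current)])
            current, cur_cutoff = {}, None

        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#cutoff"):
                flush()
                continue
            cutoff_s, cid, sample, _count, ids = line.split("\t")
            cur_cutoff = float(cutoff_s)
            current.setdefault(int(cid), {})[sample] = ids.split(",") if ids else []
        flush()
        return ClusterSet(cutoffs, partitions)
    finally:
        if own:
            handle.close()
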