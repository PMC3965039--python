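"""Retrainable naive Bayes genus classifier with bootstrap confidence.

Training over N sequences builds, for every possible 8-base word w, a
prior P_w = (n(w) + 0.5) / (N + 1) from the number n(w) of training
sequences containing w, and for every genus g with M_g training
sequences a conditional probability (m_g(w) + P_w) / (M_g + 1), where
m_g(w) counts that genus's sequences containing w.  A query is scored
by summing log conditionals over a random subsample of one eighth of
its word positions; 100 such bootstrap trials vote for the top-scoring
genus (ties split 1/g so each trial contributes exactly one vote), and
the vote fractions, accumulated up the lineage, are the per-rank
confidence estimates.

Two classified libraries can be compared per taxon: an exact two-sided
binomial test when the pooled expected count in the smaller library is
below 20, a two-proportion chi-square approximation otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as _Seq

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Sequence
from .seqmatch import word_positions
from .taxonomy import TaxonomyTree, TaxonNode

WORD_SIZE = 8
N_WORDS = 4 ** WORD_SIZE
DEFAULT_TRIALS = 100
DEFAULT_CONFIDENCE_CUTOFF = 0.8


class ClassifierError(ValueError):
    pass


@dataclass
class TrainedModel:
    tree: TaxonomyTree
    genus_taxids: list[int]            # one per genus, model row order
    genus_counts: np.ndarray           # M_g, shape (G,)
    log_cond: np.ndarray               # log conditionals, shape (G, 4^8) float32
    word_prior: np.ndarray             # P_w, shape (4^8,)
    n_training: int

    @property
    def n_genera(self) -> int:
        return len(self.genus_taxids)


def _occupancy(seqs: Iterable[Sequence]) -> list[np.ndarray]:
    """Unique encoded 8-mers per training sequence."""
    out = []
    for s in seqs:
        try:
            words = word_positions(s.residues, WORD_SIZE)
        except Exception as exc:
            raise ClassifierError(f"training sequence {s.id!r}: {exc}") from exc
        out.append(np.unique(np.asarray(words, dtype=np.int64)))
    return out


def train(seqs: _Seq[Sequence], tree: TaxonomyTree,
          lineages: _Seq[list[str]] | None = None) -> TrainedModel:
    """Train from sequences whose lineages resolve to genus-level nodes.

    ``lineages`` gives a root-first name path per sequence; when absent,
    each record's description is parsed as a ``;``-separated lineage.
    Unresolvable lineages are reported together, so taxonomy errors in a
    custom training set surface in one pass.
    """
    if not seqs:
        raise ClassifierError("no training sequences")
    if lineages is None:
        lineages = [[p.strip() for p in s.description.split(";") if p.strip()]
                    for s in seqs]
    errors = []
    genus_of: list[int] = []
    for s, path in zip(seqs, lineages):
        try:
            genus_of.append(tree.resolve_path(list(path)).taxid)
        except Exception as exc:
            errors.append(f"{s.id}: {exc}")
    if errors:
        raise ClassifierError("unresolvable training lineages:\n" + "\n".join(errors))

    order = sorted(set(genus_of))
    gidx = {t: i for i, t in enumerate(order)}
    G, N = len(order), len(seqs)
    occ = _occupancy(seqs)

    n_w = np.zeros(N_WORDS, dtype=np.int64)
    m_gw = np.zeros((G, N_WORDS), dtype=np.int32)
    M_g = np.zeros(G, dtype=np.int64)
    for words, taxid in zip(occ, genus_of):
        n_w[words] += 1
        m_gw[gidx[taxid], words] += 1
        M_g[gidx[taxid]] += 1

    prior = (n_w + 0.5) / (N + 1)
    log_cond = np.log((m_gw + prior[None, :]) / (M_g[:, None] + 1)).astype(np.float32)
    return TrainedModel(tree, order, M_g, log_cond, prior, N)


@dataclass
class Assignment:
    """Per-rank (taxon, confidence) path for one query, root to genus."""

    query_id: str
    path: list[tuple[TaxonNode, float]]

    def assigned_node(self, cutoff: float) -> TaxonNode:
        """Lowest taxon whose bootstrap confidence reaches ``cutoff``."""
        node = self.path[0][0]
        for n, conf in self.path:
            if conf >= cutoff:
                node = n
            else:
                break
        return node

    def genus_confidence(self) -> float:
        return self.path[-1][1]


def _vote(scores: np.ndarray) -> np.ndarray:
    """Per-genus vote fractions from a (G, trials) score matrix; tied
    top scores within a trial split the trial's single vote evenly."""
    top = scores.max(axis=0)
    ties = scores == top[None, :]
    votes = (ties / ties.sum(axis=0)[None, :]).sum(axis=1)
    return votes / scores.shape[1]


def classify(seq: Sequence, model: TrainedModel, trials: int = DEFAULT_TRIALS,
             seed: int | np.random.Generator = 0) -> Assignment:
    """Bootstrap classification of one query down to genus rank."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        words = word_positions(seq.residues, WORD_SIZE)
    except Exception as exc:
        raise ClassifierError(f"query {seq.id!r}: {exc}") from exc
    if not words:
        raise ClassifierError(f"query {seq.id!r}: no clean {WORD_SIZE}-mers")
    warr = np.asarray(words, dtype=np.int64)
    V = len(warr)
    n_sub = max(1, V // WORD_SIZE)
    picks = rng.integers(0, V, size=(trials, n_sub))
    scores = model.log_cond[:, warr[picks]].sum(axis=2, dtype=np.float64)
    votes = _vote(scores)

    # winning genus: most votes, ties to the lexicographically first name
    best = min(range(model.n_genera),
               key=lambda g: (-votes[g], model.tree.nodes[model.genus_taxids[g]].name))
    lineage = model.tree.lineage(model.genus_taxids[best])
    lineage_ids = [n.taxid for n in lineage]
    conf = {t: 0.0 for t in lineage_ids}
    for g, taxid in enumerate(model.genus_taxids):
        for anc in model.tree.lineage(taxid):
            if anc.taxid in conf:
                conf[anc.taxid] += votes[g]
    path = [(n, min(1.0, conf[n.taxid])) for n in lineage]
    return Assignment(seq.id, path)


def classify_samples(samples: Mapping[str, _Seq[Sequence]], model: TrainedModel,
                     cutoff: float = DEFAULT_CONFIDENCE_CUTOFF,
                     trials: int = DEFAULT_TRIALS,
                     seed: int = 0) -> tuple[pd.DataFrame, dict[str, list[Assignment]]]:
    """Classify several samples into a taxon-by-sample count matrix.

    Each query is assigned to its lowest taxon with confidence >= cutoff
    (falling back to an above-cutoff ancestor; the root always
    qualifies), and every node from the root down to the assigned taxon
    is incremented — so a taxon row counts queries assigned at or below
    it, and the root row of each column equals the sample size.

    Returns the matrix (index: (rank, taxon name)) and per-sample
    assignment details.
    """
    rng = np.random.default_rng(seed)
    counts: dict[int, dict[str, int]] = {}
    details: dict[str, list[Assignment]] = {}
    for sample, seqs in samples.items():
        details[sample] = []
        for seq in seqs:
            asn = classify(seq, model, trials=trials, seed=rng)
            details[sample].append(asn)
            target = asn.assigned_node(cutoff)
            for node in model.tree.lineage(target.taxid):
                counts.setdefault(node.taxid, {}).setdefault(sample, 0)
                counts[node.taxid][sample] += 1
    tree = model.tree
    taxids = sorted(counts, key=lambda t: (tree.nodes[t].depth, tree.nodes[t].name))
    index = pd.MultiIndex.from_tuples(
        [(tree.nodes[t].rank, tree.nodes[t].name) for t in taxids],
        names=["rank", "taxon"])
    mat = pd.DataFrame(0, index=index, columns=list(samples), dtype=int)
    for t, row in zip(taxids, mat.index):
        for sample, c in counts[t].items():
            mat.loc[row, sample] = c
    mat.attrs["taxids"] = taxids
    return mat, details


EXPECTED_COUNT_SWITCH = 20.0


def compare_libraries(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon two-library significance test on a 2-column count matrix
    from :func:`classify_samples`.

    For a taxon with x1 of n1 assignments versus x2 of n2 (n = library
    sizes from the root row): when the pooled expected count in the
    smaller library is below 20, an exact two-sided binomial test of x1
    out of x1+x2 at success probability n1/(n1+n2); otherwise a 2x2
    chi-square without continuity correction.  Output sorted by P value
    with columns p, rank, taxon, n_sample1, n_sample2.
    """
    if matrix.shape[1] != 2:
        raise ClassifierError("compare_libraries needs exactly two sample columns")
    s1, s2 = matrix.columns
    root_mask = [r == "rootrank" for r, _ in matrix.index]
    if any(root_mask):
        root_row = matrix[root_mask].iloc[0]
        n1, n2 = int(root_row[s1]), int(root_row[s2])
    else:
        n1, n2 = int(matrix[s1].max()), int(matrix[s2].max())
    if n1 == 0 or n2 == 0:
        raise ClassifierError("empty library")
    rows = []
    for (rank, name), row in matrix.iterrows():
        x1, x2 = int(row[s1]), int(row[s2])
        total = x1 + x2
        if total == 0:
            p = 1.0
        else:
            p_pool = n1 / (n1 + n2)
            expected_smaller = total * min(n1, n2) / (n1 + n2)
            if expected_smaller < EXPECTED_COUNT_SWITCH:
                p = stats.binomtest(x1, total, p_pool).pvalue
            else:
                table = np.array([[x1, n1 - x1], [x2, n2 - x2]])
                if table.min() < 0:
                    raise ClassifierError(f"taxon {name!r}: count exceeds library size")
                p = stats.chi2_contingency(table, correction=False)[1] \
                    if table.sum(axis=0).min() > 0 else 1.0
        rows.append((p, rank, name, x1, x2))
    out = pd.DataFrame(rows, columns=["p", "rank", "taxon", "n_sample1", "n_sample2"])
    return out.sort_values("p", kind="stable").reset_index(drop=True)
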