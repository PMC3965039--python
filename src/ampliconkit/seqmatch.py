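"""Word-sharing nearest-neighbor search.

Two sequences are compared by the fraction of unique overlapping
7-base words they share, normalized by the smaller unique-word count
(the S_ab score).  Words containing any symbol outside {A,C,G,T} are
skipped rather than expanded.  The searcher scores both orientations
of the query and keeps the better one per reference; the top-k hits
feed a lowest-common-ancestor assignment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .seqio import Sequence, reverse_complement
from .taxonomy import TaxonomyTree, TaxonNode

DEFAULT_WORD_SIZE = 7

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SeqMatchError(ValueError):
    pass


@dataclass(frozen=True)
class WordSet:
    """Unique clean w-mers of one sequence, encoded 2 bits/base."""

    owner: str
    words: frozenset[int]

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class MatchHit:
    query_id: str
    match_id: str
    orientation: str  # '+' or '-'
    sab: float
    shared_words: int


def word_positions(residues: str, w: int = DEFAULT_WORD_SIZE) -> list[int]:
    """Encoded words at every clean (ACGT-only) window, in sequence order.

    Duplicates are kept; this is the word list the classifier's
    bootstrap samples from.
    """
    s = residues.upper()
    if len(s) < w:
        raise SeqMatchError(f"sequence shorter than word size {w}")
    out: list[int] = []
    code = 0
    run = 0  # clean-window run length ending at current base
    mask = (1 << (2 * w)) - 1
    for ch in s:
        b = _BASE_CODE.get(ch)
        if b is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | b) & mask
        run += 1
        if run >= w:
            out.append(code)
    return out


def unique_words(seq: Sequence | str, w: int = DEFAULT_WORD_SIZE) -> WordSet:
    """Set of distinct w-mers from clean windows of ``seq``."""
    if isinstance(seq, Sequence):
        owner, residues = seq.id, seq.residues
    else:
        owner, residues = "", seq
    return WordSet(owner, frozenset(word_positions(residues, w)))


def decode_word(code: int, w: int = DEFAULT_WORD_SIZE) -> str:
    bases = "ACGT"
    return "".join(bases[(code >> (2 * (w - 1 - i))) & 3] for i in range(w))


def sab_score(a: WordSet, b: WordSet) -> float:
    """|a ∩ b| / min(|a|, |b|) — in [0, 1]."""
    if not a.words or not b.words:
        raise SeqMatchError("S_ab undefined for an empty word set")
    return len(a.words & b.words) / min(len(a.words), len(b.words))


class ReferenceIndex:
    """Pre-computed word sets (and optional taxon ids) for references."""

    def __init__(self, refs: Iterable[Sequence], w: int = DEFAULT_WORD_SIZE,
                 taxa: Mapping[str, int] | None = None):
        self.w = w
        self.entries: list[tuple[str, WordSet]] = [
            (r.id, unique_words(r, w)) for r in refs]
        if not self.entries:
            raise SeqMatchError("empty reference index")
        self.taxa = dict(taxa) if taxa else {}


def search(query: Sequence, refs: ReferenceIndex, k: int = 20,
           cutoff: float = 0.0) -> list[MatchHit]:
    """Top-k references by S_ab, better orientation kept per reference.

    Hits sorted by S_ab descending, ties by more shared words then by
    match id; filtered at ``cutoff`` then truncated to ``k``.
    """
    if k < 1:
        raise SeqMatchError("k must be >= 1")
    fwd = unique_words(query, refs.w)
    rev = unique_words(reverse_complement(query), refs.w)
    if not fwd.words:
        return []
    hits = []
    for rid, ws in refs.entries:
        if not ws.words:
            continue
        shared_f = len(fwd.words & ws.words)
        shared_r = len(rev.words & ws.words)
        if shared_r > shared_f:
            orient, shared, denom = "-", shared_r, min(len(rev.words), len(ws.words))
        else:
            orient, shared, denom = "+", shared_f, min(len(fwd.words), len(ws.words))
        sab = shared / denom
        if sab >= cutoff:
            hits.append(MatchHit(query.id, rid, orient, sab, shared))
    hits.sort(key=lambda h: (-h.sab, -h.shared_words, h.match_id))
    return hits[:k]


def knn_assign(query: Sequence, refs: ReferenceIndex, k: int,
               tree: TaxonomyTree, cutoff: float = 0.0) -> TaxonNode:
    """LCA of the taxa of the k top matches; tree root when nothing hits."""
    hits = search(query, refs, k=k, cutoff=cutoff)
    if not hits:
        return tree.nodes[tree.root]
    taxids = []
    for h in hits:
        if h.match_id not in refs.taxa:
            raise SeqMatchError(f"reference {h.match_id!r} has no taxon mapping")
        taxids.append(refs.taxa[h.match_id])
    return tree.lca(taxids)


def screen_by_sab(query: Sequence, exemplars: Mapping[str, Iterable[Sequence]],
                  threshold: float = 0.3,
                  w: int = DEFAULT_WORD_SIZE) -> tuple[bool, str | None, float]:
    """Keep a sequence iff its best S_ab against any domain exemplar set
    reaches ``threshold``; returns (keep, best domain label, best score).

    This is the database-intake screen: candidate rRNA sequences are
    kept only when similar enough to a hand-curated exemplar panel.
    """
    try:
        fwd = unique_words(query, w)
        rev = unique_words(reverse_complement(query), w)
    except SeqMatchError:
        return False, None, 0.0
    if not fwd.words:
        return False, None, 0.0
    best_label, best_score = None, -1.0
    for label, seqs in exemplars.items():
        for ref in seqs:
            ws = unique_words(ref, w)
            if not ws.words:
                continue
            score = max(sab_score(fwd, ws), sab_score(rev, ws))
            if score > best_score:
                best_label, best_score = label, score
    if best_score < 0:
        return False, None, 0.0
    return best_score >= threshold, best_label, best_score
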