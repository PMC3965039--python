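"""Defined-community (mock) error-rate analysis and synthetic data
generation.

A defined community is a sequencing sample of organisms whose reference
genes are known; observed per-base error rates are measured by matching
each read to its best reference (word-sharing search, both strands)
and counting substitutions, insertions and deletions in a semi-global
alignment (free end gaps on the read; match +1, mismatch -1, gap open
-4, gap extend -1 — exposed as parameters).

The same module generates the synthetic communities and reads the test
suite runs on: genus ancestors mutated from a common root at a stated
inter-genus divergence, sequences mutated from their ancestor at an
intra-genus divergence, and paired reads with position-dependent
Phred-governed substitution errors plus a truth table of every injected
error.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence as _Seq

import numpy as np
from Bio import Align

from .assembler import read_q
from .seqio import Sequence, reverse_complement
from .seqmatch import ReferenceIndex, search as sab_search
from .taxonomy import TaxonomyTree, tree_from_lineages

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class QCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Alignment to reference and error rates
# ---------------------------------------------------------------------------

def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -4.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # the read may map inside the reference: reference overhangs are free
    if hasattr(aligner, "open_end_deletion_score"):
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    else:
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


@dataclass
class ReadErrors:
    read_id: str
    reference_id: str
    strand: str
    aligned_length: int
    substitutions: int
    insertions: int
    deletions: int
    read_q: float | None = None

    @property
    def total_errors(self) -> int:
        return self.substitutions + self.insertions + self.deletions

    @property
    def error_rate(self) -> float:
        return self.total_errors / self.aligned_length


def align_to_reference(read: Sequence, refs: _Seq[Sequence],
                       index: ReferenceIndex | None = None,
                       aligner: Align.PairwiseAligner | None = None) -> ReadErrors:
    """Best reference by S_ab (both strands), then a semi-global
    alignment of the read to it; errors counted inside the read's span."""
    if not refs:
        raise QCError("empty reference set")
    if index is None:
        index = ReferenceIndex(refs)
    hits = sab_search(read, index, k=1)
    if hits:
        ref_id, strand = hits[0].match_id, hits[0].orientation
    else:
        ref_id, strand = refs[0].id, "+"
    ref = next(r for r in refs if r.id == ref_id)
    oriented = read if strand == "+" else reverse_complement(read)
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(ref.residues.upper(), oriented.residues.upper())[0]
    t_aligned, q_aligned = str(aln[0]), str(aln[1])
    # span of the read inside the alignment (strip reference overhangs)
    first = next(i for i, ch in enumerate(q_aligned) if ch != "-")
    last = len(q_aligned) - 1 - next(
        i for i, ch in enumerate(reversed(q_aligned)) if ch != "-")
    sub = ins = dele = 0
    for t, q in zip(t_aligned[first:last + 1], q_aligned[first:last + 1]):
        if t == "-":
            ins += 1
        elif q == "-":
            dele += 1
        elif t != q:
            sub += 1
    rq = read_q(read.qualities) if read.qualities is not None else None
    return ReadErrors(read.id, ref_id, strand, last - first + 1, sub, ins, dele, rq)


@dataclass
class ErrorReport:
    per_read: list[ReadErrors]
    by_class: dict[str, int] = field(default_factory=dict)

    @property
    def aggregate_rate(self) -> float:
        """Length-weighted mean per-base error rate."""
        total_len = sum(r.aligned_length for r in self.per_read)
        total_err = sum(r.total_errors for r in self.per_read)
        return total_err / total_len if total_len else 0.0

    def rate_at_read_q(self, min_read_q: float) -> float:
        kept = [r for r in self.per_read
                if r.read_q is not None and r.read_q >= min_read_q]
        total_len = sum(r.aligned_length for r in kept)
        total_err = sum(r.total_errors for r in kept)
        return total_err / total_len if total_len else 0.0


def error_rates(reads: Iterable[Sequence], refs: _Seq[Sequence]) -> ErrorReport:
    """Observed error rates of a defined-community sample against its
    known reference genes."""
    index = ReferenceIndex(refs)
    aligner = _make_aligner()
    per_read = [align_to_reference(r, refs, index, aligner) for r in reads]
    by_class = {
        "substitutions": sum(r.substitutions for r in per_read),
        "insertions": sum(r.insertions for r in per_read),
        "deletions": sum(r.deletions for r in per_read),
    }
    return ErrorReport(per_read, by_class)


# ---------------------------------------------------------------------------
# Synthetic communities and reads
# ---------------------------------------------------------------------------

def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with probability ``rate`` to a different
    base (uniform over the other three)."""
    out = codes.copy()
    hit = np.nonzero(rng.random(codes.size) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = (out[hit] + shift) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def simulate_community(num_genera: int = 5, seqs_per_genus: int = 8,
                       inter_divergence: float = 0.03,
                       intra_divergence: float = 0.005,
                       length: int = 450, seed: int = 0
                       ) -> tuple[list[Sequence], TaxonomyTree, dict[str, list[str]]]:
    """Reference genes for a synthetic community.

    A random root gene is mutated once per genus at ``inter_divergence``
    (the genus ancestor) and each sequence is mutated from its ancestor
    at ``intra_divergence``.  Returns (references, taxonomy tree,
    lineage name path per reference id).
    """
    if not (0 <= inter_divergence < 0.5 and 0 <= intra_divergence < 0.5):
        raise QCError("divergences must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=length).astype(np.uint8)
    refs: list[Sequence] = []
    lineages: dict[str, list[str]] = {}
    lineage_spec = []
    for g in range(1, num_genera + 1):
        ancestor = _mutate(root, inter_divergence, rng)
        genus = f"Genus{g}"
        lineage_spec.append((["Bacteria", genus], ["domain", "genus"]))
        for s in range(1, seqs_per_genus + 1):
            rid = f"G{g}_S{s}"
            seq = _mutate(ancestor, intra_divergence, rng)
            refs.append(Sequence(rid, _to_str(seq),
                                 description=f"Root;Bacteria;{genus}"))
            lineages[rid] = ["Root", "Bacteria", genus]
    tree = tree_from_lineages(lineage_spec)
    return refs, tree, lineages


def linear_q_profile(read_length: int, q_start: int = 38, q_end: int = 25) -> np.ndarray:
    """Position-dependent quality profile decaying linearly along the read."""
    return np.round(np.linspace(q_start, q_end, read_length)).astype(int)


@dataclass
class ReadTruth:
    read_id: str
    source_id: str
    fragment_start: int
    fragment_length: int
    errors_fwd: list[int]   # 0-based read positions with injected errors
    errors_rev: list[int]
    read_through: bool = False


_ADAPTER = "CTGTCTCTTATACACATCTCCGAGCCCACGAGAC"


def simulate_reads(refs: _Seq[Sequence], n_reads: int = 1000,
                   read_length: int = 250, paired: bool = True,
                   fragment_length: int = 400,
                   q_profile: np.ndarray | None = None,
                   seed: int = 0
                   ) -> tuple[list[tuple[Sequence, Sequence]] | list[Sequence],
                              list[ReadTruth]]:
    """Simulate amplicon reads with Phred-governed substitution errors.

    Fragments are the first ``fragment_length`` bases of a uniformly
    chosen reference (amplicons share their primer-anchored start).
    When the fragment is shorter than the read, sequencing runs through
    into adapter (read-through layout, flagged in the truth record).
    """
    if q_profile is None:
        q_profile = linear_q_profile(read_length)
    q_profile = np.asarray(q_profile, dtype=int)
    if q_profile.size != read_length:
        raise QCError("q_profile length must equal read_length")
    eps = np.power(10.0, -q_profile / 10.0)
    rng = np.random.default_rng(seed)
    code_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref_codes = [np.array([code_of[c] for c in r.residues.upper()], dtype=np.uint8)
                 for r in refs]

    def sequencer_pass(template: np.ndarray) -> tuple[np.ndarray, list[int]]:
        """Pad with adapter to read length, inject per-position errors."""
        if template.size < read_length:
            pad = np.array([code_of[c] for c in
                            (_ADAPTER * (read_length // len(_ADAPTER) + 1))],
                           dtype=np.uint8)[:read_length - template.size]
            template = np.concatenate([template, pad])
        else:
            template = template[:read_length]
        hit = np.nonzero(rng.random(read_length) < eps)[0]
        out = template.copy()
        if hit.size:
            out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
        return out, hit.tolist()

    quals = q_profile.tolist()
    reads: list = []
    truths: list[ReadTruth] = []
    for i in range(n_reads):
        src = int(rng.integers(0, len(refs)))
        frag = ref_codes[src][:fragment_length]
        rid = f"read_{i}"
        fwd_codes, err_f = sequencer_pass(frag)
        fwd = Sequence(f"{rid}/1", _to_str(fwd_codes), qualities=list(quals))
        if paired:
            rev_template = (3 - frag[::-1]) % 4  # reverse complement in codes
            rev_codes, err_r = sequencer_pass(rev_template)
            rev = Sequence(f"{rid}/2", _to_str(rev_codes), qualities=list(quals))
            reads.append((fwd, rev))
        else:
            err_r = []
            reads.append(fwd)
        truths.append(ReadTruth(rid, refs[src].id, 0, min(fragment_length,
                                                          len(ref_codes[src])),
                                err_f, err_r,
                                read_through=frag.size < read_length))
    return reads, truths


def truth_table_rows(truths: Iterable[ReadTruth]) -> list[dict]:
    """TSV-ready rows so downstream scoring never re-derives truth."""
    return [{"read_id": t.read_id, "source_id": t.source_id,
             "fragment_start": t.fragment_start,
             "fragment_length": t.fragment_length,
             "errors_fwd": ",".join(map(str, t.errors_fwd)),
             "errors_rev": ",".join(map(str, t.errors_rev)),
             "read_through": int(t.read_through)} for t in truths]
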