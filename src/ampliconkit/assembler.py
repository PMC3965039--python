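"""Paired-end read overlap assembly with posterior quality scores.

The reverse read is reverse-complemented and slid against the forward
read; every candidate offset (including read-through layouts where the
amplicon is shorter than a read) is scored by the log-likelihood of the
observed base pairs given the sequencer's per-base error estimates
eps = 10^(-Q/10):

* agreeing bases contribute  log[(1-e1)(1-e2) + e1*e2/3]
* disagreeing bases          log[(1-e1)*e2/3 + e1*(1-e2)/3 + 2*e1*e2/9]

The max-score offset wins (ties go to the smaller overlap).  In the
overlap, agreeing bases keep the base with posterior error
e' = (e1*e2/3) / (1 - e1 - e2 + 4*e1*e2/3); disagreeing positions keep
the higher-quality base with posterior error from the normalized
three-hypothesis Bayes rule under a uniform base prior.  Posterior Q
values are rounded to integers and clamped to [2, 93].  The read Q
score, -10*log10(mean per-base error probability), summarizes a whole
read for quality filtering (recommended cutoff 25-27).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import MAX_QUALITY, Sequence, reverse_complement

MIN_POSTERIOR_Q = 2
DEFAULT_MIN_OVERLAP = 10
#: reject assemblies whose mean per-column log-likelihood is below this
#: (true overlaps score near 0; random alignments near -1)
DEFAULT_MIN_COLUMN_SCORE = -1.0


class AssemblyError(ValueError):
    pass


def _error_probs() -> np.ndarray:
    q = np.arange(MAX_QUALITY + 1, dtype=np.float64)
    return np.power(10.0, -q / 10.0)

_EPS = _error_probs()
_E1 = _EPS[:, None]
_E2 = _EPS[None, :]
#: log-likelihood tables indexed [q1, q2]
_LOG_AGREE = np.log((1 - _E1) * (1 - _E2) + _E1 * _E2 / 3)
_LOG_DISAGREE = np.log((1 - _E1) * _E2 / 3 + _E1 * (1 - _E2) / 3 + 2 * _E1 * _E2 / 9)


def posterior_agree_eps(q1: int, q2: int) -> float:
    e1, e2 = _EPS[q1], _EPS[q2]
    return (e1 * e2 / 3) / (1 - e1 - e2 + 4 * e1 * e2 / 3)


def posterior_disagree_eps(q_hi: int, q_lo: int) -> float:
    e_hi, e_lo = _EPS[q_hi], _EPS[q_lo]
    z = (1 - e_hi) * (e_lo / 3) + (e_hi / 3) * (1 - e_lo) + 2 * (e_hi / 3) * (e_lo / 3)
    return 1 - (1 - e_hi) * (e_lo / 3) / z


def _eps_to_q(eps: float) -> int:
    if eps <= 0:
        return MAX_QUALITY
    q = round(-10 * math.log10(eps))
    return max(MIN_POSTERIOR_Q, min(MAX_QUALITY, q))


@dataclass
class AssembledRead:
    id: str
    residues: str
    qualities: list[int]
    offset: int          # start of the rc-reverse read relative to the forward read
    overlap_len: int
    layout: str          # 'normal' or 'read_through'
    score: float         # log-likelihood of the chosen overlap

    def to_sequence(self) -> Sequence:
        return Sequence(self.id, self.residues, qualities=list(self.qualities))

    @property
    def read_q(self) -> float:
        return read_q(self.qualities)


@dataclass
class Rejection:
    id: str
    reason: str


def read_q(qualities) -> float:
    """Q score of the mean per-base error probability of a whole read."""
    q = np.asarray(qualities, dtype=np.float64)
    if q.size == 0:
        raise AssemblyError("read_q of an empty read")
    return float(-10 * np.log10(np.power(10.0, -q / 10.0).mean()))


def score_overlap(fwd: Sequence, rc_rev: Sequence, offset: int) -> float:
    """Log-likelihood of the overlap when the rc-reverse read starts at
    ``offset`` relative to the forward read (may be negative)."""
    ov = _overlap_bounds(len(fwd), len(rc_rev), offset)
    if ov is None:
        raise AssemblyError(f"offset {offset} yields an empty overlap")
    lo, hi = ov
    f = _encode(fwd.residues[lo:hi])
    r = _encode(rc_rev.residues[lo - offset:hi - offset])
    qf = np.asarray(fwd.qualities[lo:hi])
    qr = np.asarray(rc_rev.qualities[lo - offset:hi - offset])
    agree = f == r
    return float(np.where(agree, _LOG_AGREE[qf, qr], _LOG_DISAGREE[qf, qr]).sum())


def _overlap_bounds(len_f: int, len_r: int, offset: int) -> tuple[int, int] | None:
    amplicon = offset + len_r
    lo, hi = max(0, offset), min(len_f, amplicon)
    return (lo, hi) if hi > lo else None


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode(), dtype=np.uint8)


def assemble(fwd: Sequence, rev: Sequence,
             min_overlap: int = DEFAULT_MIN_OVERLAP,
             min_column_score: float = DEFAULT_MIN_COLUMN_SCORE) -> AssembledRead | Rejection:
    """Assemble one read pair, or reject it with a reason.

    All offsets with at least ``min_overlap`` overlapping columns are
    scored; offsets where the rc-reverse read starts before the forward
    read (negative) or the forward read runs past the amplicon end are
    read-through layouts whose overhanging bases are trimmed.
    """
    if fwd.qualities is None or rev.qualities is None:
        raise AssemblyError("assembly requires per-base qualities on both reads")
    rid = fwd.id.removesuffix("/1")
    rc = reverse_complement(rev)
    len_f, len_r = len(fwd), len(rc)
    if min(len_f, len_r) < min_overlap:
        return Rejection(rid, "reads shorter than min overlap")

    f_codes, r_codes = _encode(fwd.residues), _encode(rc.residues)
    qf_all = np.asarray(fwd.qualities, dtype=np.intp)
    qr_all = np.asarray(rc.qualities, dtype=np.intp)

    # pairwise column scores: C[i, j] for fwd base i against rc base j;
    # offset t pairs i with j = i - t, so score(t) is the diagonal sum i-j==t
    agree = f_codes[:, None] == r_codes[None, :]
    col = np.where(agree, _LOG_AGREE[qf_all[:, None], qr_all[None, :]],
                   _LOG_DISAGREE[qf_all[:, None], qr_all[None, :]])
    diag = (np.arange(len_f)[:, None] - np.arange(len_r)[None, :]).ravel() + len_r - 1
    scores_all = np.bincount(diag, weights=col.ravel(), minlength=len_f + len_r - 1)

    offsets = np.arange(-(len_r - 1), len_f)
    amplicons = offsets + len_r
    overlaps = np.minimum(len_f, amplicons) - np.maximum(0, offsets)
    ok = overlaps >= min_overlap
    if not ok.any():
        return Rejection(rid, "no offset with sufficient overlap")
    # max score; ties: smaller overlap, then shorter amplicon
    order = np.lexsort((amplicons[ok], overlaps[ok], -scores_all[ok]))
    pick = order[0]
    offset = int(offsets[ok][pick])
    score = float(scores_all[ok][pick])
    overlap = int(overlaps[ok][pick])
    if score / overlap < min_column_score:
        return Rejection(rid, "overlap score below threshold")

    amplicon = offset + len_r
    lo, hi = max(0, offset), min(len_f, amplicon)
    residues: list[str] = []
    quals: list[int] = []
    for pos in range(amplicon):
        in_f = pos < len_f
        in_r = pos >= offset
        if in_f and in_r:
            bf, br = fwd.residues[pos], rc.residues[pos - offset]
            q1, q2 = fwd.qualities[pos], rc.qualities[pos - offset]
            if bf.upper() == br.upper():
                eps = posterior_agree_eps(q1, q2)
                residues.append(bf)
            else:
                if q1 >= q2:
                    residues.append(bf)
                    eps = posterior_disagree_eps(q1, q2)
                else:
                    residues.append(br)
                    eps = posterior_disagree_eps(q2, q1)
            quals.append(_eps_to_q(eps))
        elif in_f:
            residues.append(fwd.residues[pos])
            quals.append(fwd.qualities[pos])
        else:
            residues.append(rc.residues[pos - offset])
            quals.append(rc.qualities[pos - offset])
    layout = "normal" if offset >= 0 and amplicon >= len_f else "read_through"
    return AssembledRead(rid, "".join(residues), quals, offset, overlap, layout, score)


def assemble_pairs(pairs, min_overlap: int = DEFAULT_MIN_OVERLAP,
                   min_column_score: float = DEFAULT_MIN_COLUMN_SCORE,
                   min_read_q: float | None = None):
    """Assemble many (fwd, rev) pairs; returns (assembled, rejections).

    With ``min_read_q`` set, assembled reads below the read-Q cutoff are
    rejected with reason ``low read Q``.
    """
    assembled: list[AssembledRead] = []
    rejected: list[Rejection] = []
    for fwd, rev in pairs:
        result = assemble(fwd, rev, min_overlap, min_column_score)
        if isinstance(result, Rejection):
            rejected.append(result)
        elif min_read_q is not None and result.read_q < min_read_q:
            rejected.append(Rejection(result.id, "low read Q"))
        else:
            assembled.append(result)
    return assembled, rejected
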