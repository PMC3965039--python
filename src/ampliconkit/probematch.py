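"""Approximate primer/probe matching with the Myers bit-vector algorithm.

The primer (pattern, <= 64 IUPAC symbols so it fits one machine word)
is matched semi-globally against a target: the whole primer versus any
target substring, under unit-cost Levenshtein distance.  Degenerate
positions match when the IUPAC expansions of primer and target symbols
intersect; a target ``N`` matches every primer position.  A forward /
reverse primer pair searched in tandem yields in-silico PCR amplicons.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .seqio import IUPAC_EXPANSION, Sequence, reverse_complement_pattern

MAX_PRIMER_LEN = 64

#: 4-bit base sets per IUPAC code (A=1, C=2, G=4, T=8)
_BITS = {code: sum(1 << "ACGT".index(b) for b in bases)
         for code, bases in IUPAC_EXPANSION.items()}


class ProbeMatchError(ValueError):
    pass


@dataclass(frozen=True)
class Primer:
    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.pattern) <= MAX_PRIMER_LEN:
            raise ProbeMatchError(
                f"primer {self.name!r}: length must be in [1, {MAX_PRIMER_LEN}]")
        for ch in self.pattern.upper():
            if ch not in _BITS:
                raise ProbeMatchError(f"primer {self.name!r}: invalid symbol {ch!r}")


@dataclass(frozen=True)
class ProbeHit:
    seq_id: str
    primer_name: str
    strand: str          # '+' or '-'
    start: int           # 1-based inclusive, plus-strand coordinates
    end: int             # 1-based inclusive
    distance: int
    span: str            # matched target substring (plus strand)


def compile_primer(primer: Primer) -> dict[str, int]:
    """Per-target-base bit masks: bit i of mask[b] is set iff target base
    b is compatible with primer position i."""
    pat = primer.pattern.upper()
    masks: dict[str, int] = {}
    for code, tbits in _BITS.items():
        m = 0
        for i, pch in enumerate(pat):
            if _BITS[pch] & tbits:
                m |= 1 << i
        masks[code] = m
    return masks


def _myers_distances(masks: dict[str, int], m: int, target: str) -> list[int]:
    """Edit distance of the full pattern vs the target substring ending at
    each position (free start), one value per target base."""
    word = (1 << m) - 1
    Pv, Mv = word, 0
    score = m
    hi = 1 << (m - 1)
    out = []
    for ch in target:
        Eq = masks.get(ch, 0)  # unknown symbol matches nothing
        Xv = Eq | Mv
        Xh = (((Eq & Pv) + Pv) ^ Pv) | Eq
        Ph = Mv | (~(Xh | Pv) & word)
        Mh = Pv & Xh
        if Ph & hi:
            score += 1
        elif Mh & hi:
            score -= 1
        Ph = (Ph << 1) & word
        Mh = (Mh << 1) & word
        Pv = Mh | (~(Xv | Ph) & word)
        Mv = Ph & Xv
        out.append(score)
    return out


def _span_start(primer: Primer, target: str, end0: int, dist: int) -> int:
    """0-based start of the best span ending at ``end0`` (inclusive),
    found by a small reverse DP restricted to the feasible window."""
    pat = primer.pattern.upper()
    m = len(pat)
    lo = max(0, end0 + 1 - m - dist)
    window = target[lo:end0 + 1][::-1]
    rpat = pat[::-1]
    # DP of reversed pattern vs reversed window, free end in window
    prev = list(range(m + 1))
    best_len, best_d = 0, m  # empty span: all-deletion alignment
    for j, tch in enumerate(window, start=1):
        tbits = _BITS.get(tch.upper(), 0)
        cur = [j] + [0] * m
        for i in range(1, m + 1):
            sub = prev[i - 1] + (0 if _BITS[rpat[i - 1]] & tbits else 1)
            cur[i] = min(sub, prev[i] + 1, cur[i - 1] + 1)
        prev = cur
        # prefer the longest span among equal distances (leftmost start)
        if cur[m] <= best_d:
            best_d, best_len = cur[m], j
    return end0 + 1 - best_len


def search(primer: Primer, target: Sequence, maxdist: int = 0,
           strands: str = "both") -> list[ProbeHit]:
    """Semi-global search of ``primer`` in ``target`` within ``maxdist``
    edits; runs of adjacent qualifying end positions are reduced to their
    local minimum (first-best position in each run).

    Minus-strand sites are found by matching the reverse complement of
    the primer on the plus strand; coordinates stay plus-strand, 1-based.
    """
    if maxdist < 0:
        raise ProbeMatchError("maxdist must be >= 0")
    text = target.residues.upper()
    if not text:
        return []
    hits: list[ProbeHit] = []
    todo = []
    if strands in ("both", "+"):
        todo.append(("+", primer.pattern))
    if strands in ("both", "-"):
        todo.append(("-", reverse_complement_pattern(primer.pattern)))
    for strand, pattern in todo:
        p = Primer(primer.name, pattern)
        masks = compile_primer(p)
        dists = _myers_distances(masks, len(pattern), text)
        j = 0
        n = len(dists)
        while j < n:
            if dists[j] > maxdist:
                j += 1
                continue
            # run of adjacent qualifying positions -> keep first minimum
            k = j
            best = j
            while k < n and dists[k] <= maxdist:
                if dists[k] < dists[best]:
                    best = k
                k += 1
            d = dists[best]
            start0 = _span_start(p, text, best, d)
            hits.append(ProbeHit(target.id, primer.name, strand,
                                 start0 + 1, best + 1, d,
                                 text[start0:best + 1]))
            j = k
    hits.sort(key=lambda h: (h.end, h.strand))
    return hits


def best_primer_hit(primers: Iterable[Primer], seq: Sequence,
                    maxdist: int = 0) -> ProbeHit | None:
    """Minimal-distance hit across primers and strands; ties broken by
    primer input order, then smaller end position.  ``None`` = no match."""
    primers = list(primers)
    if not primers:
        raise ProbeMatchError("at least one primer required")
    best: tuple[int, int, int] | None = None
    best_hit: ProbeHit | None = None
    for idx, primer in enumerate(primers):
        for hit in search(primer, seq, maxdist):
            key = (hit.distance, idx, hit.end)
            if best is None or key < best:
                best, best_hit = key, hit
    return best_hit


@dataclass(frozen=True)
class Amplicon:
    start: int   # 1-based inclusive, outer end of the 5' primer
    end: int     # 1-based inclusive, outer end of the 3' primer
    strand: str  # '+': fwd on plus / rev on minus; '-': swapped
    fwd_hit: ProbeHit
    rev_hit: ProbeHit


def in_silico_pcr(fwd: Primer, rev: Primer, target: Sequence,
                  maxdist: int = 0) -> list[Amplicon]:
    """All amplicons where the forward primer matches one strand and the
    reverse primer matches the other strand downstream of it.  Nested and
    overlapping candidate pairs are all reported."""
    fwd_plus = search(fwd, target, maxdist, strands="+")
    fwd_minus = search(fwd, target, maxdist, strands="-")
    rev_plus = search(rev, target, maxdist, strands="+")
    rev_minus = search(rev, target, maxdist, strands="-")
    out = []
    for f in fwd_plus:
        for r in rev_minus:
            if r.start > f.end:
                out.append(Amplicon(f.start, r.end, "+", f, r))
    for r in rev_plus:
        for f in fwd_minus:
            if f.start > r.end:
                out.append(Amplicon(r.start, f.end, "-", f, r))
    out.sort(key=lambda a: (a.start, a.end, a.strand))
    return out
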