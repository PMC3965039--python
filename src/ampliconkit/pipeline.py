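"""Initial processing of raw amplicon runs: demultiplex by sample tag,
trim tags and primers, quality-filter, and report per-filter statistics.

Paired-end input is assembled first (see :mod:`ampliconkit.assembler`),
then reads are sorted by the sample tag anchored at the read start,
tag and primer regions are trimmed, and reads failing the length /
ambiguous-base / read-Q filters are removed.  Filters are applied in a
fixed order (length, Ns, read Q) so every removed read has exactly one
recorded reason, and the report balances: every input read lands in
exactly one outcome bin.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence as _Seq

from .assembler import (DEFAULT_MIN_COLUMN_SCORE, DEFAULT_MIN_OVERLAP,
                        Rejection, assemble, read_q)
from .probematch import Primer, search as probe_search
from .seqio import IUPAC_EXPANSION, Sequence, read_sequences, reverse_complement_pattern

DEFAULT_MIN_LENGTH = 50
DEFAULT_MAX_NS = 0
DEFAULT_MIN_READ_Q = 20.0
DEFAULT_PAIRED_MIN_READ_Q = 27.0
DEFAULT_TAG_EDITS = 0
DEFAULT_PRIMER_EDITS = 2


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class SampleRow:
    sample: str
    tag: str
    fwd_primer: str | None = None
    rev_primer: str | None = None


class SampleSheet:
    """Rows of (sample, tag, forward primer, reverse primer)."""

    def __init__(self, rows: Iterable[SampleRow]):
        self.rows = list(rows)
        tags = [r.tag.upper() for r in self.rows]
        if len(set(tags)) != len(tags):
            raise PipelineError("duplicate tags in sample sheet")
        for r in self.rows:
            for label, pat in (("tag", r.tag), ("fwd_primer", r.fwd_primer),
                               ("rev_primer", r.rev_primer)):
                if pat:
                    for ch in pat.upper():
                        if ch not in IUPAC_EXPANSION:
                            raise PipelineError(
                                f"sample {r.sample}: invalid {label} symbol {ch!r}")

    @classmethod
    def from_tsv(cls, source) -> "SampleSheet":
        rows = []
        if hasattr(source, "read"):
            lines = source.read().splitlines()
        else:
            with open(source) as fh:
                lines = fh.read().splitlines()
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise PipelineError("sample sheet rows need at least sample and tag")
            fields += [None] * (4 - len(fields))
            rows.append(SampleRow(fields[0], fields[1], fields[2] or None,
                                  fields[3] or None))
        return cls(rows)


def _anchored_tag_distance(tag: str, read: str, max_edits: int) -> tuple[int, int]:
    """(min edit distance, matched prefix length) of an IUPAC tag against
    read prefixes; the tag is anchored at position 0."""
    m = len(tag)
    limit = min(len(read), m + max_edits)
    prev = list(range(m + 1))
    best_d, best_j = prev[m], 0
    tag_bits = [IUPAC_EXPANSION[ch] for ch in tag.upper()]
    for j in range(1, limit + 1):
        rch = read[j - 1].upper()
        rset = IUPAC_EXPANSION.get(rch, frozenset())
        cur = [j] + [0] * m
        for i in range(1, m + 1):
            sub = prev[i - 1] + (0 if tag_bits[i - 1] & rset else 1)
            cur[i] = min(sub, prev[i] + 1, cur[i - 1] + 1)
        prev = cur
        if cur[m] < best_d:
            best_d, best_j = cur[m], j
    return best_d, best_j


def demultiplex(reads: Iterable[Sequence], sheet: SampleSheet,
                max_tag_edits: int = DEFAULT_TAG_EDITS
                ) -> tuple[dict[str, list[Sequence]], list[Sequence]]:
    """Assign each read to the unique best tag within the edit budget and
    trim the tag; ambiguous or unmatched reads go to the unmatched bin."""
    by_sample: dict[str, list[Sequence]] = {r.sample: [] for r in sheet.rows}
    unmatched: list[Sequence] = []
    for read in reads:
        scored = []
        for row in sheet.rows:
            d, j = _anchored_tag_distance(row.tag, read.residues, max_tag_edits)
            if d <= max_tag_edits:
                scored.append((d, row.sample, j))
        if not scored:
            unmatched.append(read)
            continue
        scored.sort()
        if len(scored) > 1 and scored[0][0] == scored[1][0]:
            unmatched.append(read)  # two tags at equal distance
            continue
        _, sample, j = scored[0]
        quals = read.qualities[j:] if read.qualities is not None else None
        by_sample[sample].append(
            Sequence(read.id, read.residues[j:], read.description, quals))
    return by_sample, unmatched


def trim_primers(read: Sequence, fwd_primer: str,
                 max_edits: int = DEFAULT_PRIMER_EDITS) -> Sequence | None:
    """Locate the forward primer at the 5' end (within the first
    len(primer)+max_edits bases) and cut through its end; ``None`` when
    no qualifying site exists."""
    primer = Primer("fwd", fwd_primer)
    window = len(fwd_primer) + max_edits
    head = Sequence(read.id, read.residues[:window])
    hits = [h for h in probe_search(primer, head, max_edits, strands="+")]
    if not hits:
        return None
    end = min(h.end for h in hits if h.distance == min(x.distance for x in hits))
    quals = read.qualities[end:] if read.qualities is not None else None
    return Sequence(read.id, read.residues[end:], read.description, quals)


def trim_reverse_primer(read: Sequence, rev_primer: str,
                        max_edits: int = DEFAULT_PRIMER_EDITS) -> Sequence:
    """Optional 3'-end trim: search revcomp(rev primer) near the read end
    and cut from the matched span start; unchanged when absent."""
    rc = reverse_complement_pattern(rev_primer)
    window = len(rev_primer) + max_edits
    offset = max(0, len(read.residues) - window)
    tail = Sequence(read.id, read.residues[offset:])
    hits = probe_search(Primer("rev_rc", rc), tail, max_edits, strands="+")
    if not hits:
        return read
    best = min(hits, key=lambda h: (h.distance, -h.start))
    cut = offset + best.start - 1
    quals = read.qualities[:cut] if read.qualities is not None else None
    return Sequence(read.id, read.residues[:cut], read.description, quals)


PASS = "passed"
TOO_SHORT = "too short"
TOO_MANY_NS = "ambiguous bases"
LOW_READ_Q = "low read Q"


def quality_filter(read: Sequence, min_length: int = DEFAULT_MIN_LENGTH,
                   max_ns: int = DEFAULT_MAX_NS,
                   min_read_q: float | None = DEFAULT_MIN_READ_Q
                   ) -> tuple[bool, str]:
    """Apply the filters in order (length, Ns, read Q); the first failing
    rule is the recorded reason."""
    if len(read.residues) < min_length:
        return False, TOO_SHORT
    n_count = sum(1 for ch in read.residues.upper() if ch not in "ACGT")
    if n_count > max_ns:
        return False, TOO_MANY_NS
    if min_read_q is not None:
        if read.qualities is None:
            raise PipelineError(
                f"read {read.id!r}: read-Q filter requires qualities")
        if read_q(read.qualities) < min_read_q:
            return False, LOW_READ_Q
    return True, PASS


@dataclass
class FilterReport:
    """Per-filter removal counts and the passed-length histogram.

    ``input_total == assembly_failed + tag_unmatched + sum(per-sample
    assigned)`` and per sample ``assigned == passed + removals``.
    """

    input_total: int = 0
    assembly_failed: int = 0
    tag_unmatched: int = 0
    per_sample: dict[str, Counter] = field(default_factory=dict)
    length_histogram: dict[str, Counter] = field(default_factory=dict)

    def sample_counter(self, sample: str) -> Counter:
        return self.per_sample.setdefault(sample, Counter())

    def balances(self) -> bool:
        assigned = sum(c["assigned"] for c in self.per_sample.values())
        if self.input_total != self.assembly_failed + self.tag_unmatched + assigned:
            return False
        for c in self.per_sample.values():
            removed = (c[TOO_SHORT] + c[TOO_MANY_NS] + c[LOW_READ_Q]
                       + c["primer unmatched"])
            if c["assigned"] != c[PASS] + removed:
                return False
        return True

    def to_rows(self) -> list[dict]:
        rows = []
        for sample, c in sorted(self.per_sample.items()):
            rows.append({"sample": sample, **{k: c[k] for k in
                         ("assigned", "primer unmatched", TOO_SHORT,
                          TOO_MANY_NS, LOW_READ_Q, PASS)}})
        return rows


@dataclass
class ProcessingConfig:
    sheet: SampleSheet
    paired: bool = False
    max_tag_edits: int = DEFAULT_TAG_EDITS
    max_primer_edits: int = DEFAULT_PRIMER_EDITS
    trim_fwd_primer: bool = True
    trim_rev_primer: bool = False
    min_length: int = DEFAULT_MIN_LENGTH
    max_ns: int = DEFAULT_MAX_NS
    min_read_q: float | None = None   # resolved per mode when None
    min_overlap: int = DEFAULT_MIN_OVERLAP
    min_column_score: float = DEFAULT_MIN_COLUMN_SCORE

    def resolved_min_read_q(self) -> float:
        if self.min_read_q is not None:
            return self.min_read_q
        return DEFAULT_PAIRED_MIN_READ_Q if self.paired else DEFAULT_MIN_READ_Q


def run_initial_processing(config: ProcessingConfig,
                           reads: _Seq[Sequence] | None = None,
                           pairs: _Seq[tuple[Sequence, Sequence]] | None = None
                           ) -> tuple[dict[str, list[Sequence]], FilterReport]:
    """Full initial-processing pass over an in-memory run.

    Paired mode assembles each pair first; single mode starts at
    demultiplexing.  Returns passed reads grouped by sample plus the
    filter report.
    """
    report = FilterReport()
    if config.paired:
        if pairs is None:
            raise PipelineError("paired mode requires read pairs")
        report.input_total = len(pairs)
        pool: list[Sequence] = []
        for fwd, rev in pairs:
            result = assemble(fwd, rev, config.min_overlap, config.min_column_score)
            if isinstance(result, Rejection):
                report.assembly_failed += 1
            else:
                pool.append(result.to_sequence())
    else:
        if reads is None:
            raise PipelineError("single mode requires reads")
        report.input_total = len(reads)
        pool = list(reads)

    by_sample, unmatched = demultiplex(pool, config.sheet, config.max_tag_edits)
    report.tag_unmatched = len(unmatched)

    primers = {r.sample: (r.fwd_primer, r.rev_primer) for r in config.sheet.rows}
    min_read_q = config.resolved_min_read_q()
    out: dict[str, list[Sequence]] = {}
    for sample, sample_reads in by_sample.items():
        counter = report.sample_counter(sample)
        hist = report.length_histogram.setdefault(sample, Counter())
        counter["assigned"] += len(sample_reads)
        fwd_primer, rev_primer = primers[sample]
        kept: list[Sequence] = []
        for read in sample_reads:
            if config.trim_fwd_primer and fwd_primer:
                trimmed = trim_primers(read, fwd_primer, config.max_primer_edits)
                if trimmed is None:
                    counter["primer unmatched"] += 1
                    continue
                read = trimmed
            if config.trim_rev_primer and rev_primer:
                read = trim_reverse_primer(read, rev_primer, config.max_primer_edits)
            has_quals = read.qualities is not None
            ok, reason = quality_filter(
                read, config.min_length, config.max_ns,
                min_read_q if has_quals else None)
            if ok:
                kept.append(read)
                counter[PASS] += 1
                hist[len(read.residues)] += 1
            else:
                counter[reason] += 1
        out[sample] = kept
    return out, report


def load_paired_files(fwd_path, rev_path, quality_offset: int = 33
                      ) -> list[tuple[Sequence, Sequence]]:
    """Read R1/R2 FASTQ files (optionally gzipped) into aligned pairs."""
    fwd = read_sequences(fwd_path, quality_offset=quality_offset)
    rev = read_sequences(rev_path, quality_offset=quality_offset)
    if len(fwd) != len(rev):
        raise PipelineError(
            f"paired files differ in record count: {len(fwd)} vs {len(rev)}")
    return list(zip(fwd, rev))
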