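"""Sequence I/O: FASTA/FASTQ/GenBank/EMBL reading, IUPAC alphabets,
reverse complement, id-based selection and model-column alignments.

Sequences are nucleotide strings over the IUPAC alphabet
``ACGTUMRWSYKVHDBN`` (``U`` is normalized to ``T`` on input, case
preserved).  Per-base Phred qualities, when present, are integers in
``[0, 93]``.  Aligned FASTA uses case to encode column classes:
uppercase (and ``-``) columns are model positions, lowercase (and
``.``) columns are inserts.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as _Seq

from Bio import SeqIO as _BioSeqIO

IUPAC_NUCLEOTIDES = "ACGTUMRWSYKVHDBN"

#: expansion of each IUPAC code into the set of plain bases it stands for
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "M": frozenset("AC"), "R": frozenset("AG"), "W": frozenset("AT"),
    "S": frozenset("CG"), "Y": frozenset("CT"), "K": frozenset("GT"),
    "V": frozenset("ACG"), "H": frozenset("ACT"), "D": frozenset("AGT"),
    "B": frozenset("CGT"), "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "M": "K", "R": "Y", "W": "W", "S": "S", "Y": "R", "K": "M",
    "V": "B", "H": "D", "D": "H", "B": "V", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(
    {**_COMPLEMENT, **{k.lower(): v.lower() for k, v in _COMPLEMENT.items()}}
)

_GAP_CHARS = frozenset("-.")

MAX_QUALITY = 93


class SeqIOError(ValueError):
    """Malformed sequence record or alignment."""


@dataclass
class Sequence:
    """A nucleotide sequence with optional per-base Phred qualities."""

    id: str
    residues: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise SeqIOError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize_residues(raw: str, record_label: str) -> str:
    """Validate against the IUPAC alphabet and fold U -> T (case kept)."""
    out = raw.replace("U", "T").replace("u", "t")
    for ch in set(out.upper()):
        if ch not in IUPAC_EXPANSION and ch not in _GAP_CHARS:
            raise SeqIOError(f"record {record_label}: non-IUPAC symbol {ch!r}")
    return out


def _open_text(source, mode: str = "rt"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, mode), True
    return open(path, mode), True


def _sniff_format(handle) -> str:
    pos = handle.tell()
    head = handle.read(256)
    handle.seek(pos)
    stripped = head.lstrip()
    if stripped.startswith(">"):
        return "fasta"
    if stripped.startswith("@"):
        return "fastq"
    if stripped.startswith("LOCUS"):
        return "genbank"
    if stripped.startswith("ID"):
        return "embl"
    raise SeqIOError("cannot auto-detect sequence format from file head")


def read_sequences(source, format: str = "auto", quality_offset: int = 33) -> list[Sequence]:
    """Read sequence records from ``source`` (path, ``.gz`` path or handle).

    ``format`` is one of ``auto``, ``fasta``, ``fastq``, ``genbank``,
    ``embl``.  ``quality_offset`` selects the FASTQ dialect (33 Sanger,
    64 old Illumina).  GenBank/EMBL records yield id + residues only.
    """
    handle, own = _open_text(source)
    try:
        fmt = _sniff_format(handle) if format == "auto" else format
        if fmt == "fastq":
            fmt = "fastq" if quality_offset == 33 else "fastq-illumina"
        elif fmt not in ("fasta", "genbank", "embl"):
            raise SeqIOError(f"unsupported format {fmt!r}")
        out: list[Sequence] = []
        for i, rec in enumerate(_BioSeqIO.parse(handle, fmt)):
            residues = _normalize_residues(str(rec.seq), f"#{i} ({rec.id})")
            if not residues:
                raise SeqIOError(f"record #{i} ({rec.id}): empty sequence")
            quals = rec.letter_annotations.get("phred_quality")
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            out.append(Sequence(rec.id, residues, desc,
                                list(quals) if quals is not None else None))
        return out
    finally:
        if own:
            handle.close()


def write_fasta(seqs: Iterable[Sequence], dest, width: int = 70) -> None:
    handle, own = _open_text(dest, "wt")
    try:
        for s in seqs:
            header = f">{s.id} {s.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(s.residues), width):
                handle.write(s.residues[i:i + width] + "\n")
    finally:
        if own:
            handle.close()


def write_fastq(seqs: Iterable[Sequence], dest, quality_offset: int = 33) -> None:
    handle, own = _open_text(dest, "wt")
    try:
        for s in seqs:
            if s.qualities is None:
                raise SeqIOError(f"record {s.id!r}: FASTQ output requires qualities")
            qline = "".join(chr(min(q, MAX_QUALITY) + quality_offset) for q in s.qualities)
            header = f"@{s.id} {s.description}".rstrip()
            handle.write(f"{header}\n{s.residues}\n+\n{qline}\n")
    finally:
        if own:
            handle.close()


def reverse_complement(seq: Sequence) -> Sequence:
    """IUPAC-aware reverse complement; qualities are reversed in step."""
    for ch in set(seq.residues.upper()):
        if ch not in IUPAC_EXPANSION:
            raise SeqIOError(f"record {seq.id!r}: cannot complement symbol {ch!r}")
    rc = seq.residues.translate(_COMPLEMENT_TABLE)[::-1]
    quals = seq.qualities[::-1] if seq.qualities is not None else None
    return Sequence(seq.id, rc, seq.description, quals)


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of a bare IUPAC string (primers, tags)."""
    return pattern.translate(_COMPLEMENT_TABLE)[::-1]


def select_sequences(seqs: Iterable[Sequence], ids: Iterable[str],
                     exclude: bool = False) -> tuple[list[Sequence], int]:
    """Keep (or drop, with ``exclude``) the records whose ids are listed.

    Returns the selected records in input order plus the number of
    requested ids that were not present in the source.
    """
    wanted = set(ids)
    seqs = list(seqs)
    present = {s.id for s in seqs}
    missing = len(wanted - present)
    if exclude:
        return [s for s in seqs if s.id not in wanted], missing
    return [s for s in seqs if s.id in wanted], missing


# ---------------------------------------------------------------------------
# Model-column alignments (case-encoded aligned FASTA)
# ---------------------------------------------------------------------------

MODEL, INSERT = "model", "insert"


@dataclass
class ModelAlignment:
    """Aligned records whose columns are classed model/insert by case.

    A column is a model position when it contains an uppercase base or a
    ``-`` gap; insert columns contain lowercase bases or ``.`` fill.
    Every record has the same total column count and hence the same
    model-column count.
    """

    records: list[tuple[str, str]]
    column_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            self.column_classes = []
            return
        ncol = len(self.records[0][1])
        for rid, row in self.records:
            if len(row) != ncol:
                raise SeqIOError(
                    f"alignment record {rid!r}: {len(row)} columns, expected {ncol}")
        if not self.column_classes:
            self.column_classes = [self._classify_column(c) for c in range(ncol)]

    def _classify_column(self, c: int) -> str:
        has_model = has_insert = False
        for _, row in self.records:
            ch = row[c]
            if ch.isupper() or ch == "-":
                has_model = True
            elif ch.islower() or ch == ".":
                has_insert = True
        if has_model and has_insert:
            raise SeqIOError(f"alignment column {c}: mixed model/insert characters")
        return MODEL if has_model else INSERT

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def model_columns(self) -> list[int]:
        return [i for i, cls in enumerate(self.column_classes) if cls == MODEL]

    def model_row(self, idx: int) -> str:
        _, row = self.records[idx]
        return "".join(row[c] for c in self.model_columns)


def read_alignment(source) -> ModelAlignment:
    seqs = _read_aligned_fasta(source)
    return ModelAlignment(records=seqs)


def _read_aligned_fasta(source) -> list[tuple[str, str]]:
    handle, own = _open_text(source)
    try:
        recs: list[tuple[str, str]] = []
        rid, chunks = None, []
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    recs.append((rid, "".join(chunks)))
                rid = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
        if rid is not None:
            recs.append((rid, "".join(chunks)))
        return recs
    finally:
        if own:
            handle.close()


def write_alignment(aln: ModelAlignment, dest) -> None:
    handle, own = _open_text(dest, "wt")
    try:
        for rid, row in aln.records:
            handle.write(f">{rid}\n{row}\n")
    finally:
        if own:
            handle.close()


def degap(aligned: str) -> str:
    """Unaligned residues of one alignment row (gaps and fill removed)."""
    return "".join(ch for ch in aligned if ch not in _GAP_CHARS)


def _insert_slots(aln: ModelAlignment) -> tuple[list[int], list[list[str]]]:
    """Split rows into K+1 insert slots around K model columns.

    Returns (slot widths, per-record slot strings).  Slot ``i`` is the
    run of insert columns before model column ``i`` (slot K trails the
    last model column).
    """
    model_cols = aln.model_columns
    bounds = [-1] + model_cols + [aln.n_columns]
    widths = [bounds[i + 1] - bounds[i] - 1 for i in range(len(bounds) - 1)]
    per_record = []
    for _, row in aln.records:
        slots = [row[bounds[i] + 1:bounds[i + 1]] for i in range(len(bounds) - 1)]
        per_record.append(slots)
    return widths, per_record


def merge_alignments(a: ModelAlignment, b: ModelAlignment) -> ModelAlignment:
    """Merge two alignments sharing a model: pad insert slots to the max
    width observed in either input ('.'-filled on the right), keep model
    columns aligned, concatenate record lists (``a`` first)."""
    if not a.records:
        return ModelAlignment(records=list(b.records))
    if not b.records:
        return ModelAlignment(records=list(a.records))
    ka, kb = len(a.model_columns), len(b.model_columns)
    if ka != kb:
        raise SeqIOError(f"model-column counts differ: {ka} vs {kb}")
    widths_a, slots_a = _insert_slots(a)
    widths_b, slots_b = _insert_slots(b)
    widths = [max(wa, wb) for wa, wb in zip(widths_a, widths_b)]

    def rebuild(aln: ModelAlignment, slots_all: list[list[str]]) -> list[tuple[str, str]]:
        model_cols = aln.model_columns
        out = []
        for (rid, row), slots in zip(aln.records, slots_all):
            parts = []
            for k, slot in enumerate(slots):
                parts.append(slot + "." * (widths[k] - len(slot)))
                if k < len(model_cols):
                    parts.append(row[model_cols[k]])
            out.append((rid, "".join(parts)))
        return out

    return ModelAlignment(records=rebuild(a, slots_a) + rebuild(b, slots_b))
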