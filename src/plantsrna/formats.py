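"""Readers and writers for every external representation the pipeline touches.

Sequences are held internally in RNA alphabet (U, uppercase); DNA input is
converted on read and converted back on write only when the source file was
DNA.  Coordinates are 0-based half-open internally and 1-based inclusive in
every report and GFF3 file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

log = logging.getLogger("plantsrna")

_VALID = set("ACGUN")
_STRANDS = {"+", "-"}

COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement in the internal RNA alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class TranscriptSet:
    """Ordered id -> sequence map in the internal RNA alphabet.

    ``dna_input`` records whether the source file used T, so a FASTA
    round-trip reproduces the original alphabet.
    """

    entries: dict[str, str] = field(default_factory=dict)
    dna_input: bool = False

    def __post_init__(self) -> None:
        for tid, seq in self.entries.items():
            self._check(tid, seq)

    @staticmethod
    def _check(tid: str, seq: str) -> None:
        if not seq:
            raise ValueError(f"empty sequence for transcript {tid!r}")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"transcript {tid!r} has characters outside ACGUN: {sorted(bad)}"
            )

    def add(self, tid: str, seq: str) -> None:
        if tid in self.entries:
            raise ValueError(f"duplicate transcript id {tid!r}")
        seq = to_rna(seq)
        self._check(tid, seq)
        self.entries[tid] = seq

    def __getitem__(self, tid: str) -> str:
        return self.entries[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def items(self):
        return self.entries.items()


def read_fasta(path: str | Path) -> TranscriptSet:
    """Read a FASTA file into a :class:`TranscriptSet`.

    The record id is everything up to the first whitespace in the header.
    Duplicate ids and empty sequences are hard errors.
    """
    ts = TranscriptSet()
    saw_t = False
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            tid = header.split()[0] if header.split() else header
            if not tid:
                raise ValueError(f"{path}: record with empty id")
            up = seq.upper()
            if "T" in up:
                saw_t = True
            ts.add(tid, up)
    ts.dna_input = saw_t
    return ts


def write_fasta(ts: TranscriptSet, path: str | Path, width: int = 70) -> None:
    """Write a TranscriptSet; alphabet follows ``ts.dna_input``."""
    with open(path, "w") as fh:
        for tid, seq in ts.items():
            out = to_dna(seq) if ts.dna_input else seq
            fh.write(f">{tid}\n")
            for i in range(0, len(out), width):
                fh.write(out[i:i + width] + "\n")


def _parse_count_suffix(header: str) -> int | None:
    """Count from a collapsed-FASTA header: trailing ``_<n>`` or ``x<n>``."""
    name = header.split()[0]
    for sep in ("_", "x"):
        idx = name.rfind(sep)
        if idx != -1 and name[idx + 1:].isdigit():
            return int(name[idx + 1:])
    return None


def read_tag_library(path: str | Path, format: str = "tsv",
                     sample_id: str | None = None):
    """Read a collapsed small-RNA tag library.

    ``format="fasta_count"`` expects headers ending in ``_<count>`` or
    ``x<count>``; ``format="tsv"`` expects ``sequence<TAB>count`` lines.
    Counts must be positive integers.
    """
    from .processing import TagLibrary  # local import avoids a cycle

    tags: dict[str, int] = {}
    if format == "fasta_count":
        with open(path) as fh:
            for lineno, (header, seq) in enumerate(SimpleFastaParser(fh), 1):
                count = _parse_count_suffix(header)
                if count is None or count <= 0:
                    raise ValueError(
                        f"{path} record {lineno}: header {header!r} lacks a "
                        "positive integer count suffix"
                    )
                tags[to_rna(seq)] = tags.get(to_rna(seq), 0) + count
    elif format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns")
                seq, raw = parts
                try:
                    count = int(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {raw!r}"
                    ) from None
                if count <= 0:
                    raise ValueError(f"{path}:{lineno}: count must be > 0")
                seq = to_rna(seq)
                tags[seq] = tags.get(seq, 0) + count
    else:
        raise ValueError(f"unknown tag-library format {format!r}")

    sid = sample_id or Path(path).stem
    return TagLibrary(sample_id=sid, tags=tags)


def write_tag_library(lib, path: str | Path, format: str = "tsv") -> None:
    with open(path, "w") as fh:
        if format == "tsv":
            for seq, count in lib.tags.items():
                fh.write(f"{seq}\t{count}\n")
        elif format == "fasta_count":
            for i, (seq, count) in enumerate(lib.tags.items(), 1):
                fh.write(f">t{i}_{count}\n{seq}\n")
        else:
            raise ValueError(f"unknown tag-library format {format!r}")


_LOCUS_TYPES = {"pre_miRNA", "TAS3", "phasiRNA_locus", "target_site"}


@dataclass
class Locus:
    """An annotated interval on a transcript (0-based half-open)."""

    transcript_id: str
    start: int
    end: int
    strand: str = "+"
    type: str = "phasiRNA_locus"
    attributes: dict = field(default_factory=dict)
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus start {self.start} > end {self.end} on "
                f"{self.transcript_id}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if self.type not in _LOCUS_TYPES:
            raise ValueError(f"unknown locus type {self.type!r}")


def _fmt_attr(value) -> str:
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_gff3(loci: Iterable[Locus], path: str | Path,
               source: str = "plantsrna") -> None:
    """Write loci as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, loc in enumerate(loci, 1):
            attrs = {"ID": loc.attributes.get("ID", f"{loc.type}_{i}")}
            attrs.update({k: v for k, v in loc.attributes.items() if k != "ID"})
            attr_str = ";".join(f"{k}={_fmt_attr(v)}" for k, v in attrs.items())
            score = format(loc.score, "g") if loc.score is not None else "."
            fh.write("\t".join([
                loc.transcript_id, source, loc.type,
                str(loc.start + 1), str(loc.end), score, loc.strand, ".",
                attr_str,
            ]) + "\n")
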