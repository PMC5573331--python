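"""Small-RNA read collapsing, blocklist filtering, and RPTM normalization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .formats import TranscriptSet, revcomp, to_rna

log = logging.getLogger("plantsrna")

LENGTH_MIN = 16
LENGTH_MAX = 30


@dataclass
class TagLibrary:
    """Collapsed unique small-RNA tags with raw counts for one sample.

    ``library_size`` is frozen at the total qualified reads of the library
    *before* any annotation filtering, because it normalizes sequencing depth
    (reads per ten million); removing rRNA/tRNA tags afterwards does not
    change how deep the library was sequenced.
    """

    sample_id: str
    tags: dict[str, int] = field(default_factory=dict)
    library_size: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        for seq, count in self.tags.items():
            if count <= 0:
                raise ValueError(f"tag {seq!r} has non-positive count {count}")
        if self.library_size == 0:
            self.library_size = sum(self.tags.values())

    def total_reads(self) -> int:
        return sum(self.tags.values())


def collapse_reads(reads: Iterable[str], sample_id: str = "sample") -> TagLibrary:
    """Collapse raw reads to unique tags with counts.

    The sum of tag counts equals the number of input reads; an empty input
    yields an empty (size-0) library.
    """
    tags: dict[str, int] = {}
    n = 0
    for read in reads:
        seq = to_rna(read)
        tags[seq] = tags.get(seq, 0) + 1
        n += 1
    lib = TagLibrary(sample_id=sample_id, tags=tags, library_size=n)
    log.info("collapse %s: %d reads -> %d unique tags", sample_id, n, len(tags))
    return lib


def length_filter(lib: TagLibrary, min_len: int = LENGTH_MIN,
                  max_len: int = LENGTH_MAX) -> TagLibrary:
    """Keep tags within the small-RNA size range (default 16-30 nt)."""
    kept = {s: c for s, c in lib.tags.items() if min_len <= len(s) <= max_len}
    log.info("length filter %s: %d -> %d tags", lib.sample_id,
             len(lib.tags), len(kept))
    return TagLibrary(sample_id=lib.sample_id, tags=kept,
                      library_size=lib.library_size)


def filter_blocklist(lib: TagLibrary,
                     blocklists: Iterable[TranscriptSet]) -> TagLibrary:
    """Remove tags contained verbatim in any blocklist sequence (either strand).

    Matching is exact full-tag containment; ``library_size`` is left
    untouched so RPTM normalization still reflects sequencing depth.
    """
    haystacks: list[str] = []
    for bl in blocklists:
        for _, seq in bl.items():
            haystacks.append(seq)
            haystacks.append(revcomp(seq))
    if not haystacks:
        return TagLibrary(sample_id=lib.sample_id, tags=dict(lib.tags),
                          library_size=lib.library_size)
    joined = "\n".join(haystacks)  # \n never matches a tag character
    kept = {s: c for s, c in lib.tags.items() if s not in joined}
    log.info("blocklist filter %s: %d -> %d tags", lib.sample_id,
             len(lib.tags), len(kept))
    return TagLibrary(sample_id=lib.sample_id, tags=kept,
                      library_size=lib.library_size)


def length_histogram(lib: TagLibrary) -> dict[int, tuple[int, int]]:
    """Map tag length -> (total reads, unique tags)."""
    out: dict[int, tuple[int, int]] = {}
    for seq, count in lib.tags.items():
        reads, uniq = out.get(len(seq), (0, 0))
        out[len(seq)] = (reads + count, uniq + 1)
    return dict(sorted(out.items()))


def normalize_rptm(raw, library_size: int):
    """Reads per ten million: raw * 1e7 / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive for RPTM")
    return raw * 1e7 / library_size


def expression_matrix(libraries: Iterable[TagLibrary],
                      features: Mapping[str, str]) -> pd.DataFrame:
    """RPTM expression matrix (feature id x sample) for named sequences.

    ``features`` maps feature id (e.g. a mature miRNA name) to its tag
    sequence; counts are looked up per library and RPTM-normalized with each
    library's own size.
    """
    cols = {}
    for lib in libraries:
        if lib.library_size <= 0:
            raise ValueError(f"library {lib.sample_id} has zero size")
        cols[lib.sample_id] = {
            fid: normalize_rptm(lib.tags.get(seq, 0), lib.library_size)
            for fid, seq in features.items()
        }
    return pd.DataFrame(cols)
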