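"""Conserved and novel miRNA discovery on a transcript database.

The discovery chain mirrors homology-based plant miRNA annotation:

1. ungapped homolog search of known mature miRNAs (substitutions only,
   small mismatch budget, both strands);
2. extraction of a candidate precursor window (mature hit plus 150-nt
   flanks);
3. secondary-structure prediction (:mod:`plantsrna.folding`);
4. a hairpin filter (paired nucleotides within the mature region, folding
   energy threshold);
5. a MIRcheck-style duplex audit of the mature region (mismatches, bulged /
   asymmetrically unpaired nucleotides, longest mismatch run);
6. novel calls that strictly require a detected miRNA* with a Dicer-like
   ~2-nt 3' overhang duplex geometry;
7. an isomiR merge rule: mature sequences differing by at most two terminal
   nucleotides collapse to one family member unless distinct precursors are
   recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .folding import fold, partner_map
from .formats import TranscriptSet, revcomp
from .processing import TagLibrary

log = logging.getLogger("plantsrna")

_ORD = np.frombuffer(b"ACGUN", dtype=np.uint8)


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass
class HomologHit:
    mirna_id: str
    transcript_id: str
    start: int              # 0-based half-open span on the transcript
    end: int
    strand: str
    mismatches: int


def find_homolog_loci(known: TranscriptSet, transcripts: TranscriptSet,
                      max_mm: int = 2) -> list[HomologHit]:
    """All ungapped alignments of known matures with <= max_mm substitutions.

    Both strands of every transcript are searched; ``N`` never matches.
    """
    hits: list[HomologHit] = []
    for tid, tseq in transcripts.items():
        t = _enc(tseq)
        for mid, mseq in known.items():
            L = len(mseq)
            if L > len(tseq):
                continue
            win = np.lib.stride_tricks.sliding_window_view(t, L)
            for strand in ("+", "-"):
                q = _enc(mseq if strand == "+" else revcomp(mseq))
                mm = (win != q).sum(axis=1)
                # N never matches, even against N
                mm = mm + ((win == ord("N")) & (q == ord("N"))).sum(axis=1)
                for pos in np.nonzero(mm <= max_mm)[0]:
                    hits.append(HomologHit(mid, tid, int(pos), int(pos) + L,
                                           strand, int(mm[pos])))
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.mirna_id, h.strand))
    log.info("homolog search: %d hits (max_mm=%d)", len(hits), max_mm)
    return hits


def extract_flanks(transcript: str, span: tuple[int, int],
                   flank: int) -> tuple[tuple[int, int], bool, bool]:
    """Candidate window = span widened by ``flank`` nt, clipped at the ends.

    Returns the window (0-based half-open) plus left/right truncation flags.
    """
    start, end = span
    if not (0 <= start <= end <= len(transcript)):
        raise ValueError(f"span {span} outside transcript of length "
                         f"{len(transcript)}")
    wstart = max(0, start - flank)
    wend = min(len(transcript), end + flank)
    return (wstart, wend), wstart > start - flank, wend < end + flank


@dataclass
class HairpinCandidate:
    """A candidate pre-miRNA window with its fold and filter verdicts.

    ``mature_span`` and ``star_span`` are 0-based half-open intervals in
    candidate-local coordinates.
    """

    transcript_id: str
    span: tuple[int, int]
    sequence: str
    structure: str = ""
    energy: float = 0.0
    mature_span: tuple[int, int] | None = None
    star_span: tuple[int, int] | None = None
    paired_in_mature: int = 0
    strand: str = "+"
    verdicts: dict = field(default_factory=dict)

    def folded(self) -> bool:
        return len(self.structure) == len(self.sequence)


def make_candidate(transcript_id: str, transcript: str,
                   hit_span: tuple[int, int], flank: int = 150,
                   strand: str = "+",
                   backend: str = "auto") -> HairpinCandidate:
    """Fold the flank-extended window around a mature hit."""
    (ws, we), _, _ = extract_flanks(transcript, hit_span, flank)
    seq = transcript[ws:we]
    if strand == "-":
        seq = revcomp(seq)
        mstart = we - hit_span[1]
    else:
        mstart = hit_span[0] - ws
    structure, energy = fold(seq, backend=backend)
    cand = HairpinCandidate(
        transcript_id=transcript_id, span=(ws, we), sequence=seq,
        structure=structure, energy=energy,
        mature_span=(mstart, mstart + (hit_span[1] - hit_span[0])),
        strand=strand,
    )
    cand.paired_in_mature = _count_paired(cand)
    return cand


def _count_paired(c: HairpinCandidate) -> int:
    partner = partner_map(c.structure)
    ms, me = c.mature_span
    return sum(1 for i in range(ms, me) if partner[i] != -1)


def hairpin_filter(c: HairpinCandidate, min_paired: int = 18,
                   max_energy: float = -40.0) -> bool:
    """Precursor filter: paired nucleotides within the mature region and a
    strict folding-energy threshold (energy must be *smaller than* the bound).
    """
    if c.mature_span is None:
        raise ValueError("mature_span unset")
    if not c.folded():
        raise ValueError("candidate not folded")
    paired_ok = c.paired_in_mature >= min_paired
    energy_ok = c.energy < max_energy
    c.verdicts["paired"] = paired_ok
    c.verdicts["energy"] = energy_ok
    c.verdicts["hairpin"] = paired_ok and energy_ok
    return c.verdicts["hairpin"]


def mircheck_filter(c: HairpinCandidate, max_mismatch: int = 6,
                    max_bulge: int = 2,
                    max_run: int = 3) -> tuple[bool, int, int, int]:
    """Audit the mature-region duplex the way MIRcheck does.

    Walking the mature region 5'->3' against its pairing partner:

    * unpaired mature positions facing an unpaired partner-side counterpart
      count as *mismatches*;
    * unpaired mature positions with no partner-side counterpart, mature
      positions paired internally (within the mature region itself) and
      positions whose partner breaks the duplex's monotone geometry count as
      *bulged / asymmetrically unpaired*;
    * the longest run of consecutive mismatches is tracked.

    Unpaired nucleotides at the extreme mature termini are exempt (Dicer
    duplexes carry 2-nt 3' overhangs).  Pass requires mismatches <= 6,
    bulged <= 2 and run <= 3.
    """
    if c.mature_span is None:
        raise ValueError("mature_span unset")
    partner = partner_map(c.structure)
    ms, me = c.mature_span

    paired = [(i, partner[i]) for i in range(ms, me)
              if partner[i] != -1 and not ms <= partner[i] < me]

    # The duplex = the longest chain of partners descending as the mature
    # ascends.  Mature positions off that chain — unpaired, paired within
    # the mature itself, or paired inconsistently with the duplex — are
    # audited against the partner-side gap: matched-size gaps are
    # mismatches, excess mature-side nucleotides are bulges.
    anchors = _longest_decreasing_chain(paired)
    mism = 0
    bulged = 0
    longest_run = 0
    for (i1, p1), (i2, p2) in zip(anchors, anchors[1:]):
        gap_m = i2 - i1 - 1
        gap_p = p1 - p2 - 1
        mism += min(gap_m, gap_p)
        bulged += max(gap_m - gap_p, 0)
        # a continuous run counts every consecutive off-duplex mature nt
        longest_run = max(longest_run, gap_m)

    if anchors:
        # mature termini outside the duplex count as mismatches (but not
        # as a continuous interior run)
        mism += (anchors[0][0] - ms) + ((me - 1) - anchors[-1][0])
    else:
        mism = me - ms                   # nothing duplexed at all
        longest_run = me - ms

    ok = mism <= max_mismatch and bulged <= max_bulge and longest_run <= max_run
    c.verdicts["mircheck"] = ok
    c.verdicts["mircheck_counts"] = (mism, bulged, longest_run)
    return ok, mism, bulged, longest_run


def _longest_decreasing_chain(
        pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest subsequence (by ascending i) with strictly decreasing
    partners — the consistent mature/star duplex within a fold."""
    n = len(pairs)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for b in range(n):
        for a in range(b):
            if pairs[a][1] > pairs[b][1] and best_len[a] + 1 > best_len[b]:
                best_len[b] = best_len[a] + 1
                prev[b] = a
    end = max(range(n), key=lambda b: (best_len[b], -b))
    chain = []
    while end != -1:
        chain.append(pairs[end])
        end = prev[end]
    return chain[::-1]


@dataclass
class MatureCall:
    """One mature miRNA call (homolog-supported or novel)."""

    name: str
    family: str
    sequence: str
    arm: str                      # "5p" | "3p"
    source: str                   # homolog_with_precursor | homolog_mature_only | novel
    precursor_id: str | None = None
    star_sequence: str | None = None
    member_key: str | None = None


def _loop_span(structure: str) -> tuple[int, int] | None:
    """Innermost hairpin loop of the dominant stem: the closing pair whose
    enclosed region is completely unpaired."""
    partner = partner_map(structure)
    best = None
    for i, p in enumerate(partner):
        if p > i and all(partner[q] == -1 for q in range(i + 1, p)):
            if best is None or (p - i) < (best[1] - best[0]):
                best = (i + 1, p)
    return best


def _map_tags(lib: TagLibrary, seq: str) -> list[tuple[int, int, str, int]]:
    """Exact tag placements on ``seq``: (start, end, tag, count)."""
    placements = []
    for tag, count in lib.tags.items():
        start = seq.find(tag)
        while start != -1:
            placements.append((start, start + len(tag), tag, count))
            start = seq.find(tag, start + 1)
    return placements


def call_novel(c: HairpinCandidate, lib: TagLibrary,
               overhang: int = 2, tolerance: int = 1,
               name: str = "novel") -> MatureCall | None:
    """Novel-miRNA call: demands reads on *both* hairpin arms whose dominant
    tags form a duplex with ~2-nt 3' overhangs (tolerance +/- 1 nt).

    The more abundant arm tag becomes the mature, the other the star.
    Returns ``None`` when the star is absent or the duplex geometry is off.
    """
    if not c.folded():
        raise ValueError("candidate not folded")
    loop = _loop_span(c.structure)
    if loop is None:
        return None
    partner = partner_map(c.structure)
    placements = _map_tags(lib, c.sequence)
    arm5 = [p for p in placements if p[1] <= loop[0]]
    arm3 = [p for p in placements if p[0] >= loop[1]]
    if not arm5 or not arm3:
        return None
    a0, a1, tag5, n5 = max(arm5, key=lambda p: (p[3], -p[0]))
    b0, b1, tag3, n3 = max(arm3, key=lambda p: (p[3], -p[0]))

    diag = [i + partner[i] for i in range(a0, a1)
            if partner[i] != -1 and b0 <= partner[i] < b1]
    if len(diag) < 5:
        return None
    cstar = int(np.median(diag))
    o5 = (a1 - 1) - (cstar - b0)
    o3 = (b1 - 1) - (cstar - a0)
    if abs(o5 - overhang) > tolerance or abs(o3 - overhang) > tolerance:
        return None

    if n5 >= n3:
        mature, star, arm = tag5, tag3, "5p"
    else:
        mature, star, arm = tag3, tag5, "3p"
    return MatureCall(
        name=name, family=name, sequence=mature, arm=arm, source="novel",
        precursor_id=f"{c.transcript_id}:{c.span[0]}-{c.span[1]}",
        star_sequence=star,
    )


def _terminal_trim_cost(a: str, b: str, max_cost: int = 2) -> int | None:
    """Minimal total terminal nucleotides trimmed from a and b so the
    remaining cores are identical and non-empty; None if > max_cost."""
    best = None
    for t5a in range(max_cost + 1):
        for t3a in range(max_cost + 1 - t5a):
            for t5b in range(max_cost + 1 - t5a - t3a):
                for t3b in range(max_cost + 1 - t5a - t3a - t5b):
                    cost = t5a + t3a + t5b + t3b
                    ca = a[t5a:len(a) - t3a or None]
                    cb = b[t5b:len(b) - t3b or None]
                    if ca and ca == cb and (best is None or cost < best):
                        best = cost
    return best


def merge_members(calls: list[MatureCall]) -> list[list[MatureCall]]:
    """Collapse isomiRs: calls within one family whose sequences differ only
    by <= 2 terminal nucleotides are one member, unless they carry distinct
    precursors (a recorded precursor pins a call to its own locus)."""
    parent = list(range(len(calls)))

    def root(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(calls)):
        for j in range(i + 1, len(calls)):
            a, b = calls[i], calls[j]
            if a.family != b.family:
                continue
            if (a.precursor_id and b.precursor_id
                    and a.precursor_id != b.precursor_id):
                continue
            if _terminal_trim_cost(a.sequence, b.sequence) is not None:
                parent[root(i)] = root(j)

    groups: dict[int, list[MatureCall]] = {}
    for i, call in enumerate(calls):
        groups.setdefault(root(i), []).append(call)
    members = list(groups.values())
    for k, group in enumerate(members):
        for call in group:
            call.member_key = f"{group[0].family}.m{k + 1}"
    return members


def member_counts(members: list[list[MatureCall]]) -> dict[str, int]:
    """Members per family after the isomiR merge."""
    counts: dict[str, int] = {}
    for group in members:
        fam = group[0].family
        counts[fam] = counts.get(fam, 0) + 1
    return counts
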