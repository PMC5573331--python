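"""phasiRNA detection: 21-nt register statistics over 210-nt windows.

A window spanning ``m`` phases of length 21 holds ``21*m`` possible 5'-end
positions.  With ``n`` distinct positions occupied by unique 21-nt sRNAs, of
which ``k`` fall in the register defined by the window start, the chance of
seeing ``k`` or more in-register positions under uniform placement is the
hypergeometric upper tail

    P = sum_{X=k}^{min(n,m)} C(m, X) * C(20m, n-X) / C(21m, n).

A companion phase score summarizes read support:

    score = (k - 2) * ln(1 + 10 * sum(P_i) / (1 + sum(U_i)))   for k >= 3,

with ``P_i`` the in-register (phased) read count of phase ``i`` and ``U_i``
the off-register read count; the score is 0 for ``k <= 2``.

Reads on the antisense strand are shifted +2 nt before phase assignment,
reflecting the 2-nt 3' overhang of the siRNA duplex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .config import RunConfig
from .formats import Locus

log = logging.getLogger("plantsrna")


@dataclass
class EffectiveRead:
    """A mapped 21-nt tag with its phase-effective 5' position.

    ``position`` is the leftmost transcript coordinate of the alignment;
    antisense reads get ``effective = position + 2``, sense reads
    ``effective = position``.
    """

    tag: str
    strand: str
    position: int
    count: int
    effective: int


def map_effective_positions(reads: Iterable[tuple[str, str, int, int]],
                            phase_len: int = 21) -> list[EffectiveRead]:
    """Apply the antisense +2 offset; keep only tags of the phase length.

    ``reads`` yields (tag, strand, leftmost position, count).
    """
    out: list[EffectiveRead] = []
    dropped = 0
    for tag, strand, pos, count in reads:
        if len(tag) != phase_len:
            dropped += 1
            continue
        eff = pos + 2 if strand == "-" else pos
        out.append(EffectiveRead(tag, strand, pos, count, eff))
    if dropped:
        log.info("map_effective_positions: %d non-%d-nt tags excluded",
                 dropped, phase_len)
    return out


def map_tags_to_transcripts(lib, transcripts
                            ) -> dict[str, list[tuple[str, str, int, int]]]:
    """Ungapped exact-match mapping of collapsed tags, both strands.

    Returns per-transcript (tag, strand, leftmost position, count) lists;
    a tag maps everywhere it matches exactly.
    """
    from .formats import revcomp
    out: dict[str, list[tuple[str, str, int, int]]] = {}
    for tid, seq in transcripts.items():
        hits = []
        for tag, count in lib.tags.items():
            for strand, query in (("+", tag), ("-", revcomp(tag))):
                start = seq.find(query)
                while start != -1:
                    hits.append((tag, strand, start, count))
                    start = seq.find(query, start + 1)
        if hits:
            out[tid] = sorted(hits)
    return out


def _log_choose(a: int, b: int) -> float:
    if b < 0 or b > a:
        return -math.inf
    return (math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1))


@lru_cache(maxsize=100_000)
def window_pvalue(n: int, k: int, m: int = 10) -> float:
    """Hypergeometric upper-tail probability of >= k phased positions.

    Evaluated in log space; exact to ~1e-13 relative for n up to 210.
    """
    if k < 0 or n < 0:
        raise ValueError("n and k must be non-negative")
    if k > n or k > m:
        raise ValueError(f"k={k} exceeds min(n={n}, m={m})")
    if n > 21 * m:
        raise ValueError(f"n={n} exceeds the {21 * m} positions of the window")
    if k == 0:
        return 1.0
    denom = _log_choose(21 * m, n)
    terms = []
    for x in range(k, min(n, m) + 1):
        t = _log_choose(m, x) + _log_choose(20 * m, n - x) - denom
        if t != -math.inf:
            terms.append(t)
    if not terms:
        return 0.0
    hi = max(terms)
    p = math.exp(hi) * sum(math.exp(t - hi) for t in terms)
    return min(p, 1.0)


def phase_score(P: Sequence[float], U: Sequence[float], k: int) -> float:
    """Eq.-2-style read-support score; 0 unless k >= 3 phased unique sRNAs."""
    if len(P) != len(U):
        raise ValueError("P and U must have one entry per phase")
    if any(p < 0 for p in P) or any(u < 0 for u in U):
        raise ValueError("negative read counts")
    if k < 3:
        return 0.0
    sp = float(sum(P))
    su = float(sum(U))
    return (k - 2) * math.log1p(10.0 * sp / (1.0 + su))


@dataclass
class PhaseWindow:
    """One scan window with its register statistics."""

    transcript_id: str
    window_start: int
    m: int
    n: int
    k: int
    P: list[int] = field(default_factory=list)
    U: list[int] = field(default_factory=list)
    p_value: float = 1.0
    phase_score: float = 0.0


def scan_transcript(reads: Iterable[EffectiveRead] | list[EffectiveRead],
                    transcript_id: str, transcript_len: int,
                    start_from: int = 0,
                    cfg: RunConfig | None = None) -> list[PhaseWindow]:
    """Slide a 210-nt window by 1 nt from ``start_from`` to the transcript end.

    ``n`` counts distinct occupied effective positions in the window, ``k``
    those in the register defined by the window start; ``P_i``/``U_i`` are
    raw read counts.  Transcripts shorter than one window yield an empty
    list.
    """
    cfg = cfg or RunConfig()
    W, phase, m = cfg.window_len, cfg.phase_len, cfg.n_phases
    if start_from >= transcript_len:
        raise ValueError("start_from beyond transcript end")
    last_start = transcript_len - W
    if last_start < start_from:
        log.info("scan %s: transcript shorter than one window", transcript_id)
        return []

    depth = np.zeros(transcript_len + phase, dtype=np.int64)
    occupied = np.zeros(transcript_len + phase, dtype=bool)
    for r in reads:
        if 0 <= r.effective < transcript_len:
            depth[r.effective] += r.count
            occupied[r.effective] = True

    occ_cum = np.concatenate([[0], np.cumsum(occupied)])
    depth_cum = np.concatenate([[0], np.cumsum(depth)])

    windows: list[PhaseWindow] = []
    for s in range(start_from, last_start + 1):
        n = int(occ_cum[s + W] - occ_cum[s])
        phase_pos = range(s, s + W, phase)
        k = int(sum(occupied[p] for p in phase_pos))
        P = [int(depth[p]) for p in phase_pos]
        U = [int(depth_cum[s + (i + 1) * phase] - depth_cum[s + i * phase]) - P[i]
             for i in range(m)]
        pv = window_pvalue(n, k, m)
        windows.append(PhaseWindow(
            transcript_id=transcript_id, window_start=s, m=m, n=n, k=k,
            P=P, U=U, p_value=pv, phase_score=phase_score(P, U, k),
        ))
    return windows


def call_phased_loci(windows: Iterable[PhaseWindow],
                     p_max: float = 1e-3,
                     score_min: float = 5.0) -> list[Locus]:
    """Transcripts with >= 1 window at p <= p_max and score >= score_min;
    the best window (smallest p, then largest score) represents the locus."""
    if p_max <= 0 or score_min < 0:
        raise ValueError("thresholds must be positive")
    best: dict[str, PhaseWindow] = {}
    for w in windows:
        if w.p_value <= p_max and w.phase_score >= score_min:
            cur = best.get(w.transcript_id)
            if (cur is None
                    or (w.p_value, -w.phase_score, w.window_start)
                    < (cur.p_value, -cur.phase_score, cur.window_start)):
                best[w.transcript_id] = w
    loci = []
    for tid in sorted(best):
        w = best[tid]
        loci.append(Locus(
            transcript_id=tid, start=w.window_start,
            end=w.window_start + w.m * 21, strand="+", type="phasiRNA_locus",
            score=w.phase_score,
            attributes={"p_value": w.p_value, "phase_score": w.phase_score,
                        "n": w.n, "k": w.k},
        ))
    log.info("call_phased_loci: %d loci", len(loci))
    return loci


def anchor_to_trigger(site, windows: Iterable[PhaseWindow],
                      p_max: float = 1e-3,
                      score_min: float = 5.0) -> Locus | None:
    """Tie a phased locus to a validated trigger cleavage site.

    Only windows starting at or downstream of the site's cleavage position
    are considered; the returned locus carries the trigger id and the offset
    between the cleavage position and the best window start (0 mod 21 means
    the locus sits in the trigger-defined register).
    """
    cleave = site.cleavage_pos
    eligible = [w for w in windows
                if w.window_start >= cleave
                and w.p_value <= p_max and w.phase_score >= score_min]
    if not eligible:
        return None
    w = min(eligible,
            key=lambda w: (w.p_value, -w.phase_score, w.window_start))
    offset = w.window_start - cleave
    return Locus(
        transcript_id=w.transcript_id, start=w.window_start,
        end=w.window_start + w.m * 21, strand="+", type="phasiRNA_locus",
        score=w.phase_score,
        attributes={"p_value": w.p_value, "phase_score": w.phase_score,
                    "trigger": site.small_rna_id, "offset": offset,
                    "in_register": offset % 21 == 0},
    )
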