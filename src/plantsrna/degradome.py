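"""Degradome (PARE) profiles, miRNA/tasiRNA target validation, TAS3 loci.

Target sites are scored by reverse complementarity of the small RNA against
the transcript over every ungapped offset.  G:U wobbles count half a
mismatch by default (SeqTar-style accounting; a switch restores GU = 1).
The canonical cleavage position sits opposite small-RNA positions 10-11; a
degradome read is *valid* for a site when its 5' end falls opposite
positions 9-11.

TAS3 loci are recognized by the two-hit trigger architecture: a tasiARF
homolog flanked by miR390 complementary sites on both sides, with the
tasiARF register phased (mod 21) to the 3' site's cleavage position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from .formats import TranscriptSet, read_fasta
from .mirna import find_homolog_loci
from .processing import TagLibrary

log = logging.getLogger("plantsrna")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def packaged_reference(name: str) -> TranscriptSet:
    """Load a packaged reference FASTA (``tasiarf`` or ``mir390``)."""
    path = resources.files("plantsrna").joinpath(f"data/{name}.fasta")
    with resources.as_file(path) as p:
        return read_fasta(p)


class DegradomeProfile(dict):
    """transcript_id -> per-position 5'-end read counts (numpy int array)."""


def build_profile(tags: TagLibrary | Iterable[tuple[str, int]],
                  transcripts: TranscriptSet) -> DegradomeProfile:
    """Place each degradome tag at every exact sense match; the count is
    added at the match's 5' position.  Multi-mapping tags hit every locus."""
    items = tags.tags.items() if isinstance(tags, TagLibrary) else tags
    profile = DegradomeProfile(
        (tid, np.zeros(len(seq), dtype=np.int64))
        for tid, seq in transcripts.items()
    )
    multi = 0
    for tag, count in items:
        placements = []
        for tid, seq in transcripts.items():
            start = seq.find(tag)
            while start != -1:
                placements.append((tid, start))
                start = seq.find(tag, start + 1)
        if len(placements) > 1:
            multi += 1
        for tid, pos in placements:
            profile[tid][pos] += count
    if multi:
        log.info("build_profile: %d multi-mapping tags counted at every locus",
                 multi)
    return profile


@dataclass
class TargetSite:
    """One small-RNA complementary site on a transcript."""

    small_rna_id: str
    transcript_id: str
    start: int                 # 0-based half-open span on the transcript
    end: int
    mismatches: float          # GU wobbles contribute 0.5 by default
    gu_pairs: int
    cleavage_pos: int          # 5' end of the 3' cleavage fragment
    valid_reads: int = 0
    pos10_reads: int = 0
    total_site_reads: int = 0
    category: str = "conserved"
    rule: str | None = None

    @property
    def effective_mm(self) -> int:
        return math.floor(self.mismatches)


def find_sites(small_rna: str, small_rna_id: str,
               transcript: str, transcript_id: str,
               max_mm: int = 4, gu_half: bool = True) -> list[TargetSite]:
    """Ungapped complementary sites with floor(mismatch score) <= max_mm.

    Small-RNA position ``q`` (0-based, 5'->3') pairs transcript position
    ``start + L - 1 - q``; scoring: Watson-Crick 0, G:U wobble 0.5 (or 1
    with ``gu_half=False``), anything else 1.
    """
    L = len(small_rna)
    sites: list[TargetSite] = []
    if L > len(transcript):
        return sites
    for s in range(len(transcript) - L + 1):
        mm = 0.0
        gu = 0
        for q in range(L):
            a = small_rna[q]
            b = transcript[s + L - 1 - q]
            if (a, b) in _WC:
                continue
            if (a, b) in _GU:
                gu += 1
                mm += 0.5 if gu_half else 1.0
            else:
                mm += 1.0
            if mm > max_mm:
                break
        if mm <= max_mm:
            sites.append(TargetSite(
                small_rna_id=small_rna_id, transcript_id=transcript_id,
                start=s, end=s + L, mismatches=mm, gu_pairs=gu,
                cleavage_pos=s + L - 10,
            ))
    sites.sort(key=lambda t: (t.mismatches, t.start))
    return sites


def classify_valid_reads(site: TargetSite,
                         profile: DegradomeProfile) -> int:
    """Valid reads: degradome 5' ends opposite small-RNA positions 9-11."""
    vec = profile.get(site.transcript_id)
    if vec is None:
        site.valid_reads = 0
        return 0
    L = site.end - site.start
    positions = [site.start + L - p for p in (9, 10, 11)]
    site.valid_reads = int(sum(vec[p] for p in positions
                               if 0 <= p < len(vec)))
    p10 = site.start + L - 10
    site.pos10_reads = int(vec[p10]) if 0 <= p10 < len(vec) else 0
    site.total_site_reads = int(vec[site.start:site.end].sum())
    return site.valid_reads


def validate_targets(sites: Iterable[TargetSite],
                     profiles: DegradomeProfile,
                     family_of: Mapping[str, str | None]) -> list[TargetSite]:
    """Apply the retention rules per small-RNA class.

    Conserved miRNAs (mapped to a family): sites with < 4 mismatches are
    kept outright; 4-5-mismatch sites are kept only when their family has no
    lower-mismatch site anywhere (the conserved-family fallback).  Novel
    miRNAs (family ``None``): < 4 mismatches *and* at least one valid
    degradome read.
    """
    sites = list(sites)
    for site in sites:
        classify_valid_reads(site, profiles)

    fam_best: dict[str, int] = {}
    for site in sites:
        fam = family_of.get(site.small_rna_id)
        if fam is not None:
            cur = fam_best.get(fam)
            if cur is None or site.effective_mm < cur:
                fam_best[fam] = site.effective_mm

    kept: list[TargetSite] = []
    for site in sites:
        fam = family_of.get(site.small_rna_id)
        mm = site.effective_mm
        if fam is None:
            site.category = "nonconserved"
            if mm < 4 and site.valid_reads >= 1:
                site.rule = "novel_valid"
                kept.append(site)
        else:
            site.category = "conserved"
            if mm < 4:
                site.rule = "conserved_lt4"
                kept.append(site)
            elif 4 <= mm <= 5 and fam_best.get(fam, 6) >= 4:
                site.rule = "conserved_fallback_4to5"
                kept.append(site)
    log.info("validate_targets: %d/%d sites retained", len(kept), len(sites))
    return kept


def tplot_data(profile: DegradomeProfile, transcript_id: str,
               sites: Iterable[TargetSite] = ()) -> tuple[pd.DataFrame, list[int]]:
    """Per-position degradome table (1-based, non-zero rows only) plus
    cleavage-position markers for the given sites."""
    vec = profile.get(transcript_id)
    if vec is None or not vec.any():
        return pd.DataFrame(columns=["position", "reads"]), []
    nz = np.nonzero(vec)[0]
    table = pd.DataFrame({"position": nz + 1, "reads": vec[nz]})
    markers = [s.cleavage_pos + 1 for s in sites
               if s.transcript_id == transcript_id]
    return table, markers


def plot_tplot(profile: DegradomeProfile, transcript_id: str,
               sites: Iterable[TargetSite] = (),
               path: str | None = None):
    """Render a t-plot (requires matplotlib; install the ``plot`` extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table, markers = tplot_data(profile, transcript_id, sites)
    fig, ax = plt.subplots(figsize=(7, 2.5))
    if not table.empty:
        ax.vlines(table["position"], 0, table["reads"], color="0.4")
    for m in markers:
        ax.axvline(m, color="red", lw=0.8, ls="--")
    ax.set_xlabel(f"position on {transcript_id}")
    ax.set_ylabel("degradome reads")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass
class Tas3Locus:
    """A TAS3-like transcript: tasiARF homolog flanked by two miR390 sites."""

    transcript_id: str
    five_prime_site: TargetSite
    three_prime_site: TargetSite
    tasiarf_spans: list[tuple[int, int]] = field(default_factory=list)
    register: int = 0          # (3'-site cleavage - tasiARF start) mod 21


def find_tas3(tasiarf_refs: TranscriptSet, mir390: str,
              transcripts: TranscriptSet,
              cfg: RunConfig | None = None,
              tasiarf_max_mm: int = 3,
              mir390_max_mm: int = 5) -> list[Tas3Locus]:
    """Two-hit TAS3 detection.

    A transcript qualifies when a tasiARF reference matches it (<= 3
    mismatches, sense strand) and miR390 complementary sites lie both 5' and
    3' of the matched region (each <= 5 mismatches).
    """
    loci: list[Tas3Locus] = []
    hits = find_homolog_loci(tasiarf_refs, transcripts,
                             max_mm=tasiarf_max_mm)
    by_tid: dict[str, list] = {}
    for h in hits:
        if h.strand == "+":
            by_tid.setdefault(h.transcript_id, []).append(h)
    for tid in sorted(by_tid):
        spans = sorted({(h.start, h.end) for h in by_tid[tid]})
        first, last = spans[0][0], spans[-1][1]
        sites = find_sites(mir390, "miR390", transcripts[tid], tid,
                           max_mm=mir390_max_mm)
        up = [s for s in sites if s.end <= first]
        down = [s for s in sites if s.start >= last]
        if not up or not down:
            continue
        five = min(up, key=lambda s: (s.mismatches, s.start))
        three = min(down, key=lambda s: (s.mismatches, s.start))
        register = (three.cleavage_pos - first) % 21
        loci.append(Tas3Locus(
            transcript_id=tid, five_prime_site=five, three_prime_site=three,
            tasiarf_spans=spans, register=register,
        ))
    log.info("find_tas3: %d loci", len(loci))
    return loci
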