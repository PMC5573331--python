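"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any sequencing data:
random transcripts carry planted fold-back precursors, 21-nt phased sRNA
registers downstream of trigger complementary sites, TAS3-style dual-miR390
cassettes and miRNA target sites; count libraries follow a negative
binomial with a Small/Large group effect coupled to root biomass; degradome
profiles put peaks at canonical cleavage positions over a Poisson
background; phenotype tables come from a Gaussian copula with a requested
trait correlation matrix.  A :class:`GroundTruth` records every planted
feature so discovery stages can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import TranscriptSet, revcomp

_BASES = np.array(list("ACGU"))
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

TRAITS = ["TRM", "RM", "HT", "MLL", "MLW", "TLA", "LN"]


def _default_corr() -> np.ndarray:
    """A plausible root-phenotype correlation structure: biomass traits
    (TRM, RM) tightly coupled, leaf-area traits moderately coupled to
    biomass, everything mildly positive."""
    r = np.array([
        # TRM   RM    HT    MLL   MLW   TLA   LN
        [1.00, 0.90, 0.50, 0.45, 0.40, 0.78, 0.35],
        [0.90, 1.00, 0.45, 0.40, 0.38, 0.70, 0.32],
        [0.50, 0.45, 1.00, 0.55, 0.45, 0.50, 0.30],
        [0.45, 0.40, 0.55, 1.00, 0.60, 0.70, 0.28],
        [0.40, 0.38, 0.45, 0.60, 1.00, 0.65, 0.25],
        [0.78, 0.70, 0.50, 0.70, 0.65, 1.00, 0.40],
        [0.35, 0.32, 0.30, 0.28, 0.25, 0.40, 1.00],
    ])
    return nearest_correlation(r)


def nearest_correlation(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2)
    w = np.clip(w, 1e-8, None)
    m = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


TRAIT_MEANS = {"TRM": 30.0, "RM": 20.0, "HT": 30.0, "MLL": 10.0,
               "MLW": 4.0, "TLA": 150.0, "LN": 7.0}
TRAIT_SDS = {"TRM": 12.0, "RM": 8.0, "HT": 8.0, "MLL": 2.0,
             "MLW": 1.0, "TLA": 50.0, "LN": 2.0}


@dataclass
class SimDesign:
    """Study-scale parameters of the synthetic dataset."""

    n_transcripts: int = 30
    transcript_len_range: tuple[int, int] = (600, 1200)
    n_planted_hairpins: int = 5
    n_planted_phased_loci: int = 3
    n_decoy_loci: int = 3
    n_planted_tas3: int = 1
    n_target_sites: int = 5
    phased_read_depth: int = 5         # reads per 21-nt cycle
    phased_cycles: int = 10
    offtarget_frac: float = 0.2
    antisense_frac: float = 0.25
    background_read_rate: float = 0.02  # uniform reads per nt on decoys
    n_libraries_per_group: int = 6
    group_fold_change: float = 3.0
    nb_dispersion: float = 0.05
    n_background_mirnas: int = 180
    n_diff_mirnas: int = 20
    mean_library_size: int = 5_000_000
    degradome_peak_depth: int = 24
    degradome_background: float = 0.1   # Poisson rate per position
    hairpin_loop_len: int = 12
    max_hairpin_mismatches: int = 2
    phenotype_corr: np.ndarray = field(default_factory=_default_corr)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_transcripts", "n_planted_hairpins",
                     "n_planted_phased_loci", "n_decoy_loci",
                     "n_planted_tas3", "n_target_sites",
                     "n_background_mirnas", "n_diff_mirnas"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.group_fold_change <= 0:
            raise ValueError("group_fold_change must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.offtarget_frac <= 1:
            raise ValueError("offtarget_frac must lie in [0, 1]")
        if not 0 <= self.antisense_frac <= 1:
            raise ValueError("antisense_frac must lie in [0, 1]")
        corr = np.asarray(self.phenotype_corr, dtype=float)
        if corr.shape[0] != corr.shape[1] or not np.allclose(np.diag(corr), 1):
            raise ValueError("phenotype_corr must be square with unit diagonal")
        if np.linalg.eigvalsh((corr + corr.T) / 2).min() < -1e-8:
            raise ValueError("phenotype_corr must be positive semidefinite")
        self.phenotype_corr = corr


@dataclass
class GroundTruth:
    """Every planted feature, recorded exactly once."""

    hairpins: list[dict] = field(default_factory=list)
    phased_loci: list[dict] = field(default_factory=list)
    decoy_transcripts: list[str] = field(default_factory=list)
    tas3: list[dict] = field(default_factory=list)
    target_sites: list[dict] = field(default_factory=list)
    diff_mirnas: dict[str, str] = field(default_factory=dict)
    phenotype_params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _noncomplementary_base(rng: np.random.Generator, partner: str) -> str:
    """A base that neither Watson-Crick pairs nor wobbles with ``partner``."""
    bad = {_COMP[partner]}
    if partner == "G":
        bad.add("U")
    if partner == "U":
        bad.add("G")
    return str(rng.choice([b for b in "ACGU" if b not in bad]))


def gen_hairpin(mature: str, mismatches_in_duplex: int = 0,
                loop_len: int = 12,
                rng: np.random.Generator | None = None,
                basal_stem: int = 8) -> tuple[str, str]:
    """Build a fold-back precursor
    ``basal5' + mature + loop + star-arm + 2-nt tail + basal3'``.

    The star arm is the full reverse complement of the mature with the
    requested number of interior substitutions, so the designed stem pairs
    ``21 - mismatches`` mature positions; a short basal stem clamps the
    duplex the way the DCL1-required lower stem does in real precursors.
    The *star tag* — what Dicer would release and what novel-miRNA calling
    must detect — is the arm shifted by two positions plus the tail,
    giving the duplex its 2-nt 3' overhangs on both strands.  Returns
    ``(precursor, star_tag)``; the mature starts at ``basal_stem`` within
    the precursor.
    """
    if not 0 <= mismatches_in_duplex <= 6:
        raise ValueError("mismatches_in_duplex must lie in [0, 6]")
    if loop_len < 3:
        raise ValueError("loop_len < 3 is unfoldable")
    if len(mature) != 21:
        raise ValueError("mature must be 21 nt")
    rng = rng or np.random.default_rng(0)

    arm = list(revcomp(mature))        # arm[j] pairs mature[20 - j]
    if mismatches_in_duplex:
        # interior arm positions, widely separated first so the helix
        # segments between mismatches stay long enough to fold stably
        slots = [6, 13, 9, 4, 16, 11]
        for j in slots[:mismatches_in_duplex]:
            arm[j] = _noncomplementary_base(rng, mature[20 - j])
    tail = (_noncomplementary_base(rng, mature[1])
            + _noncomplementary_base(rng, mature[0]))

    loop_pool = [b for b in "AC"
                 if _COMP[b] not in mature[19:21]] or ["A"]
    loop = "".join(loop_pool[i % len(loop_pool)] for i in range(loop_len))
    basal5 = random_sequence(rng, basal_stem)
    precursor = (basal5 + mature + loop + "".join(arm) + tail
                 + revcomp(basal5))
    arm_start = basal_stem + 21 + loop_len
    star_tag = precursor[arm_start + 2:arm_start + 23]
    return precursor, star_tag


def gen_phased_locus(transcript_len: int, register_start: int,
                     n_cycles: int, depth: int,
                     offtarget_frac: float = 0.0,
                     antisense_frac: float = 0.0,
                     rng: np.random.Generator | None = None,
                     transcript: str | None = None
                     ) -> list[tuple[str, str, int, int]]:
    """Reads for one phased locus as (tag, strand, leftmost position, count).

    A fraction ``1 - offtarget_frac`` of the ``depth * n_cycles`` reads
    start exactly on the 21-nt register (sense, or antisense shifted so the
    +2 rule maps them back on register); the rest start uniformly off the
    register within the locus span.
    """
    if not 0 <= offtarget_frac <= 1 or not 0 <= antisense_frac <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if register_start + 21 * n_cycles > transcript_len:
        raise ValueError("register does not fit in the transcript")
    rng = rng or np.random.default_rng(0)
    if transcript is None:
        transcript = random_sequence(rng, transcript_len)

    total = depth * n_cycles
    n_phased = int(round(total * (1.0 - offtarget_frac)))
    reads: dict[tuple[str, str, int], int] = {}

    def emit(pos: int, antisense: bool) -> None:
        if antisense and pos - 2 >= 0 and pos + 19 <= transcript_len:
            left = pos - 2
            tag = revcomp(transcript[left:left + 21])
            key = (tag, "-", left)
        else:
            if pos + 21 > transcript_len:
                pos = transcript_len - 21
            tag = transcript[pos:pos + 21]
            key = (tag, "+", pos)
        reads[key] = reads.get(key, 0) + 1

    for r in range(n_phased):
        cycle = r % n_cycles
        pos = register_start + 21 * cycle
        emit(pos, bool(rng.random() < antisense_frac))

    span_lo = register_start
    span_hi = register_start + 21 * n_cycles
    for _ in range(total - n_phased):
        while True:
            pos = int(rng.integers(span_lo, span_hi))
            if (pos - register_start) % 21 != 0:
                break
        emit(pos, False)

    return [(tag, strand, pos, count)
            for (tag, strand, pos), count in sorted(reads.items())]


def gen_transcriptome(design: SimDesign) -> tuple[TranscriptSet, GroundTruth]:
    """Random transcripts with planted features, plus the ground truth.

    Features are placed at non-overlapping positions; identical designs and
    seeds give byte-identical output.
    """
    from .degradome import packaged_reference

    rng = np.random.default_rng(design.seed)
    truth = GroundTruth()
    lo, hi = design.transcript_len_range
    ts = TranscriptSet()
    lengths = [int(rng.integers(lo, hi + 1))
               for _ in range(design.n_transcripts)]
    seqs = [list(random_sequence(rng, L)) for L in lengths]
    occupied: list[list[tuple[int, int]]] = [[] for _ in lengths]

    def place(t_idx: int, length: int, retries: int = 100) -> int:
        L = lengths[t_idx]
        if L < length:
            raise ValueError("transcript too short for feature; "
                             "increase transcript_len_range")
        for _ in range(retries):
            start = int(rng.integers(0, L - length + 1))
            if all(start + length <= a or start >= b
                   for a, b in occupied[t_idx]):
                occupied[t_idx].append((start, start + length))
                return start
        raise ValueError("could not place feature without overlap; "
                         "increase transcript lengths or count")

    n_feat = (design.n_planted_hairpins + design.n_planted_phased_loci
              + design.n_planted_tas3 + design.n_target_sites
              + design.n_decoy_loci)
    if n_feat > design.n_transcripts:
        raise ValueError("need at least one transcript per feature")
    order = list(range(design.n_transcripts))
    t_iter = iter(order)

    for i in range(design.n_planted_hairpins):
        t_idx = next(t_iter)
        mature = random_sequence(rng, 21)
        mm = int(rng.integers(0, design.max_hairpin_mismatches + 1))
        precursor, star = gen_hairpin(mature, mm, design.hairpin_loop_len,
                                      rng)
        start = place(t_idx, len(precursor))
        seqs[t_idx][start:start + len(precursor)] = list(precursor)
        mstart = start + 8  # mature sits past the basal stem
        truth.hairpins.append({
            "id": f"mirH{i + 1}", "transcript": f"t{t_idx + 1}",
            "span": [start, start + len(precursor)],
            "mature": mature, "star": star,
            "mature_span": [mstart, mstart + 21],
            "duplex_mismatches": mm,
        })

    for i in range(design.n_planted_phased_loci):
        t_idx = next(t_iter)
        trigger = random_sequence(rng, 21)
        L = lengths[t_idx]
        need = 21 + 21 * design.phased_cycles + 30
        start = place(t_idx, min(need, L))
        site = revcomp(trigger)
        seqs[t_idx][start:start + 21] = list(site)
        cleave = start + 21 - 10  # 5' end of the 3' cleavage fragment
        truth.phased_loci.append({
            "id": f"phas{i + 1}", "transcript": f"t{t_idx + 1}",
            "trigger": f"trig{i + 1}", "trigger_seq": trigger,
            "site_span": [start, start + 21],
            "cleavage_pos": cleave, "register_start": cleave,
            "n_cycles": design.phased_cycles,
        })

    tasiarf = packaged_reference("tasiarf")
    mir390 = next(iter(packaged_reference("mir390").items()))[1]
    arfs = [seq for _, seq in tasiarf.items()][:2]
    for i in range(design.n_planted_tas3):
        t_idx = next(t_iter)
        site_seq = revcomp(mir390)
        # cassette: 5' site, spacer, two tasiARF 21-mers, then a 3' site
        # whose cleavage position is phased (mod 21) with the tasiARF start
        spacer5 = 9
        a = len(site_seq) + spacer5
        t0 = a + 52                       # (t0 + 11 - a) % 21 == 0
        cassette = (site_seq + "A" * spacer5 + arfs[0] + arfs[1]
                    + "C" * (t0 - a - 42) + site_seq)
        start = place(t_idx, len(cassette))
        seqs[t_idx][start:start + len(cassette)] = list(cassette)
        truth.tas3.append({
            "id": f"tas3_{i + 1}", "transcript": f"t{t_idx + 1}",
            "five_site_span": [start, start + 21],
            "tasiarf_spans": [[start + a, start + a + 21],
                              [start + a + 21, start + a + 42]],
            "three_site_span": [start + t0, start + t0 + 21],
        })

    for i in range(design.n_target_sites):
        t_idx = next(t_iter)
        mirna = random_sequence(rng, 21)
        start = place(t_idx, 21)
        seqs[t_idx][start:start + 21] = list(revcomp(mirna))
        truth.target_sites.append({
            "id": f"mirT{i + 1}", "mirna_seq": mirna,
            "transcript": f"t{t_idx + 1}", "site_span": [start, start + 21],
            "cleavage_pos": start + 21 - 10,
        })

    for _ in range(design.n_decoy_loci):
        t_idx = next(t_iter)
        truth.decoy_transcripts.append(f"t{t_idx + 1}")

    for t_idx in range(design.n_transcripts):
        ts.add(f"t{t_idx + 1}", "".join(seqs[t_idx]))
    return ts, truth


def gen_srna_reads(ts: TranscriptSet, truth: GroundTruth, design: SimDesign,
                   rng: np.random.Generator | None = None
                   ) -> dict[str, list[tuple[str, str, int, int]]]:
    """Per-transcript positioned sRNA reads: phased loci plus uniform
    background on decoy transcripts."""
    rng = rng or np.random.default_rng(design.seed + 1)
    reads: dict[str, list] = {}
    for locus in truth.phased_loci:
        tid = locus["transcript"]
        reads.setdefault(tid, []).extend(gen_phased_locus(
            len(ts[tid]), locus["register_start"], locus["n_cycles"],
            design.phased_read_depth, design.offtarget_frac,
            design.antisense_frac, rng, transcript=ts[tid],
        ))
    for tid in truth.decoy_transcripts:
        L = len(ts[tid])
        n_reads = rng.poisson(design.background_read_rate * L)
        acc: dict[tuple[str, str, int], int] = {}
        for _ in range(n_reads):
            pos = int(rng.integers(0, L - 21 + 1))
            key = (ts[tid][pos:pos + 21], "+", pos)
            acc[key] = acc.get(key, 0) + 1
        reads.setdefault(tid, []).extend(
            (tag, strand, pos, c)
            for (tag, strand, pos), c in sorted(acc.items()))
    return reads


def gen_count_libraries(truth: GroundTruth, design: SimDesign,
                        rng: np.random.Generator | None = None):
    """Negative-binomial miRNA count libraries with a Small/Large effect.

    Returns ``(counts, library_sizes, group_labels, trm)``.  Spiked miRNAs
    have a Large/Small mean ratio of ``group_fold_change``; per-sample TRM
    is positively coupled to the first spiked miRNA's normalized abundance.
    """
    if design.n_libraries_per_group < 2:
        raise ValueError("need at least 2 libraries per group")
    rng = rng or np.random.default_rng(design.seed + 2)
    n = design.n_libraries_per_group
    samples = [f"S{i + 1}" for i in range(n)] + [f"L{i + 1}" for i in range(n)]
    group = {s: ("Small" if s.startswith("S") else "Large") for s in samples}

    ids = ([h["id"] for h in truth.hairpins]
           + [f"bg{i + 1}" for i in range(design.n_background_mirnas)])
    spiked = [i for i in ids if i.startswith("bg")][:design.n_diff_mirnas]
    fc = design.group_fold_change
    if fc != 1.0:
        truth.diff_mirnas = {m: "up_in_large" for m in spiked}

    base_rptm = 10 ** rng.uniform(np.log10(20), np.log10(2000), size=len(ids))
    lib_sizes = np.round(design.mean_library_size
                         * np.exp(rng.normal(0, 0.2, size=len(samples)))
                         ).astype(np.int64)
    counts = np.zeros((len(ids), len(samples)), dtype=np.int64)
    phi = design.nb_dispersion
    for j, s in enumerate(samples):
        mult = np.ones(len(ids))
        scale = np.sqrt(fc)
        for gi, mid in enumerate(ids):
            if mid in spiked:
                mult[gi] = scale if group[s] == "Large" else 1.0 / scale
        mu = base_rptm * mult / 1e7 * lib_sizes[j]
        counts[:, j] = rng.negative_binomial(1.0 / phi,
                                             1.0 / (1.0 + phi * mu))

    counts_df = pd.DataFrame(counts, index=ids, columns=samples)
    lib = pd.Series(lib_sizes, index=samples)
    if spiked:
        lead = counts_df.loc[spiked[0]] / lib * 1e7
        z = (lead - lead.mean()) / (lead.std(ddof=1) or 1.0)
    else:
        z = pd.Series(0.0, index=samples)
    trm = 30.0 + 10.0 * z + rng.normal(0, 3.0, size=len(samples))
    trm = pd.Series(np.maximum(trm.to_numpy(), 1.0), index=samples)
    return counts_df, lib, group, trm


def gen_degradome(truth: GroundTruth, design: SimDesign,
                  ts: TranscriptSet,
                  rng: np.random.Generator | None = None
                  ) -> dict[str, np.ndarray]:
    """Per-transcript 5'-end count vectors: one peak of
    ``degradome_peak_depth`` reads at each true cleavage position over a
    Poisson(``degradome_background``) per-position background."""
    if design.degradome_peak_depth < 0:
        raise ValueError("degradome_peak_depth must be >= 0")
    rng = rng or np.random.default_rng(design.seed + 3)
    profile = {tid: rng.poisson(design.degradome_background, size=len(seq))
               .astype(np.int64) for tid, seq in ts.items()}
    features = (truth.target_sites
                + [{"transcript": p["transcript"],
                    "cleavage_pos": p["cleavage_pos"]}
                   for p in truth.phased_loci])
    for t3 in truth.tas3:
        for key in ("five_site_span", "three_site_span"):
            s0, s1 = t3[key]
            features.append({"transcript": t3["transcript"],
                             "cleavage_pos": s1 - 10})
    for feat in features:
        vec = profile[feat["transcript"]]
        c = feat["cleavage_pos"]
        if 0 <= c < len(vec):
            vec[c] += design.degradome_peak_depth
    return profile


def degradome_tags(profile: dict[str, np.ndarray],
                   ts: TranscriptSet,
                   fragment_len: int = 20) -> list[tuple[str, int]]:
    """Collapse a degradome profile into (5'-anchored tag, count) pairs."""
    tags: dict[str, int] = {}
    for tid, vec in profile.items():
        seq = ts[tid]
        for pos in np.nonzero(vec)[0]:
            frag = seq[pos:pos + fragment_len]
            if len(frag) == fragment_len:
                tags[frag] = tags.get(frag, 0) + int(vec[pos])
    return sorted(tags.items())


def gen_phenotypes(n_plants: int,
                   corr: np.ndarray | None = None,
                   means: Sequence[float] | None = None,
                   sds: Sequence[float] | None = None,
                   rng: np.random.Generator | None = None,
                   floor: float = 0.05) -> pd.DataFrame:
    """Multivariate phenotype table via a Gaussian copula.

    Rows are plants, columns the seven root/leaf traits; negative draws are
    truncated at ``floor * sd`` above zero.
    """
    if n_plants < 2:
        raise ValueError("need at least 2 plants")
    corr = _default_corr() if corr is None else np.asarray(corr, dtype=float)
    if corr.shape != (len(TRAITS), len(TRAITS)):
        raise ValueError(f"corr must be {len(TRAITS)}x{len(TRAITS)}")
    if not np.allclose(np.diag(corr), 1):
        raise ValueError("corr needs a unit diagonal")
    w = np.linalg.eigvalsh((corr + corr.T) / 2)
    if w.min() < -1e-8:
        raise ValueError("corr must be positive semidefinite")
    rng = rng or np.random.default_rng(0)
    means = np.array([TRAIT_MEANS[t] for t in TRAITS]) if means is None \
        else np.asarray(means, dtype=float)
    sds = np.array([TRAIT_SDS[t] for t in TRAITS]) if sds is None \
        else np.asarray(sds, dtype=float)
    z = rng.multivariate_normal(np.zeros(len(TRAITS)),
                                nearest_correlation(corr), size=n_plants,
                                method="cholesky")
    x = means + sds * z
    x = np.maximum(x, floor * sds)
    df = pd.DataFrame(x, columns=TRAITS)
    df.index = [f"plant{i + 1}" for i in range(n_plants)]
    return df
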