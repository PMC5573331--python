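"""Degradome profiles, complementary-site search, valid-read rules,
target validation tiers, t-plot data, and TAS3 two-hit detection."""

import numpy as np
import pytest

from plantsrna.config import RunConfig
from plantsrna.degradome import (DegradomeProfile, TargetSite, build_profile,
                                 classify_valid_reads, find_sites, find_tas3,
                                 packaged_reference, tplot_data,
                                 validate_targets)
from plantsrna.formats import TranscriptSet, revcomp
from plantsrna.processing import TagLibrary
from plantsrna.simulate import (SimDesign, gen_degradome, gen_transcriptome,
                                random_sequence)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}


def brute_sites(small_rna, transcript, max_mm, gu_half=True):
    """Independent all-offset complementarity scan."""
    L = len(small_rna)
    out = []
    for s in range(len(transcript) - L + 1):
        mm = 0.0
        for q in range(L):
            pair = (small_rna[q], transcript[s + L - 1 - q])
            if pair in _WC:
                continue
            mm += 0.5 if (pair in _GU and gu_half) else 1.0
        if mm <= max_mm:
            out.append((s, mm))
    return sorted(out)


class TestBuildProfile:
    def test_counts_at_five_prime_position(self, rng):
        tr = random_sequence(rng, 200)
        tag = tr[50:70]
        profile = build_profile([(tag, 24)], TranscriptSet({"t": tr}))
        assert profile["t"][50] == 24
        assert profile["t"].sum() == 24

    def test_no_match_zero_profile(self, rng):
        tr = "A" * 100
        profile = build_profile([("GCGCGCGCGCGCGCGCGCGC", 5)],
                                TranscriptSet({"t": tr}))
        assert not profile["t"].any()

    def test_multimapping_counted_everywhere(self):
        tr = "AAGCGCGCGCGCGCGCGCGCGCAAAAAGCGCGCGCGCGCGCGCGCGCAA"
        tag = "GCGCGCGCGCGCGCGCGCGC"
        profile = build_profile([(tag, 3)], TranscriptSet({"t": tr}))
        assert (profile["t"] == 3).sum() == 2


class TestFindSites:
    def test_perfect_complement(self, rng):
        mirna = random_sequence(rng, 21)
        tr = random_sequence(rng, 100) + revcomp(mirna) \
            + random_sequence(rng, 100)
        sites = find_sites(mirna, "m", tr, "t", max_mm=4)
        exact = [s for s in sites if s.mismatches == 0]
        assert len(exact) == 1 and exact[0].start == 100
        assert exact[0].cleavage_pos == 100 + 21 - 10

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            mirna = random_sequence(rng, 21)
            tr = random_sequence(rng, 150) + revcomp(mirna) \
                + random_sequence(rng, 40)
            got = sorted((s.start, s.mismatches)
                         for s in find_sites(mirna, "m", tr, "t", max_mm=5))
            assert got == brute_sites(mirna, tr, 5)

    def test_gu_counts_half_by_default(self):
        mirna = "G" * 21
        tr = "U" * 21          # every pair is G:U
        sites = find_sites(mirna, "m", tr, "t", max_mm=11)
        assert sites[0].mismatches == 10.5 and sites[0].gu_pairs == 21
        assert sites[0].effective_mm == 10
        strict = find_sites(mirna, "m", tr, "t", max_mm=21, gu_half=False)
        assert strict[0].mismatches == 21

    def test_three_substitutions_reported(self, rng):
        mirna = random_sequence(rng, 21)
        site = list(revcomp(mirna))
        for pos in (4, 10, 16):
            base = site[pos]
            site[pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
        tr = random_sequence(rng, 60) + "".join(site) + random_sequence(rng, 60)
        sites = [s for s in find_sites(mirna, "m", tr, "t", max_mm=4)
                 if s.start == 60]
        assert sites and 2.5 <= sites[0].mismatches <= 3


class TestValidReads:
    def test_canonical_spike_counted(self, rng):
        mirna = random_sequence(rng, 21)
        tr = random_sequence(rng, 80) + revcomp(mirna) \
            + random_sequence(rng, 80)
        site = find_sites(mirna, "m", tr, "t", max_mm=0)[0]
        profile = DegradomeProfile({"t": np.zeros(len(tr), dtype=int)})
        profile["t"][site.cleavage_pos] = 24
        assert classify_valid_reads(site, profile) == 24
        assert site.pos10_reads == 24

    def test_distant_reads_not_valid(self, rng):
        mirna = random_sequence(rng, 21)
        tr = random_sequence(rng, 80) + revcomp(mirna) \
            + random_sequence(rng, 80)
        site = find_sites(mirna, "m", tr, "t", max_mm=0)[0]
        profile = DegradomeProfile({"t": np.zeros(len(tr), dtype=int)})
        profile["t"][site.cleavage_pos + 5] = 30
        assert classify_valid_reads(site, profile) == 0

    def test_plus_minus_one_window(self, rng):
        mirna = random_sequence(rng, 21)
        tr = random_sequence(rng, 50) + revcomp(mirna) + random_sequence(rng, 50)
        site = find_sites(mirna, "m", tr, "t", max_mm=0)[0]
        profile = DegradomeProfile({"t": np.zeros(len(tr), dtype=int)})
        # positions opposite small-RNA 9, 10, 11
        for p in (site.cleavage_pos + 1, site.cleavage_pos,
                  site.cleavage_pos - 1):
            profile["t"][p] = 2
        assert classify_valid_reads(site, profile) == 6


def _site(sid, mm, valid, tid="t"):
    s = TargetSite(sid, tid, 0, 21, float(mm), 0, cleavage_pos=11)
    s.valid_reads = valid
    return s


class TestValidateTargets:
    def _profiles(self, sites):
        prof = DegradomeProfile()
        for s in sites:
            vec = prof.setdefault(s.transcript_id, np.zeros(100, dtype=int))
            vec[s.cleavage_pos] += s.valid_reads
        return prof

    def test_conserved_prediction_tier_without_degradome(self):
        sites = [_site("miR1", 2, 0)]
        kept = validate_targets(sites, self._profiles(sites),
                                {"miR1": "fam1"})
        assert len(kept) == 1 and kept[0].rule == "conserved_lt4"

    def test_novel_requires_valid_read(self):
        sites = [_site("nov1", 2, 0)]
        assert validate_targets(sites, self._profiles(sites),
                                {"nov1": None}) == []
        sites = [_site("nov1", 2, 3)]
        kept = validate_targets(sites, self._profiles(sites), {"nov1": None})
        assert len(kept) == 1 and kept[0].rule == "novel_valid"

    def test_fallback_blocked_by_better_family_site(self):
        sites = [_site("miR1a", 3, 1), _site("miR1b", 5, 9, tid="u")]
        fam = {"miR1a": "fam1", "miR1b": "fam1"}
        kept = validate_targets(sites, self._profiles(sites), fam)
        assert [s.small_rna_id for s in kept] == ["miR1a"]

    def test_fallback_admits_when_family_has_nothing_better(self):
        sites = [_site("miR1b", 5, 0)]
        kept = validate_targets(sites, self._profiles(sites),
                                {"miR1b": "fam1"})
        assert len(kept) == 1 and kept[0].rule == "conserved_fallback_4to5"

    def test_fallback_exclusion_property_randomized(self, rng):
        """Whenever a family has a <4-mm site, none of its 4-5-mm sites
        survive; novel retention tracks (mm < 4) & (valid >= 1) exactly."""
        for _ in range(50):
            sites = []
            fam_map = {}
            for i in range(int(rng.integers(2, 12))):
                sid = f"s{i}"
                fam_map[sid] = rng.choice(["famA", "famB", None])
                sites.append(_site(sid, int(rng.integers(0, 7)),
                                   int(rng.integers(0, 3))))
            kept = validate_targets(sites, self._profiles(sites), fam_map)
            kept_ids = {id(s) for s in kept}
            best = {}
            for s in sites:
                f = fam_map[s.small_rna_id]
                if f is not None:
                    best[f] = min(best.get(f, 9), s.effective_mm)
            for s in sites:
                f = fam_map[s.small_rna_id]
                if f is None:
                    expect = s.effective_mm < 4 and s.valid_reads >= 1
                elif s.effective_mm < 4:
                    expect = True
                elif s.effective_mm <= 5:
                    expect = best[f] >= 4
                else:
                    expect = False
                assert (id(s) in kept_ids) == expect


class TestTplot:
    def test_single_spike(self, rng):
        profile = DegradomeProfile({"t": np.zeros(50, dtype=int)})
        profile["t"][30] = 24
        table, markers = tplot_data(profile, "t")
        assert len(table) == 1
        assert table.iloc[0].tolist() == [31, 24]

    def test_empty_profile(self):
        profile = DegradomeProfile({"t": np.zeros(10, dtype=int)})
        table, markers = tplot_data(profile, "t")
        assert table.empty and markers == []

    def test_two_sites_two_markers(self):
        profile = DegradomeProfile({"t": np.zeros(100, dtype=int)})
        profile["t"][[20, 60]] = 9
        sites = [TargetSite("a", "t", 9, 30, 0, 0, cleavage_pos=20),
                 TargetSite("b", "t", 49, 70, 0, 0, cleavage_pos=60)]
        table, markers = tplot_data(profile, "t", sites)
        assert len(table) == 2 and markers == [21, 61]


class TestTas3:
    def test_planted_cassette_detected_register_zero(self):
        design = SimDesign(n_transcripts=12, n_planted_hairpins=0,
                           n_planted_phased_loci=0, n_decoy_loci=0,
                           n_target_sites=0, n_planted_tas3=2, seed=4)
        ts, truth = gen_transcriptome(design)
        mir390 = next(iter(packaged_reference("mir390").items()))[1]
        loci = find_tas3(packaged_reference("tasiarf"), mir390, ts)
        assert len(loci) == 2
        for locus, planted in zip(loci, sorted(
                truth.tas3, key=lambda t: t["transcript"])):
            assert locus.register == 0
            assert len(locus.tasiarf_spans) == 2

    def test_single_site_decoys_rejected(self, rng):
        mir390 = next(iter(packaged_reference("mir390").items()))[1]
        refs = packaged_reference("tasiarf")
        arf = next(iter(refs.items()))[1]
        # tasiARF with only an upstream miR390 site
        tr1 = (random_sequence(rng, 60) + revcomp(mir390) + "AAAA" + arf
               + random_sequence(rng, 60))
        # dual miR390 sites with no tasiARF between them
        tr2 = (random_sequence(rng, 30) + revcomp(mir390)
               + random_sequence(rng, 60) + revcomp(mir390)
               + random_sequence(rng, 30))
        ts = TranscriptSet({"t1": tr1, "t2": tr2})
        assert find_tas3(refs, mir390, ts) == []


class TestGeneratorClosure:
    def test_planted_sites_recovered_and_zero_depth_dropped(self):
        design = SimDesign(n_transcripts=20, n_planted_hairpins=0,
                           n_planted_phased_loci=0, n_decoy_loci=0,
                           n_planted_tas3=0, n_target_sites=6,
                           degradome_background=0.0, seed=9)
        ts, truth = gen_transcriptome(design)
        profile = gen_degradome(truth, design, ts)
        sites = []
        family_of = {}
        for t in truth.target_sites:
            family_of[t["id"]] = None
            sites.extend(find_sites(t["mirna_seq"], t["id"],
                                    ts[t["transcript"]], t["transcript"],
                                    max_mm=4))
        kept = validate_targets(sites, DegradomeProfile(profile), family_of)
        recovered = {(s.small_rna_id, s.transcript_id, s.start) for s in kept}
        for t in truth.target_sites:
            assert (t["id"], t["transcript"], t["site_span"][0]) in recovered

        # zero depth: same truth, empty degradome
        zero = DegradomeProfile({tid: np.zeros(len(seq), dtype=int)
                                 for tid, seq in ts.items()})
        for s in sites:
            s.valid_reads = 0
        assert validate_targets(sites, zero, family_of) == []
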