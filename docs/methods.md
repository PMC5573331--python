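# Methods

`plantsrna` annotates plant small-RNA transcriptomes: it discovers miRNA
precursors by homology and hairpin structure, detects 21-nt phased siRNA
(phasiRNA) loci with a hypergeometric register statistic and a phase score,
recognizes TAS3 loci by their two-hit miR390 trigger architecture, validates
miRNA/tasiRNA targets against degradome (PARE) 5′-end profiles, and tests
miRNA abundance against a root-biomass grouping. All coordinates are 0-based
half-open internally and 1-based inclusive in reports and GFF3; sequences
are held as RNA (U) internally, with DNA input converted on read.

## Phasing statistics

A scan window spans `m` phases of `phase_len` = 21 nt (defaults `m` = 10,
window = 210 nt), so it contains `21·m` possible 5′-end positions. Let `n`
be the number of distinct positions occupied by unique 21-nt sRNAs in the
window and `k` the number of those positions in the register defined by the
window start. Under the null that occupied positions are an unordered
uniform draw of `n` of the `21·m` positions, the probability of `k` or more
in-register positions is the hypergeometric upper tail

    P = Σ_{X=k}^{min(n,m)} C(m, X) · C(20m, n−X) / C(21m, n).

The sum runs to `min(n, m)` so every term is defined when `n < m`. The tail
is evaluated in log space with `lgamma`-based binomial coefficients
(relative accuracy ~1e−13 up to `n` = 210, verified against exhaustive
placement enumeration and `scipy.stats.hypergeom`). Results are cached on
`(n, k, m)`.

Read support is summarized by

    score = (k − 2) · ln(1 + 10 · ΣP_i / (1 + ΣU_i))   for k ≥ 3, else 0,

where `P_i` and `U_i` are the in-register and off-register *raw read*
counts of phase `i`. The score is zero when fewer than three unique phased
sRNAs are present or when no phased reads exist, strictly increasing in
phased reads and non-increasing in off-register reads.

Conventions chosen where several readings are possible:

* **Antisense offset.** A minus-strand read's phase position is its
  leftmost transcript coordinate plus 2, reflecting the 2-nt 3′ overhang of
  the siRNA duplex. An all-antisense register therefore yields the same
  `(n, k)` as its all-sense mirror (a tested invariant).
* **Window slide.** Windows slide by 1 nt, so every candidate register
  start is examined; a 21-nt slide would miss registers out of phase with
  the scan origin.
* **Unique-sRNA counting.** `n` and `k` count distinct *occupied
  positions*: this is what the sampling model draws, and it keeps
  `k ≤ min(n, m)` when several distinct tags share a 5′ end. `P_i`/`U_i`
  count raw reads.
* **Tags other than 21 nt** are excluded from the scan (and logged).

A transcript is called a phased locus when some window reaches
`p ≤ 1e−3` and `score ≥ 5` (both configurable); the best window (smallest
p, then largest score, then leftmost) represents the locus.
`anchor_to_trigger` restricts the scan to windows at or downstream of a
validated cleavage site and reports the offset of the best window from the
cleavage position; offset ≡ 0 (mod 21) means the locus sits in the
trigger-defined register.

## Folding and the hairpin filters

Structure prediction is pluggable. `backend="auto"` (the default) uses the
ViennaRNA `RNAfold` binary when present on PATH — full Turner
thermodynamics, the appropriate model for deciding whether a candidate
window folds into a miRNA-like hairpin. The built-in fallback is a
Nussinov-style base-pair-maximization folder (Watson–Crick plus G:U, minimum
hairpin loop 3) with a deliberately simple energy assignment: −3 kcal/mol
per G:C, −2 per A:U, −1 per G:U, no loop terms. It is exact for its
objective (verified against brute-force enumeration of nested pairings),
deterministic, and fast (numba-compiled DP). Ties in pair count are broken
lexicographically toward Watson–Crick-rich, stacked helices, which is what
a thermodynamic model would prefer. Pair maximization treats every pair as
equally worthwhile, so on long windows it can trade stem pairs for isolated
pairs elsewhere; this is why the thermodynamic backend is preferred when
available, and why the internal model's energies must not be read as free
energies. The −40 kcal/mol precursor threshold is meaningful under both
backends (a true hairpin window scores far below it in either model).

Candidate precursors come from an ungapped, substitution-only homolog
search of known mature miRNAs (both strands, ≤ 2 mismatches by default,
`N` never matches), widened by 150-nt flanks and folded. Two filters apply:

* **Hairpin filter:** ≥ 18 paired nucleotides *within the mature region*
  (the whole-window reading would be vacuous on a 321-nt window) and
  folding energy strictly below −40 kcal/mol.
* **Duplex audit (MIRcheck-style):** the mature/star duplex is identified
  as the longest chain of mature positions whose partners strictly descend
  as the mature ascends (the only geometry a duplex can have). Walking
  consecutive chain anchors: `min(gap_mature, gap_partner)` counts as
  mismatches, mature-side excess (`gap_mature − gap_partner`) as
  bulged/asymmetrically unpaired nucleotides, and the longest contiguous
  off-duplex mature stretch between anchors as the continuous-mismatch
  run. Mature positions paired off the chain (opportunistic or internal
  pairings) are treated exactly like unpaired positions — they are not part
  of the duplex. Unpaired mature termini count toward the mismatch total
  but not the interior run. Pass requires ≤ 6 mismatches, ≤ 2 bulged
  nucleotides, and run ≤ 3.

Novel miRNA calls strictly require the star: tags must map to both hairpin
arms, and the dominant tag per arm must form a duplex whose two 3′
overhangs are 2 ± 1 nt (computed from the anti-diagonal of the paired
positions). The more abundant tag becomes the mature. IsomiRs are merged:
two calls in one family are the same member when trimming at most two
terminal nucleotides in total makes their sequences identical — unless both
carry recorded, distinct precursors, which pins them to separate loci.

## Degradome target validation

Degradome tags are placed at every exact sense match; each match increments
the 5′-end count at its position (multi-mapping tags count at every locus).
Target sites are scored over every ungapped offset, pairing small-RNA
position `q` (5′→3′) against transcript position `start + L − 1 − q`:
Watson–Crick = 0, G:U wobble = 0.5 (SeqTar-style discounting; a switch
restores G:U = 1), otherwise 1; the integer floor of the total is compared
with thresholds. The canonical cleavage position lies opposite small-RNA
positions 10–11; a degradome read is *valid* when its 5′ end falls opposite
positions 9–11 (±1-nt tolerance around the slicer site — the source method
defers this definition, so it is config-exposed).

Retention rules: conserved-family small RNAs keep sites with < 4
mismatches outright, and 4–5-mismatch sites only when the family has no
lower-mismatch site anywhere (fallback tier, no degradome support
required); novel small RNAs additionally require ≥ 1 valid read. Each kept
site is labelled with the rule that admitted it.

TAS3 loci require a tasiARF homolog (≤ 3 mismatches, sense strand; a small
replaceable reference set of canonical ARF-targeting 21-mers ships with the
package) with miR390 complementary sites (≤ 5 mismatches) on both sides.
The register is `(3′-site cleavage position − tasiARF start) mod 21`; 0
means the tasiARF sits in the phase set by the 3′ cleavage, the two-hit
signature.

## Differential abundance

Plants are grouped by total root mass: Medium is the inclusive band
mean ± 0.5·sd (sample sd, n−1; the threshold source can be an external
cohort), Small and Large lie strictly outside. RPTM = raw × 10⁷ /
library size, where library size is the total qualified reads *before*
blocklist filtering (depth normalization should not change when rRNA
fragments are removed; flagged for users since the convention is not
universal). miRNAs with mean RPTM ≥ 10 in either extreme group are tested.

The test is an exact conditional negative-binomial test on size-equalized
counts: counts are scaled to the mean library size, a common dispersion is
moment-estimated by pooling `Σ(s² − m) / Σ m²` over genes and groups, and
each gene's per-group aggregate counts `(a, b)` are tested conditionally on
`a + b` — the conditional law depends only on the aggregate size parameters
`n_group/φ`, not the expression rate, so the two-sided p-value sums every
outcome no more probable than the observed one. A quasi-likelihood
chi-square test was tried first and proved anticonservative at 6-vs-6
libraries; the exact test's null p-values are uniform by KS at that design
(measured by the acceptance script) with essentially full power at 3-fold
spikes. It is a documented in-package count test: no numerical equivalence
with any external tool is claimed. Multiplicity is controlled with
Benjamini–Hochberg (step-up, the default of the tools this analysis family
uses; Bonferroni is a one-line change via `statsmodels`).

Trait correlation matrices are pairwise-complete Pearson with two-sided
t-test p-values; constant columns give missing entries. qPCR fold changes
are 2^−ΔΔCt with ΔCt = Ct_target − Ct_reference and the calibrator's ΔCt
subtracted, so the calibrator's fold change is exactly 1.

## Synthetic data

The generator produces every input the pipeline consumes, with the planted
truth recorded for scoring. Defaults (all exposed on `SimDesign`):

| parameter | default | meaning |
|---|---|---|
| `n_transcripts`, `transcript_len_range` | 30, 600–1200 nt | i.i.d. uniform ACGU background |
| `n_planted_hairpins` / `max_hairpin_mismatches` | 5 / 2 | fold-back precursors |
| `hairpin_loop_len` | 12 nt | terminal loop, low-pairing bases |
| `n_planted_phased_loci`, `phased_cycles`, `phased_read_depth` | 3, 10, 5 reads/cycle | phased registers downstream of a trigger site |
| `offtarget_frac`, `antisense_frac` | 0.2, 0.25 | off-register and minus-strand read fractions |
| `background_read_rate` | 0.02 reads/nt | uniform reads on decoy transcripts |
| `n_libraries_per_group`, `group_fold_change`, `nb_dispersion` | 6, 3.0, 0.05 | NB count libraries, Large/Small spike ratio |
| `n_background_mirnas`, `n_diff_mirnas` | 180, 20 | expression rows; spiked subset |
| `mean_library_size` | 5×10⁶ | lognormal library sizes (σ = 0.2) |
| `degradome_peak_depth`, `degradome_background` | 24 reads, 0.1/nt | cleavage peaks over Poisson noise |
| `phenotype_corr` | biomass-leaf structure, r(TRM,TLA) = 0.78 | Gaussian-copula trait table |

Planted hairpins are `basal5′ + mature + loop + star-arm + tail + basal3′`:
the star arm is the full reverse complement of the mature with the
requested interior substitutions placed at widely separated positions (so
helix segments between mismatches stay long enough to fold stably), and an
8-bp basal stem clamps the duplex the way the DCL1-required lower stem does
in real precursors. The star *tag* is the arm shifted 2 nt plus the tail,
giving the duplex its 2-nt 3′ overhangs. Phased loci plant a perfect
trigger complementary site whose cleavage position starts the register;
counts follow NB(mean, φ) with variance μ + φμ²; per-sample TRM is coupled
positively to the first spiked miRNA's normalized abundance. Phenotypes are
drawn from a Gaussian copula at the requested correlation and truncated at
a small positive floor only at output. Identical `SimDesign` + seed gives
byte-identical outputs.

What the generator does **not** emulate: sequencing errors, adapters and
quality scores (upstream of everything here), multi-locus sRNA families,
GC-content and length heterogeneity of real transcriptomes, tagwise
dispersion heterogeneity, and batch effects. Passing closure tests
therefore demonstrates internal consistency of the statistics and the
discovery chain, not performance on real libraries.

## Numerical and edge-case choices

* Binomial coefficients via `lgamma`; p-values clipped to [0, 1];
  `(n, k, m)` memoized.
* Folding: deterministic traceback (closed pair first, stacked
  continuation preferred, then most-distal bifurcation partner); sequences
  that cannot form 3 pairs are reported unfolded with energy 0.
* Grouping with zero variance labels everything Medium with a warning;
  boundary TRM values are Medium (inclusive band).
* Empty read sets scan to all-null windows; transcripts shorter than one
  window return an empty list (logged).
* All-zero count rows give p = 1; a compared group with < 2 libraries is an
  error.
* Tag libraries reject non-positive counts with the offending line number;
  duplicate FASTA ids are a hard error naming the id.

## Problem sizes

The bundled verification uses desk-scale simulations: 20 planted phased
loci and 20 decoys, 50 planted precursors and 50 shuffled decoys, 10⁴
null windows, 10⁵ Monte-Carlo placements, a 1000-miRNA null matrix, and
100 spiked 6-vs-6 simulations. These sizes give sub-percent Monte-Carlo
error on the reported rates while keeping the whole suite and the
acceptance script each under a minute of compute on one core (plus ~40 s
of RNAfold calls in the hairpin-closure block).

## Known limitations

* Transcript-space only: no genome coordinates, no spliced alignment, and
  no SAM/BAM ingestion.
* The homolog and blocklist searches are exact/substitution-only by
  design; real pipelines using heuristic aligners may admit gapped hits.
* The internal folder's energies are not free energies; quantitative
  energy filtering should use the RNAfold backend.
* 24-nt phasing and genome-wide PHAS family discovery are out of scope.
* The exact NB test assumes a common dispersion; strongly gene-specific
  overdispersion would make its p-values approximate.
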