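# Methods

`exoncgh` implements the analysis stack of an exon-centric targeted
array-CGH workflow: probe-panel design and coverage accounting, simulation
of probe-level hybridization signals, two-tier interval-score CNV calling
with integration of the two calling modes, single-probe exon-level
analysis, and relative-dosage validation by qPCR. This note records the
models, the parameters that matter, and the design choices made where the
design was genuinely open.

## Signal model

Array CGH compares a test genome against a diploid reference. Each probe
reports a log2 ratio of hybridization intensities; a region at copy number
`c` has expected centered log2 ratio `log2(c/2)`: 0 for diploid, +0.585
for a heterozygous single-copy gain (c = 3), −1 for a heterozygous
deletion (c = 1). Copy number 0 has no finite log2 ratio; the simulator
and the copy-number estimator use a floor of −4 (configurable), which is
where homozygous deletions empirically saturate on real arrays.

The simulator draws each probe's ratio from `Normal(log2(c/2), sigma_i)`
with `sigma_i = sigma * u_i`, `u_i ~ Uniform(0.8, 1.2)`. The jitter
models per-probe quality differences and is recorded in the output as the
probe's error estimate — exactly the quantity the error-weighted caller
consumes. Optional ingredients: uniform outliers (probability 0.01 by
default, replacing the draw with `Uniform(−2, +2)`), and a sinusoidal
"wave" artifact (off by default) to stress the caller the way GC waves
stress real arrays. What the generator does *not* emulate: two-channel
raw intensities, dye effects, background, GC-dependent wave structure in
its realistic autocorrelated form, or mosaic (non-integer) states.
Passing tests therefore demonstrate correctness of the calling machinery
under its own assumptions, not robustness to every artifact of real
hybridizations.

## Noise estimation and centralization

The derivative log-ratio spread (DLRS) estimates per-probe noise from
successive differences along the genome:
`sigma_hat = 1.4826 * median(|r_{i+1} − r_i|) / sqrt(2)` per chromosome,
pooled by the median across chromosomes. Because it differences
neighbors, it is insensitive to segmental shifts (CNVs) that inflate a
naive SD.

Centralization shifts the ratios so the diploid state sits at zero. The
default "mode" method takes the densest bin of a smoothed histogram (bin
width 0.01 log2 units, 11-bin boxcar) and refines it with five flat-kernel
mean-shift iterations of half-width 0.25. The refinement converges to the
center of the diploid bulk and keeps the estimator's error well below the
gain/loss typing cuts even with ~5 % of probes inside CNVs; a raw
narrow-bin mode is far too noisy. A plain median is available and is
adequate when the aberrant fraction is small.

## Interval-score CNV calling

An interval `I` spanning probes `i..j` scores

    global   (ADM-1-like):  S(I) = |Σ r_k| / (sigma_hat · sqrt(|I|))
    weighted (ADM-2-like):  S(I) = |Σ r_k / sigma_k| / sqrt(|I|)

The two coincide when every `sigma_k` equals `sigma_hat` (asserted by
test). The published descriptions of the commercial ADM detectors specify
this statistic in outline only; the search procedure here is a recursive
maximal-interval search reconstructed from that outline, and equivalence
with any proprietary implementation is not claimed. Per chromosome, the
highest-scoring contiguous interval is found exhaustively over all O(n²)
probe pairs (prefix sums, vectorized per interval length, capped at
`max_interval_probes` = 10,000). If its score clears the threshold, a call
is emitted and both flanks are searched independently; ties break
longest-then-leftmost. An interval that clears the threshold but fails
the minimum probe count or gain/loss typing is discarded while its flanks
are still searched, so an isolated outlier probe cannot mask a real call
elsewhere; sub-intervals inside a discarded interval are not re-searched.

Parameters, with defaults and rationale:

- `threshold_T = 6.0` — a conventional ADM default. Scouting the null
  (pure `N(0, 0.2²)` arrays of 500–2,500 probes) showed the maximum
  interval score stays below 6, so the default yields essentially zero
  false calls at panel scale (asserted over 200 seeds).
- `min_probes = 3` — the standard reporting convention for multi-probe
  aCGH calls; imbalances under three probes are the single-probe module's
  job.
- Typing cuts `±0.30` — midway between noise and the heterozygous
  amplitudes (+0.585 / −1), so threshold-passing intervals whose mean is
  biologically meaningless are dropped.
- Copy number estimate: `round(2·2^mean) clamped to [0, 8]`; maps +0.58 to
  3 and −1 to 1 exactly.

Calls never span chromosomes. Both modes are run and their call sets
merged by reciprocal overlap ≥ 0.5 (same chromosome and type). Matched
pairs merge into a tier-"both" call (union interval, max score, union of
algorithm labels; the higher-scoring member donates `mean_log2` and the
copy-number estimate; probe count is the max). Unmatched calls are kept
with tier "single-algorithm": a strictly error-weighted analysis can drop
a real event that the global-noise analysis sees, so discarding
single-algorithm calls would trade sensitivity for specificity silently —
keeping them, flagged, routes them to orthogonal validation instead.

## Single-probe exon analysis

Exon-level imbalances covered by one or two probes are invisible to
3-probe interval calling. The exon caller computes `z_k = r_k / sigma_k`
per probe, maps probes to exons by ≥ 1 bp overlap, and calls an exon
aberrant only when *all* its probes exceed `z_min` with a consistent sign.
Exons with no probes are reported as `uncovered`, never `normal` — absence
of evidence is made explicit. `z_min = 3.0` by default: at panel scale
(~10⁴ probes) a 3-SD cut keeps the expected number of false single-probe
signals per array in the tens, which is acceptable for a validation track
but not for discovery; this is why aberrant statuses are, by default,
reported only for genes flagged causative. Suppressed hits on
non-causative genes are logged and returned in a separate list rather
than silently dropped. Single-probe mode is strictly more sensitive and
strictly more false-positive-prone than 3-probe calling on matched
simulations; both rates are measured and the ordering asserted in the
test suite. Probes supporting an exon call are counted within the exon
only; runs crossing exon boundaries belong to the interval caller.

## Probe design

Candidate 60-mers are slid across each exon (stride 1 by default), hard-
filtered (non-ACGT bases, homopolymer runs > 6, GC outside 30–70 %,
self-complementary stretch > 12 nt) and soft-scored by a product of
penalties for Tm deviation from the 80 °C isothermal target, GC deviation
from 50 %, homopolymer run length and self-complementarity. Up to two
candidates per exon are kept, best-per-positional-bin so the picks spread
across the exon; equal scores break to the leftmost start, making
selection deterministic. Exons where no candidate passes fall back to
end-to-end genomic tiling with a doubled Tm tolerance; exons where even
tiling fails (e.g. assembly gaps) are returned as uncovered. Exons
shorter than the probe extend symmetrically into flanking sequence.

Melting temperatures use the unified nearest-neighbor parameter set
(SantaLucia & Hicks 2004, via Biopython) at fixed documented constants —
150 mM Na⁺, 250 nM per strand, entropic salt correction — chosen so a
balanced random 60-mer sits near the 80 °C target. Specificity is
approximated by sequence-intrinsic penalties only; there is no
genome-wide uniqueness search. A k-mer uniqueness filter can be layered
on top of `score_candidate` by callers that need it.

Coverage accounting: a target is covered iff ≥ 1 probe overlaps it by
≥ 1 bp; the coverage percentage is rounded half-up to a whole percent
(the exact fraction is carried alongside); median probe spacing pools
consecutive start-to-start distances within chromosomes. Database
containment of a call is classified as completely contained (call ⊆ one
database interval), almost completely contained (contained fraction
≥ 0.9 — the phrase is conventional and has no published definition, so
the 0.9 cut is ours), overlapping, or not reported.

## qPCR dosage validation

Relative dosage uses the delta-delta-Ct model with a healthy diploid
calibrator: `dCt = Ct_target − Ct_reference` per sample,
`ddCt = dCt_sample − dCt_calibrator`, `RQ = 2^−ddCt`. RQ is computed
replicate-wise (each target replicate against the sample's mean reference
Ct) and summarized by mean and SD. Classification applies fixed bands on
the RQ scale: ≤ 0.6 loss, 0.8–1.2 normal, ≥ 1.4 gain, with the gaps
(0.6–0.8, 1.2–1.4) reported as `indeterminate` rather than forced into a
call. The thresholds are stated in the source workflow as "ΔΔCt" values,
but a normal band of 0.8–1.2 around 1 is only coherent on the `2^−ΔΔCt`
scale on which results are reported, so the bands are applied to RQ; this
interpretation is deliberate and documented here. Concordance with the
array matches each amplicon to the overlapping call (no overlapping call
means the array claims normal); indeterminate counts as discordant. The
ideal-doubling assumption (amplification efficiency exactly 2) is not
corrected for.

## Fixtures and problem sizes

The bundled `patient1` fixture reconstructs a ten-CNV case (six gains,
four losses) at printed genomic coordinates, with the printed per-call
probe counts, ~1,400 diploid backbone probes for centralization and noise
estimation, and two qPCR assays (dosages 1.5 and 0.5). The probe count of
the sub-kilobase gain record is not separable from the printed table and
is reconstructed as 3, the minimum consistent with its detection by a
≥ 3-probe interval method. `patient2` reconstructs a heterozygous
two-exon deletion where one exon carries two probes and the neighboring
exon none, exercising the single-probe path and the explicit-uncovered
reporting. Fixture hybridization noise is `sigma = 0.12`, a typical
good-quality DLRS value (the source arrays' QC metrics are unpublished);
the simulator's general default stays at 0.2. Fixture probe layouts are
reconstructions, flagged as such in fixture metadata.

Test-suite problem sizes — 2,000-probe amplitude checks, 500-probe null
arrays over 200 seeds, 150-probe detection grids at 3 amplitudes × 3
lengths × 200 replicates, 500 qPCR replicate sets — were chosen so each
statistical assertion has comfortable margin (e.g. the mean of 2,000
draws at sigma 0.2 has standard error 0.0045 against a ±0.02 band) while
the whole suite stays fast.

## Known limitations

- The ADM-likeness is a reconstruction of a published outline, not a
  re-implementation of the commercial detectors; numeric thresholds are
  not interchangeable with theirs.
- No GC-wave detrending: the wave artifact exists in the simulator to
  demonstrate the limitation, not to be corrected.
- No mosaicism, balanced rearrangements, or repeat-expansion detection —
  out of scope for log2-ratio interval calling generally.
- The qPCR model assumes perfect doubling per cycle; no efficiency
  calibration.
- Pipeline determinism is per seed and configuration; the config hash
  stamped on every output file covers parameters and tool version, not
  the execution environment.
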