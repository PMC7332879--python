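# Methods

This note documents the models, conventions and numerical choices behind
`residomics`, and what its synthetic-data tests do and do not establish
about real data.

## Processing model

Every run is a centroided LC-MS1 acquisition: ordered scans of
(m/z, intensity) centroids with retention times. Feature extraction is a
deterministic six-stage chain with the reference protocol's printed
parameters as defaults:

| stage | defaults | boundary convention |
|---|---|---|
| crop filter | scans 1–1130, RT 0.01–12.51 min, m/z 100–1200 | inclusive |
| mass detection | noise level 6.0e2 counts | keep ≥ level |
| chromatogram builder | min span 0.01 min, min height 5.0e3, tol 0.01 Th / 5 ppm | keep ≥ minima |
| RT (mobile-phase) filter | keep-window 0.01–12.01 min | inclusive |
| deconvolution | baseline 9.0e3, min peak height 1.0e4, duration 0–2 min | above baseline is strict (>) |
| isotope grouper | tol 0.01 Th / 5 ppm, RT tol 0.05 min, max charge 1, monotonic | — |

Tolerance semantics everywhere: an "X Th or Y ppm" tolerance is the
window `max(X, Y·mz/1e6)` at query mass mz — the wider wins. "Minimum"
thresholds are inclusive (≥); the deconvolution baseline cut is strict
(>); both conventions are asserted by tests that straddle the boundary
by 1% (1.0e4 kept, 0.99e4 dropped).

The chromatogram builder is single-pass greedy: each scan's centroids
join the open trace with the closest intensity-weighted representative
m/z within tolerance (ties to the more intense centroid); one point per
trace per scan; unmatched centroids open traces that only become
candidates at the next scan. No named algorithm variant is prescribed by
the protocol; this is the simplest construction satisfying its stated
parameters, and its known failure mode — trace splitting when per-scan
m/z error approaches the window, i.e. above ~1000 Th at 5 ppm error —
is visible and harmless in the attribution tests.

Isotope grouping chains features upward from the lowest m/z at spacing
1.00336/z Da (¹³C–¹²C) within the RT tolerance; with the monotonic-shape
option each successor must not exceed its predecessor's height. The most
intense member represents the group downstream and carries the charge.

## Alignment and curation

The join aligner processes runs in lexicographic run-id order (greedy
alignment is order-sensitive; fixing the order makes borderline cases
reproducible, and for compound spacings beyond twice the tolerance the
induced partition is provably order-free — asserted as a test). Features
match the best-scoring existing row within both tolerances,
`score = 10·(1 − Δmz/tol) + 10·(1 − ΔRT/tol)`, a run contributing at
most one feature per row; both weights are the protocol's printed
values. Row consensus m/z is the height-weighted member mean.

Curation follows the protocol's post-export procedure: rows with
abundance in **any** blank-pipe run are removed (the conservative
reading of "shared with the blanks"; an all-blank-replicates rule is a
config option), then each sample's TA/APW/MTBE columns are union-merged
into one compound list carrying per-row maximum height. Abundance is
peak height, not area, matching the height-driven thresholds upstream.

QC pools, ancient samples and references are aligned in **one** matrix,
so attribution intersects row ids exactly rather than re-matching with a
second tolerance layer — mirroring the single-batch design in which QC
standards run alongside the artifact extracts.

## Attribution

`venn_counts` is plain set algebra on aligned row ids; `exclusive` is
defined against the union of the *other references* (not the ancient
samples). References default to QC-pool runs, falling back to the union
of a species' replicates. No minimum shared count is imposed: a species
sharing zero compounds is legitimate output (ranked last), and the
report is ranked evidence, not a use/no-use decision.

Biomarker annotation matches aligned rows to a library of standards by
observed m/z and RT. Isobars (same m/z within tolerance) are resolved by
RT first; if several remain and fragment spectra exist, by cosine
similarity over 0.02 Th fragment bins with a 0.7 calling threshold
(cosine is the field default; nothing finer is warranted by the data);
otherwise the row is reported *ambiguous*, never silently assigned. The
bundled seven-standard library (nicotine, anabasine, cotinine, arbutin,
caffeine, theobromine, theophylline) stores instrument-observed m/z
values, which deviate from theory by several ppm and are therefore never
used as analytic ground truth. The arbutin entry is stored as [M+Na]⁺:
the observed 295.084 matches sodiated arbutin to 5 mTh, while the
doubly-sodiated label it sometimes carries would sit ~23 Th higher.

## Formula prediction

Exhaustive search of the element lattice C 0–50, H 0–100, N 0–5, O 0–40
(defaults) within `max(abs, ppm·mz/1e6)` of the query; the hydrogen
count is solved analytically from each CNO combination's mass residual,
so cost scales with the non-H range product (~13k combinations) rather
than the 1.3M-point lattice, and equality with a vectorized brute-force
enumeration is asserted over hundreds of random queries. Candidates sort
by |ppm error|, ties lexicographic by (C,H,N,O).

"[M+H]⁺" adds the hydrogen **atom** mass (1.00783 Da, electron
uncorrected) by default — the only convention that reproduces the
printed leucine-enkephalin lockmass 556.2771; an electron-corrected
proton convention is selectable. The prediction tolerance "0.0 Th or
3.0 ppm" is ppm-only by the max-window rule. Isotope envelopes come from
truncated polynomial convolution of per-element isotope distributions
(bundled NIST table, 6 d.p.), peak spacing 1.00336/z; the envelope score
is `100·(1 − Σ|obs−theo|/Σtheo)` over matched peaks, clipped to
[0, 100] — simple, bounded, monotone in agreement — with the default
minimum at 95%. Ring-double-bond and nitrogen-rule filters exist but are
off by default (the protocol states none).

## Ordination

Jaccard distances (`1 − |a∩b|/|a∪b|`, two empty sets at distance 0 with
a logged warning) feed non-metric MDS: k = 2, 20 random SMACOF starts
(delegated to scikit-learn), seeded. The reported stress is Kruskal
stress-1 recomputed in-package from the returned coordinates via
isotonic regression, so it is exactly reproducible from the outputs.
Ward clustering uses the ward.D dialect — the Lance–Williams recurrence
applied to the dissimilarities *as given*, no squaring — implemented
directly (scipy's `ward` assumes Euclidean input) and cross-checked
against R `hclust(method = "ward.D")`; it decorates the NMDS display
rather than feeding it. PCA uses Pareto scaling, `(x − x̄)/√s` with the
sample standard deviation (ddof 1), missing cells as zeros
(presence/absence semantics), zero-variance features dropped with a
warning, and no other feature filtering.

## Radiocarbon calibration

On a 1-yr calendar grid spanning the curve, the likelihood of a
conventional age a ± σ is `N(a; μ(t), √(σ² + σ_c(t)²))` with μ, σ_c
linearly interpolated between curve knots; normalizing gives the
posterior. HPD intervals take grid cells by descending density until the
coverage (default 0.954) is reached, merging contiguous cells —
CALIB-style behavior, so a single-interval result corresponds to the
"p = 1.0" notation. Ages outside the curve's ¹⁴C-age support (with a 5σ
guard) are rejected naming the supported range. Curve files use the
3-column `.14c` dialect (comma/whitespace separated, `#` comments).

## Synthetic studies: what they emulate and what they do not

The generator reproduces the design's structure: species signatures of
60 compounds (default) with an exact 10% pairwise overlap dedicated per
species pair; per-compound solvent affinity (1–3 solvents, weighted
toward 1–2); blank-pipe background compounds planted in *every* run;
QC pools as dropout-free species runs (27 pools for 3 solvents ×
8 species + blank); and ancient samples as weighted species mixtures
with ceil-exact compound dropout (default 0.3) plus environmental
contaminants — the three degradation mechanisms named for real ancient
residues. Compound m/z values occupy distinct 0.1 Th grid slots
(sub-grid offsets ±0.02 Th), keeping spacings above twice the matching
tolerance so ground-truth recovery is well-defined. Elution is Gaussian
(width 0.05 min — no peak shape is prescribed; Gaussian is the minimal
testable choice) sampled every 0.66 s over the 12.5 min gradient,
per-scan m/z error 5 ppm, RT jitter 0.02 min, log-normal intensities
(mean 10^5.2, sd 0.3 log10 units — arbitrary detector counts chosen so
planted peaks clear the 1.0e4 deconvolution minimum), plus sparse
sub-noise-level centroids (≤ 590 counts) to exercise the detector
threshold. Randomness is counter-based Philox with per-run substreams
keyed by (seed, crc32(run id)), so single runs regenerate independently
and output is byte-identical under a fixed seed.

Deliberately **not** emulated: profile-mode spectra, MS² fragmentation,
RT drift between runs (hence no RT-correction stage), detector
saturation, isotopologue ladders (off by default; a first-order A+1
option exists), and realistic correlated matrix effects. Passing the
recovery tests therefore shows the pipeline's logic is sound under
instrument-scale random error, not that it is robust to systematic
chromatographic drift — real data would need the alignment tolerances
revisited.

Test problem sizes: oracle-equivalence suites use 2–3 species × 15–25
compounds at 1–2 replicates; the two-species mixture-recovery check runs
the full default design's QC/blank/ancient arms (45 runs per replicate)
for 100 seeded replicates. These sizes were chosen as the smallest
designs that still exercise every stage nontrivially.

## Known limitations

- Greedy alignment has no gap-filling; a compound missed in one run is
  simply absent from that cell.
- Trace splitting above ~1000 Th at 5 ppm error can duplicate features;
  duplicates align consistently and do not bias presence/absence
  attribution, but feature counts slightly overestimate compounds there.
- The isotope grouper assumes singly-charged ¹³C ladders by default
  (max charge 1, per protocol), appropriate for small-molecule positive
  mode.
- NMDS embeddings with very few samples (< 6) routinely reach
  near-zero stress and should be read as display, not inference.
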