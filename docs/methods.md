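# Methods

This note documents the models implemented in `mudia`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter when interpreting
results.

## Acquisition model and demultiplexing

The window scheme is an arithmetic progression of isolation-window
centres (default 436→900 m/z, step 8, width 12) with the constraint
`step < width < 2·step`: consecutive windows must overlap, and windows
two apart must be disjoint, because the demultiplexer only reasons about
adjacent pairs. The effective precursor bins tile the scheme's range:
overlap bins are `width − step` wide, interior unique bins `2·step −
width` wide (these coincide at 4 m/z for the default geometry, where
`width = 1.5·step`), and the two edge bins extend to the scheme boundary.

Demultiplexing compares each cycle's adjacent window pairs. Peaks are
paired greedily by ascending m/z distance within a 15 ppm tolerance
(computed on the lower window's peak m/z); each peak pairs at most once.
A paired peak is assigned to the overlap bin with intensity equal to the
arithmetic mean of the two observations — the mean (rather than min or
sum) keeps intensities on the single-scan scale, which the attribution
and conservation tests rely on. An unpaired peak goes to its window's
unique bin unchanged. A peak that could in principle pair with both
neighbours is resolved left-to-right: pairs formed with window *i−1*
consume the peak before the (*i*, *i+1*) comparison.

## Identification

The search space is a tryptic digest (Keil rule: cleave C-terminal to
K/R, never before P — the standard convention) with ≤1 missed cleavage
and a 6–30-residue length window, at +2/+3 precursor charge. Fragments
are b2–b15 and y2–y15 at +1/+2; b ions run to b(n−1) and y ions to y(n),
so a short peptide retains its full-length y ion. Masses come from the
standard monoisotopic residue table with water 18.010565 Da and proton
1.007276 Da. Fixed carbamidomethyl-C is always applied; the variable set
is Met oxidation, protein N-terminal acetylation (including the
Met-cleaved form), and N-terminal Gln/Glu pyro-glu. **At most one
variable modification per peptide ion** is generated: the search space
grows multiplicatively with co-occurring modifications while genuinely
multiply-modified tryptic peptides are rare, and the single-variant space
keeps the candidate count per 4 m/z bin (and hence the E-value's
multiple-testing factor) stable.

The expectation score is a binomial tail: for a candidate with *n*
theoretical fragments of which *k* match the scan within 10 ppm,
`E = N_candidates · P(X ≥ k)` with `X ~ Binomial(n, p)` and
`p = n_peaks · 2·tol·m̄z / scan_range` — the chance that one random peak
of the scan lands inside one fragment's tolerance window, using the
candidate's mean fragment m/z. E is strictly decreasing in *k* for a
fixed scan. Retained matches need k ≥ 7 and E ≤ 0.05. Within one scan,
retained candidates that share a matched peak with m/z ≥ 300 are
deduplicated, keeping the smallest E (ties: lexicographic peptide
sequence); the procedure is idempotent.

Decoys are whole-protein sequence reversals with `rev_`-prefixed
accessions; a decoy peptide whose sequence collides with any target
peptide is excluded and counted. FDR filtering ranks the best match per
peptide ion by E and keeps the longest prefix whose decoy/target ratio is
**strictly below** 1%; protein-level filtering ranks proteins by their
best peptide E at a ratio **≤** 5% — the asymmetry is deliberate and
mirrors the two thresholds' wording. Razor assignment is a single pass:
each shared peptide goes to the parent with the highest sequence coverage
(fraction of residues covered by identified peptides), ties broken by
accession; coverage is not recomputed iteratively.

## Chromatogram extraction and cross-run transfer

A peptide ion's traces are built from the scans of its effective
precursor bin, restricted to fragments with m/z ≥ 300 at 15 ppm. Within
±20 s of the expected RT, the apex is the scan with the largest summed
fragment intensity; exact ties (flat-topped signal) resolve to the scan
nearest the expected RT, then to the earlier scan. A fragment is kept
only if some scan within ±20 s of the apex reaches >70% of that
fragment's maximum over the whole run — fragments peaking elsewhere are
interference, not co-elution. Quantification requires ≥4 surviving
fragments and sums them over the apex scan plus the two bin scans on
either side; at trace boundaries the window truncates (3 or 4 scans)
rather than discarding the peptide.

RT transfer fits, per run, a monotone piecewise-linear map from the
reference run's RTs (the reference is the run with the most identified
peptides; ties break by run id). Anchors — peptides identified in both
runs — are sorted by reference RT and split into roughly equal segments
(n/10, clamped to 2–20); each contributes a (median, median) knot, the
map extrapolates linearly past the outer knots with the edge segments'
slopes, and monotonicity is enforced by a running maximum. The median
absolute anchor residual is reported as the model's scale. Fewer than 10
anchors falls back to the identity map with a warning. Peptides not
identified in the reference run get reference coordinates through the
inverse-direction fit from the best run that did identify them.

Local intensity normalization computes, per run, the median log2 ratio to
the reference over shared quantified peptides in sliding RT windows
(120 s wide, centres every 60 s); windows with <3 shared peptides inherit
the nearest estimated factor, and each peptide's correction interpolates
between window centres. This removes a global scale factor exactly and a
piecewise scale factor up to window resolution.

## Quantification and differential testing

Normalized intensities form a peptide × sample matrix scaled so each
row's smallest nonzero entry is exactly 1; missing observations are 0 and
all-zero rows are dropped. Protein roll-up uses, when a protein has more
than one peptide, only peptides quantified in **all** samples; if none
qualify, or only one peptide exists, all its peptides are used with zeros
entering the mean. The per-sample protein value is the arithmetic mean of
the used peptide rows, log2-transformed with 0 mapped to a floor of −1 —
the floor reconciles zero imputation on the linear scale with the log2
display scale. The unpaired two-sided t-test defaults to pooled variance
(group sizes are equal by design; Welch is available by flag). If both
groups have zero variance, p is 1 for equal means and 0 otherwise, with a
degeneracy flag. Differential calls require |fold change| ≥ 1.3 and
p ≤ 0.05; proteins detected in only one condition are excluded from
volcano-style displays and reported separately. Reports show decreases in
the signed "−1.3-fold" convention; internally everything is log2.

Note a consequence of median-ratio normalization: when a large fraction
of the proteome is regulated in one direction, null proteins acquire a
small opposite-direction bias. The null-uniformity validation therefore
runs on the generator's intensity layer where no cross-run normalization
is needed, and restricts to proteins quantified from ≥2 universal
peptides, where the mean is untouched by zero imputation (zeros make the
single-peptide t-statistic deliberately anti-conservative toward
"absent" calls rather than null uniformity).

## PRM arm

Inclusion lists hold ≤30 precursors each (two lists per sample), with ≤3
peptides per target protein chosen from discovery by mean chromatogram
intensity among peptides unique to the target; a named shared peptide can
be admitted through an explicit allow-list, and shortfalls are filled
from a user-supplied external peptide catalog (a TSV stand-in for a
public transition atlas; no network access). Protein groups never
straddle the two lists. Quantification extracts all theoretical
transitions at 20 ppm over the full gradient (PRM has no RT scheduling),
requires ≥6 detectable transitions, applies the same co-elution/apex-sum
rules, and requires ≥4 surviving transitions with m/z ≥ 300 — the summed
intensity uses only those. Protein values are peptide **sums** (the
discovery arm uses means of relative values — the two conventions are
deliberately distinct), normalized exactly by the run's total ion
current, placed on the same relative scale, and tested as in discovery. A
target detected in only one condition is reported with an
`only_in_A`/`only_in_B` status and no p-value.

## Synthetic data generator

The generator emulates the study design end-to-end: two conditions × four
biological replicates; DIA cycles of one MS1 survey (430–915 m/z) plus
one MS2 scan per window (140–1500 m/z); peptide ions from a fully tryptic
digest whose +2 (else +3) precursor falls in the precursor range, up to 8
per protein; lognormal per-run intensity noise with unit mean and a CV of
0.15 (matching the mid-teens replicate CVs such experiments report);
whole-run peptide missingness at 5% (a typical DIA dropout level; the
design documents give no value); Gaussian elution peaks (FWHM 6 s) at a
per-sequence stable RT (an md5-hash fraction of the gradient) plus
run-level jitter (sd 2 s); stable per-fragment relative intensities in
[0.2, 1]; and uniform noise peaks (20 per MS2 scan, lognormal intensity
around 10³ against base abundances near 10⁶). Planted effects: fractions
of up/down proteins at ±1 log2, plus one pathway whose members coherently
shift by +0.8 log2, alongside random null pathways. PRM mode cycles a
≤30-entry list at a 3.2 s duty cycle with 1.6 m/z isolation.

Simulated gradients default to 300 s rather than the hours-long gradients
of real experiments: ~100 cycles give each peptide 5–10 points across its
elution peak — the same sampling regime as the real acquisition — while
keeping a full 8-run study small. Identical (truth, config, seed) inputs
reproduce byte-identical runs; all randomness flows from
`numpy.random.default_rng` seeded by (truth seed, stream tag, condition,
replicate).

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: isotope envelopes and profile-mode
peaks; chimeric co-isolation beyond the window-sharing geometry itself;
charge-state propensity, ionization efficiency, or any peptide
detectability model (all digestible peptides in range are observable);
intensity-dependent mass error; nonlinear RT drift families beyond
jitter; and correlated (batch-like) intensity structure. Detectability
choices are conventions of the simulator, not inferences about any
instrument.

## Validation problem sizes

The shipped validation suite runs the FDR calibration at 80 proteins
(≥500 true peptide ions plus reversed decoys and 200 noise-only scans,
10 repetitions), fold-change recovery at 200 proteins × (4+4) replicates
at CV 0.15, and the full spectral pipeline at 50 proteins × 8 runs with a
10-protein planted pathway — sizes at which every stage (demultiplexing,
search, FDR, transfer, normalization, roll-up, testing, enrichment) is
exercised with comfortable statistical margins while a complete run of
the suite stays in the minutes range on one CPU.

## Known limitations

- The expectation score is a generic binomial-tail statistic standing in
  for a proprietary engine score; absolute E-values are not comparable to
  other engines, only the thresholded behaviour is.
- Pairwise demultiplexing requires `width < 2·step`; schemes with deeper
  overlap would need multi-window differencing.
- Razor assignment is single-pass; pathological sharing patterns could
  depend on the (deterministic) tie order.
- The EASE background is the quantified proteome intersected with the
  annotation universe; unannotated quantified genes do not inflate N.
- mzML I/O covers centroided peak lists with per-scan isolation windows
  (32/64-bit floats, optional zlib); vendor idiosyncrasies beyond that
  subset are out of scope.
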