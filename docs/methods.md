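# Methods

This note documents the models, rules and numerical choices behind
`mrmkit`, in the spirit of the methods documentation of mature scientific
Python packages: what each stage assumes, which knobs matter, and what a
green test does and does not establish.

## Surrogate-peptide library construction

**Digestion.** Fully tryptic, zero missed cleavages: the backbone is cut
after every K or R not followed by P. The protein N-terminal fragment is
always a valid product (its left boundary is the protein start); the
C-terminal fragment is a product only if it itself ends in K/R, otherwise it
is excluded (optionally retained with a `non_tryptic` flag for coverage
checks). Zero missed cleavages is the minimal reading of "R or K at both
ends" and the common choice for synthetic-standard surrogate peptides.

**Cleavage-resistant pairs.** The six dipeptides RR, KK, RK, KR, KP, RP are
handled by two distinct mechanisms: KP/RP suppress cleavage during digestion
(trypsin does not cut before proline), while RR/KK/RK/KR mark a peptide
whose C-terminal dipeptide is a double basic site as `ragged_end` during
scoring (variable cleavage makes such peptides poor quantitative surrogates).
Folding both into one rule would make the proline behaviour untestable.

**Scoring.** Each violated criterion adds one flag; the priority tier is
1 + number of flags, so tier 1 is best and the ordering is a simple count
rather than a weighted score (the selection rules are qualitative
"higher/lower priority" statements; a count is the least-committal ordinal).
Criteria: length outside [6, 16]; Kyte–Doolittle GRAVY outside [−2, +2]
(no scale or cutoff is standard in the field; Kyte–Doolittle is the default
everywhere and ±2 excludes only genuinely extreme peptides — both are
config-exposed); presence of C; presence of M; N-terminal W; N-glycosylation
sequon N-X-S/T with X ≠ P; ragged C-terminus. Adding a flag can never lower
the tier (tested as a property).

**Selection.** One surrogate per protein (configurable) from the best
available tier; ties are broken by a seeded `random.Random` so selection is
reproducible yet unbiased. Proteins whose best tier is poor still receive a
surrogate — a deliberately low-quality peptide is better than no assay — and
proteins with no tryptic candidate at all are reported.

**Masses.** Monoisotopic residue masses with H₂O = 18.0105647 Da and
proton = 1.00727647 Da; precursor m/z = (M + z·p)/z. Product ions are the
three longest singly charged y-ions (y_{n−1}…y_{n−3}): with no measured
spectra there is no intensity ranking, and long y-ions are the conventional
default for tryptic MRM transitions. Heavy labels are C-terminal
K(¹³C₆,¹⁵N₂) = +8.01420 Da and R(¹³C₆,¹⁵N₄) = +10.00827 Da, computed from
Δ(¹³C−¹²C) = 1.003355 and Δ(¹⁵N−¹⁴N) = 0.997035; every y-ion contains the
C-terminus and therefore shifts by the full label mass. Peptide masses are
cross-checked against Biopython's monoisotopic calculator in the tests;
default precursor charge is 2+, the dominant state for tryptic peptides of
this length.

## Chromatogram model and quantifiability screening

**Simulation.** Each peptide's three product-ion traces are
ratio_i · height · exp(−(t − rt)²/2σ²) plus i.i.d. Gaussian baseline noise,
sampled at 2 Hz over a 10-minute window with σ = 0.05 min (a 3-second-wide
peak, typical of short-gradient microflow LC). The ratios (0.5, 0.3, 0.2)
sum to one, so the planted best-transition SNR is height·0.5/noise_sd.
Gaussian baseline noise is this package's choice — no noise model is
standard for triple-quadrupole traces; real MRM noise is heteroscedastic and
occasionally spiky, so screening accuracy on these simulations is an upper
bound on real-data behaviour.

**Peak detection.** The apex is the maximum of a 5-point moving average
(smoothing stabilizes apex choice at low SNR; window config-exposed).
Baseline and noise come from samples more than 0.5 min from the apex:
baseline = median, noise = 1.4826·MAD (robust to the peak's own tails).
Height = smoothed apex − baseline; SNR = height/noise. A zero-noise trace
yields an infinite-SNR sentinel (plus warning flag) when a peak is present
and SNR 0 when flat — never a crash. Area integrates the baseline-subtracted
raw trace over apex ± 3σ, with σ estimated from the full width at half
maximum, floored at zero.

**The quantifiability gate.** quantifiable ⇔ best-transition SNR > 3 AND
max pairwise RT difference among standard / endogenous / spiked peaks
≤ 0.2 min (inclusive, with a 1e-9 relative guard against float roundoff)
AND cosine similarity of the standard vs sample top-3 area vectors ≥ 0.95.
The RT tolerance and cosine threshold are package defaults (field-typical,
config-exposed); every failed call carries machine-readable reasons.
SNR > 10 marks high confidence.

## Cohort model and the discovery cascade

**Cohorts.** Per-peptide base abundances are log10-uniform on [3, 8]
(matching the 10³–10⁸ intensity dynamic range of neat-blood MRM). Biological
and technical variation are mean-preserving multiplicative log-normals with
the stated CVs (σ² = ln(1+CV²), μ = −σ²/2), so planted fold changes are
recovered exactly in expectation and exactly in value when CVs are zero.
Technical replicates (default 2) share one biological draw. Differential
peptides are multiplied by the planted fold change in cases only; a planted
fold change of 1 is treated as "no true effects" (empty differential set).
A cohort can be forced to reuse a specific differential set so that
discovery, validation and evaluation cohorts share their planted truth.
The generator does not emulate batch drift, missingness or correlated
peptides; cascade sensitivity/false-discovery results on it are therefore
idealized.

**Cascade.** Replicates are collapsed by the mean before testing. Stage 1:
fold change of group means (median optional) with the two-sided inclusive
rule FC ≥ 1.2 or ≤ 1/1.2, AND a two-sided Wilcoxon rank-sum p < 0.05 —
exact enumeration when both groups have ≤ 8 observations and no ties,
otherwise the normal approximation with tie and continuity corrections.
Stage 2 re-applies only the fold-change rule on the validation cohort, with
the added requirement that the direction match stage 1 (a marker that flips
sign has not replicated). No multiple-testing correction by default, in line
with raw-p candidate filtering for small targeted panels; Benjamini–Hochberg
is available as an option. Missing values are dropped per peptide, not
imputed — MRM missingness is informative.

## Analytical QC

Calibration uses unweighted OLS over ≥ 6 points (1/x weighting available);
R² = 1 − SS_res/SS_tot; per-point accuracy = back-calculated concentration /
nominal × 100, passing when at most one point (≥ n−1 of n) falls outside
100 ± 20 %. Because the line is refit with the outlier included, a single
+30 % excursion passes only at low-leverage points — an inherent property of
the rule, demonstrated in the tests. Intra-day precision is the worst single
day's CV over five replicates; inter-day precision is the CV of the daily
means; both must stay ≤ 20 % (bioanalytical convention; no threshold is
standard-free, config-exposed). Stability compares day-7 to day-0 recovery
under deep-freeze (−80 °C) and fridge (4 °C) storage, passing within
100 ± 20 %. Internal-standard quantification is
conc = (analyte area / IS area) × IS amount — linear in both numerator
terms and invariant under common scaling of the two areas. The final QC gate
is a strict AND over all tests, with named failing tests per rejected
marker and `incomplete_qc` when a component result is missing.

## Classifier evaluation

Hold-out splits are stratified per class at the biological-sample level and
drawn with `numpy` Generator seeded by the random state, so splits are
deterministic and technical replicates never leak across the partition.
The default model is logistic regression on standardized features (zero-
variance features dropped with a warning); any estimator with
`predict_proba` can be registered. The operating threshold maximizes
Youden's J on the training scores and is frozen for the test set — the
evaluated sensitivity/specificity are honest out-of-sample quantities.
Metrics are averaged arithmetically over the five random states. Samples
from groups other than case/control (e.g. other cancers) can be scored with
the trained model and summarized per group without entering training or the
binary metrics.

## Pipeline and determinism

`run_pipeline` derives all stage seeds from the global seed via
`numpy.random.SeedSequence`, keeps them below 2³¹, and writes the resolved
configuration next to its outputs. Output files avoid timestamps and use
fixed float formats so a rerun with the same configuration and seed is
byte-identical (tested). The demo-scale defaults (120 proteins, 150-peptide
cohort panel, 15 planted markers) keep a full run under a second while
exercising every stage; the screening stage plants best-transition SNRs from
{0.5, 2, 5, 20, 100} so both sides of the SNR > 3 gate are populated, and
the QC stage draws calibration/precision/stability series with realistic
error so a minority of validated markers fail QC, mirroring a real funnel.

## Known limitations

- Chromatogram noise is i.i.d. Gaussian; no drift, spikes, co-eluting
  interferences or saturation.
- Transition "intensity ranking" is positional (longest y-ions), not
  spectral.
- Cohorts have independent peptides and no batch structure; classifier
  performance on them overstates what a real serum panel would achieve.
- Collision-energy optimization, raw-file parsing and spectral-library
  search are out of scope; the transition list carries collision energy as
  opaque metadata.
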