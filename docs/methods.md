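# Methods

This note documents the models behind `prmquant`, the defaults that matter,
and what the synthetic acquisitions do and do not capture. Nothing here
states an empirical result that the tests or `scripts/acceptance.py` do not
themselves compute.

## Acquisition model

A scheduled PRM run monitors each heavy/light precursor inside a
retention-time window (default 2 min) centered on its elution time. Scan
times follow a duty-cycle clock: per-scan time = max(injection time,
orbitrap transient) + overhead; the cycle serves every concurrently active
precursor once, so inter-scan spacing per precursor equals
`n_active × per-scan time`. Transient times are the standard quadrupole-
orbitrap values (32/64/128/256/512 ms for 15k–240k resolving power at
*m/z* 200); unknown resolutions fall back to the nearest tabulated value
with a warning.

Per scan and precursor, the accumulated analyte ion count is
`min(AGC target, amount × response factor × g(t) × injection time)` with
`g(t)` a unit-peak Gaussian elution profile (FWHM 0.25 min — typical of the
~30 s peaks of a 75-min nano-LC gradient; configurable). The count is
Poisson-sampled and split multinomially over the peptide's fragment
pattern; this single mechanism produces the injection-time → dot-product
trend, because short fills leave per-fragment counts in the shot-noise
regime. The default response factor is ~1 ion/(amol·ms) at the apex:
1 amol ≈ 6×10⁵ molecules, of which a sub-percent ionization/transfer
efficiency reaches the detector over a 500 ms fill.

Centroid m/z values are drawn as `m/z·(1 + ε)`,
`ε ~ N(0, σ_ppm·10⁻⁶)` with

```
σ_ppm(R, m/z, N) = C · (10⁶ / R_eff) / √N,   R_eff = R·√(200 / m/z)
```

The single constant `C = 10` is calibrated so that at 60k resolving power
and a 1000-ion reference the mean absolute error exceeds the 5 ppm
identification bound while at 240k it stays ≤ 2 ppm; everything else
(resolution and ion-statistics scaling) follows from the formula. Centroids
closer than the analyzer FWHM merge into one weighted centroid, which is
how low resolving power integrates false fragment signal.

Interference is explicit: an interferent is co-isolated only when its
precursor offset lies within half the isolation width. Its fragments are
chromatographically broad by default (σ 1 min — matrix background rather
than a discrete peak), which is what degrades S/N at wide isolation; with
no interferents declared, isolation width has no systematic effect. A small
constant electronic baseline (0.002 ions/ms/fragment) keeps traces from
being exactly zero.

All randomness flows from one seeded generator recorded in the truth
object; identical inputs give bit-identical acquisitions. Sub-seeds for
levels, replicates and experiments are derived by hashing, keeping streams
independent of loop order.

### What the simulator does not capture

Profile-mode spectra, MS1 signal, predictive AGC, retention-time drift
between runs, ion suppression, peptide-specific fragmentation changes with
collision energy, and detector saturation other than the hard AGC cap.
Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain under a physically reasonable noise
model — not instrument-level validity on real raw files.

## Panel

The panel carries 21 peptide pairs for the eight core UPR proteins, four of
them real assay sequences (GGFGVVFEAK and YLTDFEPIQCLGR for PERK — E2AK3 is
the PERK gene symbol — AEPQPLSPASSSYSVSSPR for ATF6, APLSPSLLIR), the rest
synthetic proteotypic-style tryptic sequences. APLSPSLLIR's protein
attribution is ambiguous in the source assays (GADD34 vs XBP1); it is
assigned to GADD34 and flagged `protein_ambiguous`. Heavy partners carry
+8.0142 Da (¹³C₆¹⁵N₂-Lys) or +10.0083 Da (¹³C₆¹⁵N₄-Arg) by C-terminal
residue. Default endogenous amounts span 3.3–498 amol on column,
equivalent to ~400–60,000 copies per cell at 5000 cells on column —
the dynamic range of the UPR panel; heavy standards are log-spaced over
29.5–490.4 amol, the assay's spike range.

## Signal processing and QC

XICs sum all centroids within ±10 ppm of the theoretical fragment m/z —
deliberately wider than the 5 ppm identification filter, since extraction
must tolerate the error it is meant to measure. The apex is the maximum of
the 5-point moving-average-smoothed summed trace within the expected
window; minimal smoothing avoids apex jitter at the slow scan rates of the
long-fill settings. Boundaries extend from the apex to the nearer of the
1%-of-apex crossing or the valley before a rising neighboring peak
(a sustained climb to twice the running minimum from below 20% of apex);
a plain "stop at the first local minimum" rule proved fragile, truncating
low-count peaks at noise upticks. Areas use the trapezoidal rule, making
integration exactly additive across fragments.

A transition qualifies as detected when signal is present (≥ 3 nonzero
in-boundary points) and its own intensity-weighted mean |mass error| is
under 5 ppm — the identification filter applies per transition, as in
targeted-MS review practice. A pair is accepted iff both partners have
≥ 2 qualifying transitions, the mean |mass error| of detected transitions
is < 5 ppm, the Gaussian-fit R² of the summed peak is ≥ 0.8, apexes
co-elute within max(one cycle time, 0.05 min), the light/heavy
transition-area dot product is ≥ 0.85 and the light-vs-library dot product
is ≥ 0.85. The 5 ppm / ≥ 2 transitions / Gaussian-form / co-elution /
ratio-concordance criteria are the workflow's stated rules; the numeric
shape and dot-product thresholds operationalize the qualitative ones and
are configurable. Every failed criterion is named in `rejection_reasons`.

S/N is apex height of the summed trace over the median of its lowest
quartile — a floor estimate robust to boundary placement and to chemical
background spanning the whole window.

## Calibration and LOQ

Calibration fits a weighted least-squares line of response (L/H summed-area
ratio when a constant heavy standard is present, raw area otherwise) on
nominal amount, default weighting 1/x — the targeted-MS convention for
series spanning two orders of magnitude; `none` and `1/x²` are available.
At least 3 distinct nonzero levels are required. Back-calculated deviation
at a level is `100·|x̂ − x|/x` with `x̂ = (y − b)/m`. The LOQ is the lowest
level such that it **and every higher level** deviate < 20% (contiguity
prevents a noisy mid-curve level from being skipped; the non-contiguous
variant is a flag). Levels whose pair fails QC cannot be quantified and are
excluded from the fit. Deviation at a returned LOQ is < 20% by
construction, asserted on every run.

## Quantification

Single-point mode multiplies the L/H ratio by the spiked standard amount;
curve mode back-calculates through the fitted line. Negative back-
calculated amounts clamp to zero with a warning — legitimate near blank
levels. Copies per cell = amount[mol] × 6.022×10²³ / (loaded peptide mass /
protein mass per cell); defaults 1 µg and 0.20 ng give 5000 cells on
column. Protein-level values are the unweighted mean across the protein's
accepted peptides (no weighting rule is canonical; median available behind
a flag), with sd across peptides.

Fold changes are treated/control ratios of matched proteins per timepoint;
missing controls are flagged, never silently dropped, and zero-control
comparisons are flagged undefined.

## Scheduling

The digest uses the trypsin rule (cleave after K/R except before P) with
0–2 missed cleavages. "Ragged end" is operationalized as an ambiguous
cleavage register: the residue following the peptide's C-terminus, or the
residue preceding its N-terminal cleavage site, is itself K/R. Uniqueness
is exact substring containment in exactly one supplied protein entry.
Retention times come from an input column or, for synthetic work, a
hydrophobicity-sum surrogate (Kyte–Doolittle, logistic-mapped onto the
gradient) — no external RT predictor dependency.

Selection is greedy rather than an exact optimization, mirroring the
manual curation it automates: proteins are served in rounds (neediest
first), the candidate farthest in RT from already-selected targets wins,
and a candidate is admitted only if the window set stays within the
concurrency cap (default 3 pairs) at every RT — checked by sweep-line, and
asserted on every constructed method. Infeasible proteins are reported
uncovered, never silently violated.

## Experiments and problem sizes

The three scripted experiments run at sizes chosen for interactive desk
use: instrument trends on a 4-pair sub-panel over 20 seeds; LOQ ordering
on 4 pairs × 3 parameter sets (240k-500ms, 240k-60ms, 30k-500ms) × 10
seeds with 7-step 2-fold dilutions; the induction time course on one pair
per protein, 3 replicates, 10% CV. Real-instrument magnitudes — absolute
LOQ values, copy numbers, the ~5-fold and ~17-fold inductions — enter only
as simulation parameters or ordering properties. The ATF6 trajectory is
programmed as consumption-then-recovery rather than multi-fold induction:
its proteolytic activation consumes the protein, and, with the largest
baseline amount in the panel, a 17-fold scaling would also saturate the
AGC cap and compress ratios.

## Numerical choices and degenerate inputs

Gaussian shape scoring needs ≥ 5 in-boundary points (else not evaluable);
a flat trace has no explainable curvature and scores 0; fit failures score
0. The dot product is undefined for zero vectors (raised, not defaulted).
Dilution factors ≤ 1, non-positive settings, empty panels/candidate lists
and missing truth entries raise immediately. Sweep-line concurrency uses
half-open windows (close-before-open at ties), matching the grid oracle in
the tests. Sub-seeds are kept below 2³¹.
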