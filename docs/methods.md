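# Methods

This note documents the models behind `specfinger`, the assumptions of the
synthetic-data generator, and the numerical choices made where the design
was genuinely open.

## The measurement being emulated

ATR-FT-MIR absorbance spectra of the blood low-molecular-weight fraction,
recorded over the mid-IR range and analysed in the 1500–1700 cm⁻¹
amide/carboxylate window.  Each class (FM, LC, HC) is characterised by a
small set of Gaussian bands in that window; the diagnostically decisive
feature is a band near 1565 cm⁻¹ (carboxylate side-chain stretch of
glutamate/aspartate) present in FM only, while HC carry a 1545 cm⁻¹ band
absent from both patient groups.

## Synthetic cohorts

A spectrum is rendered as

    A(ν) = a·[ Σ_fingerprint g(ν; c_k, w_k, area_k) + Σ_background g(ν; …) ]
           + s·(ν − ν̄) + z·L(ν) + ε(ν)

with FWHM-parameterized Gaussians g(ν) = h·exp(−4 ln2 (ν−c)²/w²),
area = h·w·√(π/4 ln2).  Per-sample draws: global amplitude a ~ N(1, 0.1)
(film-thickness variation), baseline slope s ~ N(0, 10⁻⁴ abs/cm⁻¹), white
noise ε ~ N(0, 0.002 abs), and a nuisance score z ~ N(0, 0.5) multiplying a
fixed unit-norm loading L (broad Gaussian at 1740 cm⁻¹, the class-irrelevant
lipid ester band) — the structured inter-individual variance that the OSC
filter exists to remove.

Class fingerprints use the consensus band table: FM 1565/1588/1639/1670 cm⁻¹
with mean area shares 36.1/38.2/4.7/21.3 %, LC 1581/1635/1670 with
70.3/9.9/23.9 %, HC 1545 at 4.1 % with the remainder split 70/10/20 across
1580/1639/1670 mirroring the LC pattern (only the 1545 share is reported
for HC).  Shares are renormalized to sum to one per class.

**Within-class variability.**  Reported per-band standard deviations
conflate biological variation with deconvolution-fit scatter.  The
generator attributes the *area* sds to biology (concentration variation;
drawn per sample, truncated at 0.5 % and renormalized) and the *center* sds
to estimation noise (band positions are chemistry-determined molecular
constants, and scatter of a few cm⁻¹ in centers fitted from noisy second
derivatives on an 8 cm⁻¹-resolution instrument is expected from the fit
alone).  Centers are therefore fixed at generation; the deconvolution
reproduces center scatter of the observed magnitude on its own (e.g. fitted
center sd ≈ 1–2 cm⁻¹ and area sd ≈ 14 points for the FM 1565 band on a
noisy 40-sample cohort).  Generating the full reported center sds as
biology would produce cohorts whose classification performance contradicts
the observed near-perfect separability (measured: Rcv drops from ≈0.97 to
≈0.87).

**Amplitude scale** (nothing is published): fingerprint-region integrated
area 10 abs·cm⁻¹ gives peak absorbances ≈0.1–0.4, typical of dried-film ATR
spectra, so the 0.002 noise sd corresponds to a realistic SNR of ~10².
Background bands (O–H/C–H stretches, lipid ester, methyl bending,
phosphodiester, C–O; total area 100) mimic the broad features of a
representative blood-LMF spectrum; bands whose centers fall outside the
simulated grid contribute their tails only.

**Grid**: 1800–1400 cm⁻¹ at 2 cm⁻¹ (full-range simulation is supported but
unnecessary: every modelled feature lives in the fingerprint window plus
margin).  **Reproducibility**: one master seed; per-sample substreams
spawned by counter, so cohorts are bit-identical for a fixed config.

What the generator does *not* emulate: ATR penetration-depth dispersion,
scan co-addition noise shaping, water-vapour/CO₂ artefacts, non-Gaussian
band shapes, and correlated metabolite panels.  Passing tests therefore
demonstrate the correctness and calibration of the *pipeline*, not clinical
performance on real cohorts.

## Pretreatment

Normalize (unit 2-norm over the full recorded range) → SG smooth (5 points,
order 2) → SG second derivative (7 points, order 2, scaled by the grid step)
→ region → mean centering, in that order.  Edge points use polynomial
extrapolation of the terminal window so grids stay aligned.  "Normalized"
is unspecified upstream; the unit-vector convention is standard for film
thickness variation and makes the pipeline invariant to positive per-sample
scaling.  Only the centering means are fitted state: held-out samples are
centered with training means, and the leave-one-out loop refits the whole
chain per fold (the stricter reading — anything less leaks).

## OSC + PLS-DA

Each OSC component removes a score/loading pair (t, p) with t = Xw carrying
maximal variance subject to *exact* orthogonality to the centered response:
w is the dominant right singular vector of X·P, P the projector onto the
complement of s = Xᵀy_c.  Because w ⊥ s by construction, yᵀt = 0 to machine
precision and applying the stored (w, p) to the training matrix reproduces
the fit exactly; the classic iterated-deflation recipe only approximates
both properties and degenerates when X has no response-orthogonal variance
(that case here yields an explicit null component removing nothing).

PLS is NIPALS PLS1; the regression vector is b = W(PᵀW)⁻¹q with intercept
ȳ.  With one latent variable b ∝ w₁ ∝ Xᵀy_c, i.e. the pipeline reduces to a
covariance-direction classifier.  Class assignment thresholds ŷ at the
midpoint 1.5 of the 1/2 coding; ties go to LC (documented, arbitrary).
Figures of merit: SECV/SEP = RMS residual with denominator n (no df
correction), Rcv = Pearson(ŷ_cv, y), R² = squared Pearson on the external
set, sensitivity/specificity with FM as the positive class (configurable —
the published table is symmetric).  "Rcv" and "Rval" are reported as the
same quantity (no separate formulas exist upstream).  ROC sweeps all
thresholds of the continuous ŷ (orientation "less": smaller ŷ is more
FM-like); the trapezoidal AUC equals Mann–Whitney pairwise concordance with
ties counted ½.

## Band deconvolution

The fit target is the region-limited, inverted (×−1) second derivative,
baseline-corrected by subtracting the straight line through the region
endpoints.  Seeding: local maxima of a lightly denoised (SG 7-point),
zero-clipped copy with prominence ≥ 5 % of the region maximum, excluding
maxima within one merge distance (8 cm⁻¹) of the region edges where the
endpoint-anchored baseline is unreliable; close maxima merge
amplitude-weighted; initial FWHMs from lobe half-height widths (the central
lobe of an inverted Gaussian second derivative is ≈0.45 of the parent
FWHM).

**Matched-transform fitting.**  Band parameters (h, c, w of the underlying
absorbance-domain Gaussians) are estimated by bounded trust-region least
squares in which the model is *pushed through the identical pretreatment*
(smooth, second derivative, inversion, endpoint baseline) before comparison
with the prepared signal.  A plain Gaussian-sum fit to the inverted second
derivative misallocates relative areas by ~10 percentage points because the
transform's negative side lobes cancel neighbouring central lobes and any
min-to-zero offset adds a pedestal; matching the transformed model instead
recovers noise-free centers to <0.1 cm⁻¹ and area shares to ≤1.5 points
(residual error comes from background-band leakage into the window).
Bounds: centers within ±10 cm⁻¹ of their seed, FWHM ∈ [8, 80] cm⁻¹,
heights ≥ 0.  Convergence: relative χ² change < 10⁻⁹ or 400 residual
evaluations; a capped fit is returned flagged `converged=False`.
Diagnostics report χ², reduced χ² and the regression F of the fitted model
against a constant.  Relative percentage areas divide by the summed fitted
band areas in the region and always total 100; they are invariant to the
raw spectrum's amplitude.

**Cohort aggregation.**  Bands are matched across samples by sequential
nearest-cluster assignment (running cluster means, at most one band per
sample per cluster, new cluster beyond the 8 cm⁻¹ merge distance), followed
by a merge of clusters whose means drift within one merge distance
(pooled single-linkage chaining was rejected: order statistics of two ~40
sample clusters 23 cm⁻¹ apart routinely bridge an 8 cm⁻¹ gap).  Summary
rows require support from ≥50 % of samples; samples missing a band
contribute nothing to that row.

## Group statistics

One-way ANOVA (between/within decomposition) and Tukey HSD at α = 0.05 with
the Tukey–Kramer rule for unequal n, applied per band to relative areas and
centers; two-group comparisons stay under the Tukey interface for uniform
reporting.  Compact letters come from a greedy clique cover of the
"not significantly different" graph in descending-mean order.  Cross-group
band pairing uses a 10 cm⁻¹ tolerance (1588↔1581 and 1639↔1635 pair up;
1565 stays FM-unique).  No multiplicity correction is applied across bands
— each band is tested marginally, a known limitation.  All-identical
observations return F = 0, p = 1 by convention.

## Degenerate inputs and tie-breaks

All-zero spectra, constant responses, single-sample centering, empty
validation sets, single-class ROC inputs and zero prepared signals raise
typed errors rather than producing numbers.  ŷ exactly at the threshold
classifies as LC.  OSC weight signs are fixed (largest component positive)
for bit-reproducibility.

## Problem sizes

Default study: 50 + 50 spectra, 80/20 stratified split, LOOCV over the 80
training samples with full per-fold refits; deconvolution cohorts of 40
samples per class.  The whole suite, including a 1000-replicate Tukey
family-wise-error calibration and full end-to-end determinism checks, runs
in a few minutes on one CPU.

## Known limitations

* Band shapes are Gaussian by construction and by fit; Lorentzian/Voigt
  profiles are out of scope.
* The absorbance-domain reading of the deconvolution target ("fit the
  absorbance spectrum directly, seeded by derivative peaks") is not
  implemented; with broadband background leaking into the window it
  performed worse than the derivative-domain matched fit.
* HC area dispersions beyond the 1545 band are extrapolated from the LC
  pattern; only the 1545 mean share is constrained by the consensus table.
* Synthetic separability is, by design, consistent with the published
  headline metrics; it is not evidence about real patients.
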