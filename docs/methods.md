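# Methods

## Mass model

Peptide masses are sums of water-subtracted residue masses plus one water
(18.01528 Da average, 18.01056 Da monoisotopic). Two scales are carried in
parallel and chosen explicitly at every call: **average** masses drive all
intact-peptide work, because unit-resolution centroids track the envelope
centroid rather than any single isotopologue, and **monoisotopic** masses
drive fragment annotation, where a high-resolution Q-TOF resolves isotopes.
The residue tables are standard 20-residue reference values to five
decimals; non-canonical residues and terminal chemical groups other than
free termini are out of scope.

A modification is a signed mass delta with a maximum occurrence count and
optional residue targets. A *modification state* applies a multiset of
deltas to a peptide; its expected average mass is the peptide mass plus the
applied deltas. State enumeration always yields the unmodified and fully
modified endpoints; intermediate occupancies are generated only for deltas
whose individual shift is at least 15 Da in magnitude — smaller shifts
(e.g. the −2 Da of thioether formation) are not separable from their
neighbours at unit resolution, so enumerating their partial states would
double-count the same extracted signal. Sub-threshold deltas therefore
toggle all-or-none.

m/z construction uses (M + z·1.00728)/z. The charge-ladder formulas below
are the one deliberate exception.

## Charge-ladder deconvolution

Five consecutive charge-state peaks m₁ < … < m₅ of one species are reduced
to a neutral mass. Each adjacent pair gives a charge estimate for its
lower-m/z member, zᵢ = (mᵢ₊₁ − 1)/(mᵢ₊₁ − mᵢ); each is offset by the
proton-count difference to peak 5, and the four z₅ estimates are averaged
and rounded (half away from zero; the procedure is silent on ties).
Charges z₅+4 … z₅ are then reassigned and each peak contributes a mass
z·m − z·1. These formulas subtract a bare 1 per proton; they are kept
verbatim so results match the established procedure, which makes the
reconstructed mean overshoot the true mass by mean(z) × 0.00728 Da and
leaves a small charge-dependent residue in the sample standard deviation.
A `physical_proton=True` flag substitutes 1.00728 throughout for users who
prefer the physical convention.

The reported uncertainty is max(sample SD over the five masses, σ·z₁),
where σ is the stored instrument constant (QQQ 0.3, QTOF 0.026 — the
stored QTOF value is used as printed even though FWHM/2.3548 = 0.0255).
Scaling by the largest charge converts single-peak m/z width into neutral-
mass uncertainty.

Ladder *selection* from a crowded spectrum is the caller's job; the
`select_ladder` helper (five-peak windows ranked by intensity, accepted
when their pair estimates agree with one consecutive assignment) is a
convenience heuristic beyond the core procedure.

## Extraction and quantification

MS1 centroids are read from mzXML with a per-peak intensity floor of 1,000
(the vendor-export setting; whether the original floor applied per peak or
per scan maximum is unknowable from the converted files, and per-peak is
the conservative reading) and filtered to 1–6 min and 500–2,500 Da, both
intervals closed. Each modification state is extracted as one EIC per
charge state inside the instrument scan range (QQQ 500–2,000 m/z, QTOF
100–3,200 m/z) with window ±2/z Da (QQQ) or ±1/z Da (QTOF); the ECC is the
pointwise sum of the EICs, an identity the code asserts rather than
approximates.

The ECC peak is fit by nonlinear least squares to
baseline + area · skewnorm(t; location, scale, shape) — the skew-normal is
the concrete "skewed Gaussian", with area the density mass in
intensity·min, excluding the fitted flat baseline. Initialization is
deterministic (location at the maximum, scale from the half-height width,
zero skew, baseline at the minimum), so no seeds are involved in fitting.
All-zero traces return a non-converged zero-area fit.

A fitted peak is accepted only if: more than eight charge states (read
literally as ≥ 9; the boundary is configurable since "greater than eight"
is ambiguous) show EIC signal above a floor (default: any strictly
positive intensity, post ingest-threshold) within ±0.2 min of the fitted
retention time, at least four of them consecutive; the ECC has no other
local maximum above 80% of its tallest and at most two others above 40%
(maxima found on a 3-point moving mean with a 5%-of-max prominence floor,
excluding the maximum nearest the fitted peak — the candidate itself;
counting on the raw-smoothed trace rather than on fit residuals is a
documented choice); fitted skew lies in [0, 1.5]; and fitted width (the
scale parameter, minutes) is ≤ 0.25. Fraction modified is the valid
modified-state area over the summed valid areas of all states; the label
set counted as "modified" is configurable so that, e.g., mono- and
di-phosphorylated states can be pooled as product. States are fitted
independently; overlapping species are not jointly deconvolved.

## MS/MS annotation

Spectra are preprocessed by (1) capping intensities at a user multiplier
times the spectrum mean and (2) slicing the m/z range into equal windows
and removing peaks strictly below snr × the mean intensity over the slice
and its existing neighbours (edge slices average over existing neighbours
only). Hypothetical ions of a structure — sequence, residue-localized
monoisotopic deltas, and crosslink spans — are the b/y series plus parent:
b_k is the residue-mass sum of the first k residues (plus retained
deltas), y_k the last k residues plus water, each at charges 1–3 with
m/z = (formula + z·1.00728)/z. Localizing deltas to residues is an
interpretation (fragments then carry exactly the deltas of residues they
retain); it is required for fragments to be informative about
modification position. Cleavage sites strictly inside a crosslink span
emit no ions — both pieces of a ring-internal backbone break remain
tethered — rather than ring-opened masses; consistent with observed
fragmentation occurring between, not within, macrocyclic repeats. Matching
takes, per ion, the nearest peak within tolerance (ties to the lower m/z);
peaks may be shared between ions, since a 2+ fragment and a lighter 1+
fragment can legitimately coincide. Coverage is the fraction of cleavage
sites with at least one generated hypothetical ion that are supported by a
match.

## Synthetic data generator

The generator emulates the statistical structure of the study conditions:
2–20 kDa fusion peptides electrosprayed into 500–2,500 m/z centroid
streams, eluting over a 1–6 min window. Each species contributes, at every
scan, one centroid per charge state at the average-mass m/z, with
intensity = abundance × (discretized-Gaussian charge-envelope weight,
normalized to sum 1) × (skew-normal elution density at the scan time), so
the integrated compound signal equals the specified abundance exactly and
the true fraction modified is an abundance ratio. Noise is a Poisson
number of peaks per scan, uniform in m/z over the scan range, with
exponential intensities. Scan intervals default to 0.3 s (QQQ) and 0.25 s
(QTOF). One centroid per charge (no isotope structure) is what a
unit-resolution centroid stream supports and keeps the ECC arithmetic
exact; an optional isotope mode adds 1.00235/z-spaced satellites for
Q-TOF-like data. All generators are deterministic given their seed.

The reference two-species run (`standard_two_state_run`) co-elutes an
unmodified and a singly dehydrated ~7.9 kDa fusion at 3.2 min (width
0.08 min, skew 1.0) with total abundance 2×10⁷ and noise (5 peaks/scan,
mean 2×10⁴), giving apex signal-to-noise well above 20 and twelve charge
states in range — the regime in which the validity rules are designed to
pass. MS/MS simulation emits each hypothetical ion with a set efficiency
at log-normal intensity (median 5,000, log-sd 0.5), jittered by
N(0, 0.005) m/z, over a floor of exponential noise peaks (mean 20):
fragment peaks of an abundant purified peptide sit orders of magnitude
above chemical noise, which is what makes a slice-mean × snr threshold a
meaningful separator. What the generator does **not** model — isotope fine
structure (by default), chromatographic drift and tailing beyond the
skew-normal, in-source fragmentation, correlated chemical noise, detector
saturation — means that passing recovery tests demonstrate correctness of
the pipeline's arithmetic and decision rules under its stated model, not
robustness to every artifact of real instrument data.

## Problem sizes and numerical choices

Recovery suites use the reference run above (≈ 1,000 scans, two species,
12 charge states each): fraction-modified recovery is checked at
f ∈ {0.1, 0.25, 0.5, 0.75, 0.9} × 4 seeds with |f̂ − f| ≤ 0.05, and MS/MS
annotation over 20 seeds at ≥ 95% of injected ions matched within
0.05 m/z. Deconvolution round-trips cover 2–50 kDa × z₅ ∈ {1, 5, 10, 20}
noiselessly and, with ±0.1 m/z uniform noise, the z₅ ≥ 5 / ≤ 20 kDa
subgrid where pair spacings remain wide relative to the noise. Peak fits
use `scipy.optimize.least_squares` with bounds (area ≥ 0, scale ≥ 10⁻⁴
min, |shape| ≤ 20, baseline ∈ [0, max]) and xtol = ftol = 10⁻¹⁰.

## Known limitations

- No cross-run alignment, normalization, or isotope-resolved
  quantification; each extract is quantified independently.
- Co-eluting states closer than ~15 Da share EIC windows at high charge
  and are not deconvolved from one another.
- The MS/MS module annotates a single supplied structure; it does not
  score alternative delta placements or perform de novo sequencing.
- mzXML is the only instrument format read; MS/MS spectra enter as plain
  peak lists (TSV/MGF), not extracted from mzXML.
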