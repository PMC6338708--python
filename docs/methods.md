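# Methods

This note documents the models, numerical choices and limitations behind
`edcscreen`: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Formula arithmetic and isotope patterns

Isotope masses and natural abundances are pinned to a published
(CIAAW/NIST-style) table shipped as package data
(`src/edcscreen/data/isotopes.csv`; H, C, N, O, F, Na, P, S, Cl, K, Br, I).
Pinning the constants makes every derived m/z reproducible to the printed
4 decimal places. The monoisotopic mass is the sum of most-abundant-isotope
masses — the convention behind every printed quantifier m/z. Charge
bookkeeping uses the proton mass (1.00727646 Da = H atom minus electron):
[M−H]− = M − m_p, [M+H]+ = M + m_p; radical anions ([M]−) add one electron
mass. Only singly charged species are modelled.

Isotope patterns are computed by element-wise convolution of per-element
isotopologue distributions, using binary exponentiation so large atom
counts stay cheap. Channels whose masses differ by less than half the
0.005-Da extraction window (merge tolerance 0.0025 Da, configurable) are
merged abundance-weighted — the pattern is what a narrow-window XIC can
actually resolve, not the fine structure. Probabilities below 1e-12 are
pruned during convolution; reported patterns prune below 0.5 % of the base
channel and normalize the base to exactly 100. The convolution is verified
in the tests against an independent exhaustive isotopologue enumeration:
channel-exact for few polyisotopic atoms, and as total abundance per
nominal M+k bin for larger formulas, where stepwise versus end merging may
split borderline channels differently (the physical content — what a
0.005-Da window sees per nominal mass — is identical).

The "within 5 %" isotope criterion is interpreted as ≤ 5 absolute
percentage points on the base-100 scale; a per-channel relative mode is
available as a configuration switch, since the wording is ambiguous.
Sulfate conjugates are constructed as parent + SO3; this choice reproduces
the printed conjugate m/z (220.9681) even where a published formula
(C7H7ClO5S) disagrees with its own printed mass.

## Spectra, XICs and peak detection

A run is a retention-time-ordered list of centroid spectra, each tagged
`low` (full-scan precursor) or `high` (broadband CID fragment) energy.
mzML is read through pyteomics (MS1 → low, all-ion fragmentation → high);
synthetic runs use a plain-text fixture dialect (JSON header + CSV of
`rt,channel,mz,intensity` rows) whose floats are serialized with `repr`,
so write→read round-trips bit-exactly.

XIC extraction sums all centroid intensities within ±window/2 of the
target m/z per scan ("0.005-Da mass-window width" is the full width); the
sum, rather than the maximum, is robust to split centroids. Peak detection
smooths the trace with a 5-scan second-order Savitzky–Golay filter for
apex finding only; height and trapezoidal area always come from the raw
trace. Neighbouring smoothed maxima separated by a valley above half the
lower apex are treated as one noisy peak. Peak boundaries are the nearer
of the valley minimum toward an adjacent detected peak and the point where
the smoothed trace falls to 1 % of the apex; with noise-free data this is
exactly the first-local-minimum-or-1 % rule, and with noisy data it avoids
truncating peaks at chance wiggles on the flanks. Noise is 1.4826 × the
median absolute deviation of the peak-free trace (the Gaussian-consistent
scale), and S/N = raw apex height / noise. Candidate peaks are screened
against a whole-trace MAD estimate first, then re-scored against the
peak-free noise; anything below the S/N threshold (default 3) is dropped.
On a sparse centroided baseline a narrow window may contain no noise at
all, in which case S/N is reported as infinite — vendor software shows the
same behaviour on clean regions.

## Identification and confidence levels

Screening one suspect follows a fixed chain: theoretical adduct m/z →
0.005-Da XIC (low channel) → peak detection → best peak (highest apex,
ties by S/N then earlier retention time). Mass accuracy is evaluated on
the intensity-weighted mean in-window centroid m/z of the apex scan.
Isotope evidence reads companion XICs at every predicted channel m/z at
the apex scan only — a deliberate simplification (single-scan, not
area-integrated) that keeps the measurement local and testable. Fragment
evidence requires a high-energy peak at each qualifier m/z whose apex
co-elutes within 0.05 min. The retention-order rule (metabolite strictly
before parent) applies only when a parent is named and detected.

Defaults: 10 ppm mass error, 5 points isotope deviation, ±0.2 min to a
reference retention time (the protocol states none; this is a common
audit value), ±30 % relative ion-ratio tolerance (the customary
EU-guideline value; also not printed), S/N ≥ 3. Any failed applicable
criterion yields "not-detected"; otherwise the reference type decides the
level: commercial standard → 1a, in-vitro synthesised → 1b, none → 2.
Compounds with limited fragmentation simply leave the fragment criterion
not-applicable; identification then rests on the isotope pattern, which
for polyhalogenated compounds is highly distinctive.

## Quantification and validation arithmetic

Calibration fits mean analyte/IS area ratio against concentration by
ordinary least squares. The linear range is selected deterministically:
while R² < 0.99 and more than 5 levels remain, drop whichever extreme
level (lowest or highest) improves R² more. Unweighted OLS is the default;
1/x weighting is available and recommended when a single top level would
otherwise dominate a four-decade range with multiplicative noise.

IDL is the concentration at S/N = 3 from a straight line through the S/N
of the two lowest measured levels; the S/N = 10 point gives the IQL, which
is additionally floored at the lowest linear-range level with < 20 % RSD.
Method limits are ML = IL / F / RC (reported in ng/L; F defaults to 400 =
100 mL → 0.25 mL SPE; solid samples need a user-supplied factor), and a
calculated MQL below the lowest calibration level is raised to that
level's method-scale equivalent. Report rounding uses one decimal place
when that still resolves the value (≥ 0.1), two otherwise; raw values are
always retained. Corrected recoveries may exceed 100 % (matrix
enhancement) and are reported as-is, never clamped. Accuracy is the grand
mean as a percentage of nominal; intra-day precision is the mean of
within-day %RSDs, inter-day precision the %RSD of day means. Sample
concentrations are back-calculated through the curve, divided by the
concentration factor, and flagged against the MDL/MQL.

## Synthetic data generator

The generator emulates centroided dual-energy acquisition of a
reverse-phase gradient: alternating low/high-energy scans (default 0.5-s
cycle over a 20-min window; studies use narrower grids around the planted
peaks to stay small), Gaussian elution profiles, full isotopologue
envelopes in the low channel, fragments only in the high channel, ppm-scale
mass jitter (default σ = 2 ppm, comfortably inside the 10-ppm criterion),
and a sparse exponential baseline. Intensity variability (default CV 5 %)
is applied as a common lognormal factor per compound per scan — modelling
electrospray fluctuation — plus an independent per-centroid term at a
quarter of the CV for ion statistics. The split matters: fully independent
per-centroid noise of 5 % would make single-scan isotopologue *ratios*
fluctuate by ~7 %, which is both unlike real ESI data (channel intensities
within a scan are strongly correlated) and incompatible with a 5-point
isotope criterion.

Validation studies are generated as complete run sets — calibration series
(the standard 13 levels, 0.01–100 µg/L, configurable), matrix blanks,
pre-extraction spikes at 100 and 200 ng/L scaled by the planted truth
recovery, and a replicate/day structure with planted intra-day (5 %) and
inter-day (3 %) CVs — together with a manifest recording every truth
value. Everything is reproducible from one integer seed; fixture files are
byte-identical across runs with equal seeds.

Not emulated: peak tailing/fronting, retention drift between runs, ion
suppression beyond a scalar recovery, detector saturation, profile-mode
data, charge states above 1. Passing tests therefore demonstrate the
correctness of the arithmetic and the criteria logic under idealised
chromatography, not robustness to pathological real-world peak shapes.

## Problem sizes and numerical notes

Tests and examples use scan grids of roughly 70–270 cycles and studies of
~70 runs with one analyte plus an internal standard; statistical
assertions on planted truths use replicate means (3–15 measurements) with
tolerances of ±5 points (recovery), ±5 % (concentration at S/N > 50) and
±3 points (intra-day CV), each about 2–3 standard errors under the planted
CVs. Degenerate inputs are defined errors, not silent results: empty
formulas, non-positive theoretical m/z, zero internal-standard area,
fewer than 5 calibration levels, fewer than 10 peak-free scans for noise
estimation, all-S/N-below-1 analytes. Ties in best-peak selection resolve
deterministically (height, then S/N, then earlier retention time), and all
reports are deterministic given fixed inputs and seed.
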