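# Methods

## Scope and model

`isocalc` implements the desk calculations of a stable-isotope tracing
experiment for unit-resolution mass spectrometry: isotopologue channel
generation (SIM and MRM), natural-isotope and tracer-purity correction of
mass isotopologue distribution vectors (MDVs), fractional labeling, and
flux split ratios at the glucose-6-phosphate branch point.

The central object is the correction matrix **CM** linking the true
labeling distribution of a fragment ion to what the instrument observes:

    MDVraw = CM · MDVcorr

For an ion with *n* tracer-labelable positions measured over
*n* + 1 + *e* channels, CM is an (*n*+1+*e*) × (*n*+1) lower-band matrix.
Column *j* is the natural mass-shift distribution of the ion formula with
*j* tracer-element atoms removed, placed starting at row *j*: the *j*
labeled positions are isotopically fixed and carry no natural variation,
while every remaining atom — including tracer-element atoms outside the
labelable backbone, such as the many carbons of a TBDMS derivatization
group — keeps its natural spread. This treatment of non-backbone
tracer-element atoms is what makes heavily derivatized GC–MS fragments
correct properly.

## Isotope convolution and binning

Natural mass-shift distributions are computed per element by repeated
self-convolution (exponentiation by squaring) of the single-atom shift
vector, then convolved across elements. All isotopes are binned by
integer nominal shift — one ¹⁸O and two ¹³C both land in M+2 — the
appropriate convention for quadrupole-resolution data where
element-specific fine structure is not resolved. Truncation to a
requested maximum shift is exact for the retained entries because the
convolution is lower-triangular in the shift index; a guard band of two
shifts is kept in the workspace. Isotope fine structure and
resolution-dependent binning are out of scope.

The default abundance table uses the values the package's reference
calculations are stated in (¹³C 1.07%, ²H 0.01%, ¹⁷O 0.04%, ¹⁸O 0.21%,
¹⁵N 0.36%, ²⁹Si 4.69%, ³⁰Si 3.09%, ³³S 0.75%, ³⁴S 4.25%), with the
lightest isotope taking the complement so every element sums to exactly 1.
Published tables differ in the third decimal; a CSV override
(`element,shift,exact_mass,abundance`) substitutes e.g. full-precision
IUPAC values. Exact isotope masses are CODATA/IUPAC monoisotopic values;
ion m/z includes the electron mass (0.000549 Da per charge), and a
nominal mode rounds m/z to integers for unit-resolution method export.

## Channel generation

SIM: an ion with *n* tracer positions gets channels M+0..M+(n+e), channel
*i* at monoisotopic m/z + *i*·Δm/|z| with Δm the tracer exact mass
difference. The *e* extra channels above M+n (default 3) capture natural
heavy isotopes riding on fully labeled species; omitting them biases the
correction of highly labeled samples. Spacing above M+n also uses Δm: at
unit resolution all +1 shifts are indistinguishable and this keeps the
list monotone.

MRM: for a precursor with *n* and a product with *m* retained tracer
positions, the tracer-consistent transitions are the pairs (i, j) with
0 ≤ i ≤ n and max(0, i−(n−m)) ≤ j ≤ min(i, m) — exactly
(m+1)(n−m+1) transitions, verified against exhaustive label-placement
enumeration. With extras the bounds widen to i ≤ n+e, j ≤ m+e,
i−j ≤ (n−m)+e and out-of-core pairs are flagged, reducing to the
tracer-consistent set at e = 0. How extra natural channels should combine
with transitions is a genuine design choice; the flag lets users filter
to any stricter convention.

## Correction

Raw areas are clipped at zero (negative integrals are integration
artifacts, logged), normalized to MDVraw, and the linear system is solved:
exact `solve` for square CM, unconstrained least squares when extra rows
are present (its natural generalization; a non-negativity-constrained
NNLS solver is available behind a flag). Corrected entries in
(−tolerance, 0) are numerical noise and are clipped; entries ≤ −tolerance
(default 1e-3) indicate model misfit — wrong formula, co-eluting peak —
and are flagged in the diagnostics while the record is kept. The output
is renormalized to the simplex.

Tracer purity α is corrected after natural-isotope correction
(keeping the two corrections composable) as
MDVlabeled = (MDVmeas − (1−α)·MDVnatural)/α, with MDVnatural defaulting
to the unit vector at M+0 — the natural state in corrected space. Passing
the theoretical natural MDV instead applies the formula pre-correction.

## Fractional labeling and split ratios

Fractional labeling is Σᵢ i·[M+i]/n over the corrected MDV — the mean
fraction of labelable positions carrying label.

Split ratios use [1-¹³C]glucose. Per unit of glucose flux: glycolysis
(EMP, fraction X) yields one unlabeled and one C3-labeled triose unit;
the oxidative PP pathway (Y) loses C1 as CO₂ and yields 5/3 unlabeled
units; the ED pathway (Z) yields one unlabeled and one C1-labeled unit.
For a fragment containing backbone carbons 1–3 of a three-carbon
intermediate, [M+0]:[M+1] = (X + 5/3·Y + Z):(X + Z); for a carbons-2–3
fragment, (X + 5/3·Y + 2Z):X, since the C1 label is outside it. The
two-pathway case (Z = 0) has closed form X = (5/3)/([M+0]/[M+1] + 2/3);
the three-pathway case solves the 3×3 linear system in cross-multiplied
form (scale-invariant, no renormalization over the first two channels).

An alternative printed convention exchanges the fragment roles in the
three-pathway system; it violates subset consistency (a molecule labeled
within carbons 2–3 is necessarily labeled within 1–3, yet that assignment
gives the smaller fragment the larger M+1 coefficient), so the
atom-mapping-consistent form above is the default and `as_printed=True`
provides the variant. Solutions outside [0,1] are clamped onto the
simplex and flagged, with the unclamped values retained; float overshoot
below 1e-9 is snapped without flagging. Two all-M+0 fragments carry no
pathway information and raise.

Pyruvate, alanine and lactate labeling should not be used for the
mammalian split ratio: unlabeled glutamine-derived carbon dilutes their
pools. 3PG or PEP fragments containing all three backbone carbons are the
appropriate inputs.

## Synthetic data

The simulator inverts the correction: areas = intensity · (CM · MDVtrue)
⊙ exp(σ·ε), ε i.i.d. standard normal. Multiplicative log-normal noise is
chosen over additive Gaussian because peak areas are positive with
roughly constant relative error; σ is the log-scale standard deviation,
default 0.01 (1% channel noise, a realistic figure for well-integrated
peaks), intensity default 1e6 counts. The documented study scenario is a
factorial layout of 2 cell lines × 4 tracer conditions × 3 replicates
over 14 metabolite targets (336 records). True MDVs may be explicit
vectors, binomial (independent labeling at a given enrichment), or
split-ratio-generated patterns.

What the simulator does *not* emulate: chromatographic peak shape and
integration error, retention-time drift, detector saturation, co-eluting
interferences, and isotopic non-stationarity. Passing recovery tests
therefore demonstrates the correctness of the algebra and its numerical
robustness to channel-level noise, not robustness to peak-picking
artifacts in real chromatograms.

## Numerical choices and limitations

- Convolution truncation: exact (see above); full distributions sum to 1
  within 1e-9.
- Correction clip tolerance 1e-3 (configurable); MDV normalization
  tolerance 1e-6.
- Singularity guards: zero diagonal for square CM; condition number >
  1e12 for the split-ratio system.
- Channel labels are 0-based mass shifts rendered "M+0", "M+1", …
  everywhere; area CSVs must be contiguous from M+0.
- Test problem sizes: oracle equivalence over all ≤4-atom formulas,
  1,000 correction round trips across 20 random ions, 100-seed recovery
  sweeps — chosen to exercise every code path at desk scale.
- Out of scope: tandem-MS (precursor × product) correction matrices,
  high-resolution correction, vendor method formats, peak integration,
  full ¹³C-MFA network fitting.
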