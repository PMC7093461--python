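# Methods

This note documents the models implemented in `lipidraft`, the defaults they
ship with and why, what the synthetic-data generator does and does not
emulate, and the numerical choices that make the pipeline deterministic.

## Identification

**Accurate-mass search.** Candidates are library entries of the feature's
ion mode within a relative precursor tolerance, default 10 ppm — typical
precursor accuracy for the QTOF instrument class this workflow targets.  The
tolerance is configurable (`ScoringParams.precursor_tol_ppm`); mass error is
reported signed in ppm relative to the library precursor.

**Reverse dot-product similarity.** The score runs over the *library*
fragments only: experimental peaks not within the fragment tolerance
(default 0.02 Da absolute, product-ion accuracy on QTOF) of any library
fragment are ignored.  This is the standard "reverse" matching convention: a
clean subset match of the reference spectrum is not penalized for
contaminant or chimeric peaks.  When several experimental peaks fall within
tolerance of one library fragment their intensities are summed and their m/z
intensity-averaged — deterministic and robust to the choice of tolerance.
The weights default to m = 1 on m/z and n = 0.6 (positive mode) / 1.0
(negative mode) on intensity; all four numbers are configuration, not code.
Intensities are used as given: the score is invariant under uniform scaling
of either spectrum, so base-peak normalization would be a no-op.
The score is a cosine, hence in [0, 1] by Cauchy–Schwarz; a perfect match
returns exactly 1.0 (the identical-weight-vector case is returned as 1
directly, sidestepping a 1-ulp `sqrt` rounding), and a spectrum sharing no
fragments returns 0.

**Retention-time similarity.** A symmetric trapezoid in d = |RT_exp −
RT_pred|: score 1 for d ≤ a, linearly decreasing to 0 at d = b, 0 beyond.
The geometry of the published trapezoid is not fully specified by its
sources, so a and b are explicit parameters, defaulting to a = 0.15 min and
b = 0.5 min — a plateau comparable to inter-run RT reproducibility on a
20-min gradient and a cutoff well inside the spacing of co-eluting
subclasses.  Both are logged with every run.

**Acceptance.** Candidates with spectral score > 0.8 are retained; the best
of them (highest spectral score; ties broken by smaller |mass error|, then
species id) is accepted iff its RT score > 0.5.  At most one identification
per feature is accepted, mirroring how quantification tables are reported
per species; all scored candidates are written to the audit table so the
alternative ordering (RT filter before ranking) can be audited from the same
output.  Features without MS/MS are never identified — this pipeline does
not do MS1-only annotation.

## Quantification

Single-point internal-standard quantification assumes a response factor of 1
between an analyte and the deuterated standard of its subclass:
amount_µg = (area_analyte / area_IS) × spiked_µg.  Conversion to moles uses
the species' average molecular weight; where a library species does not
carry an explicit average mass it is approximated as monoisotopic × 1.0007,
an error of well under 0.1% — negligible against area noise.  Amounts are
normalized per µg protein per sample.  The spike panels default to the
12-standard raft/non-raft scheme (they differ only in the Cer and SM
levels); any subclass can be overridden per sample in the metadata file.

The cholesterol path supports an external calibration curve: ordinary least
squares of response ratio on concentration (scipy.stats.linregress; the
two-point case is solved exactly), inverse interpolation for unknowns, an
`out_of_range` flag when the *undiluted* interpolation exceeds the linear
maximum (the dilute-and-reanalyze rule), and ×dilution rescaling.  Below the
linear minimum the value is flagged but reported as-is — only the high end
has a reanalysis rule.  A subclass with no usable internal standard in a
sample yields records with NaN amounts and an explicit error message rather
than silently vanishing; a subclass with neither a spike nor a curve is a
configuration error.

## Composition and statistics

mol% is computed on mole amounts (pmol), not mass.  Subclasses quantified
anywhere in a data set contribute 0 (not missing) to samples where they are
absent, keeping compositional denominators comparable across replicates.
Chain-length/saturation profiles are mole-fraction histograms over total
acyl carbons and double bonds, restricted by default to the
glycerophospholipids (PC, PE, PS, PI, PG, PA) — the subclasses for which
tail-length comparisons between membrane fractions are meaningful.

Group comparison is a two-sided two-sample Student's t-test per subclass on
replicate mol% values, pooled variance by default ("Student's t-test"
conventionally denotes the equal-variance form; Welch is a flag).  The
degenerate zero-variance case is defined as t = 0, p = 1 for identical
means.  Significance tiers are `n.s.` (p ≥ 0.05), `*` (p < 0.05), `***`
(p < 0.001); no intermediate tier is defined, and no multiple-testing
correction is applied (a deliberate mirror of common practice in this
setting; note it in downstream reporting).

## NMR intensity ratios

Y(X) = [I(X)/I₀(X)] / [I(ref)/I₀(ref)] with reference residue 5 by default —
a highly flexible N-terminal residue whose ratio calibrates out
spectrometer gain and sample concentration (Y is exactly invariant under
uniform scaling of either condition).  Missing (unassignable) residues
propagate as missing.  A peak present in the reference condition but absent
in the perturbed one is *disappeared*: Y = 0 with an explicit flag,
distinct from missing — disappearance is maximal attenuation (membrane
binding), not absent data.  Z(X) = (Y − Y₀)/Y₀ is defined only where both
profiles are defined and Y₀ ≠ 0; region summaries (mean/min/count over
half-open residue intervals) ignore missing residues and report an empty
region as missing rather than raising.  No noise-floor thresholding is
applied to intensities by default.

## The synthetic-data generator

The generator emulates the study conditions end to end with known truth:

- **Library**: species across 12 subclasses on a homologous-series mass
  model (per-subclass base mass + 14.01565 Da per CH₂ − 2.01565 Da per
  double bond, anchored at reference species; cholesterol fixed at
  386.3549 Da).  Spectra are 4 fragments — a subclass-diagnostic ion, a
  precursor-derived neutral loss, two acyl ions — with seeded simplex
  intensities, kept ≥ 0.05 Da apart so noise-free self-matches are perfect.
  This fragment model is deliberately simple, not chemistry-accurate: the
  scoring math only needs distinguishable, collision-prone spectra.
  Predicted RT = subclass offset + 0.15·carbons − 0.35·double bonds
  (retention rising with chain length, falling with unsaturation).  Decoy
  entries use odd-carbon compositions never generated in samples; deuterated
  standards (d7, d9 for SM) carry their label mass shift.
- **Experiment**: 2 groups × 3 biological replicates.  The non-raft baseline
  mixture puts SM at 0.12 mol% and is otherwise dominated by PC/PE and
  cholesterol.  Raft samples multiply each subclass by its configured
  effect — SM ×6.25 (reproducing the 0.75 vs 0.12 mol% contrast),
  cholesterol ×2, acidic phospholipids ×0.4–0.8 — and tilt species weights
  within each subclass toward shorter, more saturated tails.  The effect
  table is mole-balanced against the baseline pools and each sample is
  rescaled to a fixed total lipid pool, so every configured effect equals
  the generated mol% ratio *exactly* at zero noise.  Areas are
  amount × MW × per-subclass response × log-normal(σ = 0.1); RT jitter is
  Gaussian (sd 0.05 min); fragment intensities get log-normal(σ = 0.2)
  noise plus 2 contaminant peaks; 10 unknown features sit > 50 ppm from
  every library precursor; spiked standards are never dropped.
- **NMR**: solution intensities high and flexible at the N-terminus,
  tapering toward the C-terminus; the in-cell condition applies a
  region-wise attenuation (proline-rich N-terminus ≈ 1, SNARE motif 0.5,
  residues 78–96 → 0, i.e. disappeared); cholesterol-up/-down scale the
  SNARE-motif attenuation ±30%.  The unassignable-residue set (eight
  N-terminal prolines plus T27 and S61) is a synthetic stand-in — the real
  assignment gaps are not reproduced, only their existence and geography.

All randomness flows from one root seed through fixed-offset child streams
(library, amounts, area noise, RT noise, fragment noise, unknowns, dropout,
NMR), so noise settings can change without changing the truth, and equal
seeds give bit-for-bit identical outputs including written files.

**What passing tests do not show.** The generator produces ideal features:
no co-elution or chimeric MS/MS, no isotope envelopes or in-source
fragments, no missing internal standards, no RT drift between runs, no
matrix-dependent response factors.  Recovery and significance results on
synthetic data therefore validate the *computations*, not instrument
behavior; on real data the precursor/fragment tolerances, the trapezoid
geometry and the response-factor assumption are the parameters to revisit.

## Problem sizes and determinism

Default test/demo scale is 5 species per subclass (56 real species, 78
library entries with standards and decoys), 6 samples, ~420 features — a
scale at which the full pipeline runs in about a second and the whole suite
in a few seconds, while still exercising every code path (decoys, unknowns,
both ion modes, all subclasses).  Null-rate and power checks use 100–1000
seeded replicates at the composition level.  All outputs are written with
shortest-round-trip float formatting and re-parsed with round-trip float
precision, which is what makes rerun-byte-identity and bitwise TSV
round-trips hold.

## Known limitations

- Singly charged adducts only; no isotope-pattern or multiply-charged
  handling.
- No target-decoy FDR estimation; decoys in the simulator are for measuring
  precision against ground truth, not for FDR control.
- One MS/MS spectrum per feature (the most intense acquisition); merging of
  repeated DDA spectra is out of scope.
- Single-point IS quantification assumes unit response factors; a per-species
  override exists but no multi-point per-species calibration except the
  cholesterol curve.
- The t-test applies no multiple-testing correction across subclasses.
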