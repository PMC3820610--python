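# Methods

## Scope and data model

The package processes direct-infusion (shotgun) lipidomics acquisitions:
profile-mode high-resolution survey spectra, typically recorded as two or
more multiplexed scan ranges per sample and polarity to improve ion
statistics. Identification is *targeted*: species are looked up, not
discovered, and the survey-scan resolution supports sum-composition
annotation only (class plus total chain carbons:double bonds, with a
hydroxyl count for sphingolipids) — chain-level isomers are deliberately
outside the data model. All tabular results are long-format text: one row
per acquisition × target, with accessory lipid features as columns, so that
filtering, grouping and QC are ordinary relational operations.

## Mass arithmetic

Monoisotopic masses come from a frozen table of IUPAC atomic masses
(≥ 9 significant digits) shipped in `chemistry.py`; ion m/z is

    m/z = (mass(M ± adduct) − z·mₑ) / |z|,

with the electron mass always applied (subtracted for cations, added for
anions). Only |z| = 1 is supported — singly charged adducts (+H, +NH₄, +Na,
−H, −CH₃) cover survey-scan lipidomics. Internal arithmetic is full double
precision; the conventional 5-decimal rounding is display-only. The tests
pin three 5-decimal reference ions and cross-check the whole path against
pyteomics as an independent oracle.

Isotopologue envelopes (M+0…M+k aggregated by nominal mass shift) are
computed by exact polynomial expansion over per-element isotope abundances
(¹³C 0.0107, ²H 0.000115, ¹⁵N 0.00364, ¹⁷O/¹⁸O 0.00038/0.00205, ³³S/³⁴S
0.0075/0.0425), implemented as truncated convolution with binary
exponentiation and verified against a symbolic (sympy) expansion.

## Lipid database

Each class is a generative template: a backbone composition, a chain count
and a chain model.

* Acyl classes (glycerophospholipids, glycerolipids, sterol esters): total
  chains of C index c and db index d contribute C_c H_(2c−2d) O_(2n) and each
  esterification loses one H₂O. Ether classes (PC O-, PE O-, LPC O-, LPA O-)
  replace one ester bond by an ether (−O, +H₂) — separate templates, not a
  modifier flag, so formula arithmetic stays uniform.
* Sphingoid classes (Cer, SM, HexCer, SHexCer): the merged long-chain base +
  N-acyl contributes C_c H_(2c+1−2d) N O_(oh+1), plus the class headgroup
  (phosphocholine, hexose, sulfohexose).

A chemical-sanity cap rejects d > ⌊c/2⌋ (configurable). Enumerated ranges in
the shipped config are chosen to cover brain-tissue lipidomes and the spike
mixture (3204 species over 22 classes); the inventory is config, validated
through m/z conformance values and formula identities (e.g. the +CH₂ / −H₂
mass ladders), not by matching any particular census. Internal standards are
ordinary species at their summed indices plus a free-text display label
("TAG 17:1/17:1/17:1" → TAG 51:3), so quantification can reference them by
label while extraction treats them like any other target.

## Lock-mass adjustment

Instrument calibration drifts over an infusion series; the package estimates
a per-acquisition (and per scan range) offset from lock masses — ubiquitous
ions of known composition, e.g. a spiked standard and the
tris(ditert-butylphenyl) phosphate chemical-background ion in positive mode.
Per lock: apex bin within ±0.01 Da of the theoretical m/z (deliberately
wider than the identification tolerance, so locks are found even when the
drift exceeds it), three-point quadratic interpolation of the apex and its
neighbours (general non-uniform-spacing parabola vertex; a non-negative
curvature is "no apex"), offset = centroid − theoretical. The combined
offset is the unweighted mean in Da of the detected locks; undetected locks
are recorded as missing data, never errors — a missing internal-standard
lock is precisely the QC signal for an unspiked sample. Lipid targets are
*not* centroided: the m/z bin of the window maximum is reported, preserving
the asymmetry between lock-mass estimation (centroided) and target readout
(binned).

## Targeted extraction

The offset is applied to theoretical m/z values (shifting search targets
toward the instrument), never to measured data. For each target the window
is adjusted m/z ± tolerance, closed on both ends; default tolerance 0.0020 Da,
matched to ~100,000 fwhm resolution. Reported per target: maximum intensity
in the window, its m/z bin (ties → lowest m/z), a trapezoidal peak area over
the window (the simplest defensible area definition; the quantity is carried
as an attribute, not used by quantification), and Δm/z against the adjusted
value. A row is emitted for every target even with no bins in the window
(intensity 0, missing m/z): downstream blank subtraction and QC need dense,
aligned tables, and an explicit zero is information. Scan ranges are never
merged; the unifier concatenates per-range tables and adds `rangeID`.

## Quantification

Processing order (configurable, this default documented): sample-info join →
intensity filter (strict `<` removal, so threshold 0 removes nothing) →
blank subtraction → isotope correction → amounts.

Blank subtraction operates per (species, adduct, rangeID):
corrected = max(0, intensity − mean blank intensity). Internal-standard and
lock-mass rows are exempt, because blanks are spiked with the same standard
mixture as samples — subtracting the blank IS signal would annihilate every
denominator of the amount equation. Isotope correction mode `type2` divides
by the M+0 fraction (restoring total species signal from its monoisotopic
peak); `none` is the identity and the default, matching data whose
intensities already represent the monoisotopic peak.

Amounts use one internal standard per class (classes may share a standard
via explicit duplicate mappings, as for the lyso classes):

    amount_fmol = corrected_intensity / IS_corrected_intensity × spike_pmol × 1000.

Spikes are pmol (the convention of spike mixtures), amounts fmol. A zero or
missing IS denominator yields *missing* amounts — the acquisition cannot be
quantified, but its rows are retained. mol% is computed within grouping
cells (typically per acquisition) over a caller-chosen universe, defaulting
to endogenous, quantified, non-blank rows; per-cell mol% sums to 100 when
the denominator is positive. Technical replicates are never averaged before
amount computation; averaging is a display-time choice.

## Synthetic data generator

The generator emulates the acquisition series the package is designed for:
by default 12 tissue samples (3 brain regions × 2 genotypes × 2 animals)
plus 2 blanks, 2 technical replicates per polarity (56 acquisitions),
positive-mode ranges m/z 280–580 and 500–1200, negative-mode 370–660 and
550–1700 — 112 averaged peak lists in 4 folders of 28. Peaks are Gaussian
profiles on a fixed 0.0005 Da grid with σ = m/z / (100 000 × 2.3548)
(≈100,000 fwhm); apex intensity is proportional to planted amount
(10⁴ counts/pmol); per-acquisition true offsets follow a linear drift
(−0.002 → +0.002 Da) by default, or any constant/uniform/explicit series.
Noise is per-peak, per-scan multiplicative log-normal (default CV 0.05) plus
a uniform additive floor; setting the CV to zero gives the fully
deterministic variant. Three scans per range are averaged per acquisition
(enough to exercise the averaging path; the averaging oracle test separately
uses a 25-scan stack, the realistic per-acquisition count). One sample is
generated without internal standards (its two positive-mode injections are
07 and 08 in injection order) and a background ion colliding with the
PI 40:3 target is planted at equal intensity in samples and blanks.

What the generator does *not* emulate — and what passing recovery tests
therefore cannot show about real data: chemical noise beyond one planted
background ion, isotopologue peaks (intensities are monoisotopic-only, which
is why recovery runs with isotope correction `none`), peak-shape asymmetry,
ion suppression, and dense full-range baselines (profile points are kept
only within ±0.02 Da of planted ions; extraction semantics are unchanged
because a target with no bins in its window reports zero by design).

## Numerical choices and tolerances

* Offset recovery: apex bins are grid-quantised, so a planted offset is
  recoverable to half a grid step (2.5 × 10⁻⁴ Da at the 0.0005 Da default);
  the quadratic centroid itself contributes ≪ 10⁻⁵ Da for these peak widths.
* Noise-free end-to-end amount recovery is accurate to < 1%; the residual
  comes from grid quantisation attenuating species and standard apexes
  slightly differently.
* Noisy recovery is asserted on the mean and median absolute relative error
  (< 3 × CV): the amount is a ratio of two noisy intensities (CV ≈ 1.4×
  the per-peak CV), so a worst-case bound over hundreds of rows would be an
  order-statistics statement, not a recovery statement.
* "Zeroed by blank subtraction" in the deterministic study means a residual
  below 0.1% of the raw background intensity: with drifting calibration the
  grid sampling of the same peak differs slightly between acquisitions, so
  the subtraction leaves sub-permille residue rather than exact zeros.
* Degenerate inputs: flat centroid triplets raise ("no apex"); empty spectra
  raise in extraction; zero mol% denominators warn and yield missing values;
  offsets ≥ 1 Da are rejected as unit mistakes.

## Known limitations

Sum-composition only (no MS/MS, no chain-level identity); singly charged
ions only; no deconvolution of isobaric overlaps — an enumerated isomer
pair (e.g. diacyl PC vs a PE species of identical formula) is reported for
both targets, and distinguishing them needs tandem MS; no per-µg-protein
normalisation or statistical post-processing. mzML support is a minimal
built-in reader (uncompressed or zlib, 32/64-bit float arrays) aimed at
profile survey scans, not a general-purpose mzML implementation.
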