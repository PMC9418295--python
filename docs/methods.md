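# Methods

`atakit` implements the desk half of a transaminase-discovery workflow:
sequence-based function prediction for PLP fold-type I amine transaminases
(ATAs), conversion of photometric assay traces into activities, and analysis
of thermal and operational stability. Every analysis stage has a matching
synthetic-data generator with planted ground truth, so the whole pipeline is
testable without instrument output or curated alignments.

## Active-site fingerprints and trait rules

ATAs of fold type I can be compared position-by-position through a *unified*
numbering: a structure-based common residue numbering over the superfamily.
The **active-site fingerprint** is the residue tuple at seven unified
positions — 16, 47, 129, 145, 185, 346, 348. The bundled library
(`atakit/data/reference_library.tsv`, editable TSV) holds five characterized
reference fingerprints (e.g. the β-alanine:pyruvate subfamily parent
`MWYRGGN`, the highly active ATAs `FWYMARV` and `FWYNARL`) plus ten
investigated subfamily members.

The unified numbering is consumed, not recomputed: a `PositionMap` anchors
each unified position to an alignment column through a reference sequence
and an explicit anchor table (unified position → reference ungapped index).
Anchor drift is guarded by validating the reference's residues at the mapped
columns against its library fingerprint; disagreement raises a warning and is
recorded on the map rather than silently accepted.

Trait prediction is deliberately rule-based and transparent. Flags:

| flag | rule | reading |
|---|---|---|
| `flipping_arginine_346` | R@346 | dual substrate recognition of carboxylate co-substrates, the usual ATA hallmark |
| `carboxylate_R145` | R@145 | alternative carboxylate coordination used by the β-alanine:pyruvate subfamily |
| `distal_carboxylate_R16` | R@16 | remote arginine that can reach a distal carboxylate (ω-amino acids) |
| `high_amine_activity_motif` | (W∨Y)@47 ∧ (A∨G)@185 ∧ R@346 | the conserved pattern of highly active ATAs |
| `hydrophilic_185_low_activity` | (S∨T)@185 | hydrophilic 185 is detrimental to amine activity |
| `nonaromatic_47_reduced_activity` | 47 ∉ {W,Y,F} | loss of the conserved aromatic at 47 |

The residue classes ({W,Y,F} aromatic at 47; {S,T} hydrophilic at 185) are
fixed sets: they are the residues whose functional effect at those positions
is established; widening them would assert biology the rules cannot back. A
gap or `X` at a rule position makes that rule *undetermined*, never false.
Library comparison is a plain Hamming count with stable (library-order) tie
breaking; no significance model is attached to mismatch counts.

Percent identity depends on an often-unstated denominator, so the convention
is explicit and selectable: `both_ungapped` (default; identical pairs over
columns where both sequences are ungapped), `alignment_length`, or
`shorter_ungapped`. Values are reported to one decimal. Pairs with no shared
ungapped column are NaN, not zero.

## Assay kinetics

Volumetric activity comes from the initial-rate slope of a photometric trace:
ordinary least squares of absorbance vs time over a window (default: the full
10-minute trace). Two calibrations are bundled:

* acetophenone assay (245 nm): U/mL = slope[ΔAbs/min] · 60 / 5.23
* AlaDH/XTT coupled assay:     U/mL = slope[ΔAbs/min] · 60 / 12.64

The divisors are opaque instrument calibration constants (extinction
coefficient × path length bundled in); they are used verbatim. The ×60 with a
slope already per minute is dimensionally surprising — it suggests the
original instrument slope may have been per 30-s cycle — but the formulas are
implemented exactly as printed and the generator is their exact inverse, so
round trips are self-consistent regardless. Blank correction subtracts the
assay's designated control slope (minus-amine control for acetophenone,
minus-enzyme control for AlaDH); negative corrected slopes are clipped to
zero with a warning rather than reported as negative activity. Specific
activity is 1000·(U/mL)/(mg/mL) in mU/mg, flagged **ND** below the 4 mU/mg
detection floor. Relative-activity tables scale a substrate panel to a
reference substrate (exactly 100). An optional auto-trim drops trailing
points while R² < 0.98 to exclude depletion curvature; it is off by default
because the printed protocol fits the full window. No Michaelis–Menten
fitting is attempted.

## Stability and melting temperatures

Residual activity is 100·A(t)/A(t_first), referenced to the first *sample*
(the ~1 min initial measurement), not a t=0 extrapolation; interpolation
between samples is linear and extrapolation is refused. First-order
inactivation is fitted as least squares of ln(residual) vs time; k = −slope,
half-life ln 2/k; a non-decaying course reports k = 0 with infinite half-life
instead of a negative rate. `compare_conditions` pairs a resting and an
operating course at one time point (default workflow: 8 h at 40 °C) and
reports (RS%, OS%, RS−OS). Co-solvent panels are expressed relative to a
no-solvent reference at matching time.

Melting curves are two-state van't Hoff unfolding transitions:
f(T) = 1/(1+exp[(ΔH/R)(1/T − 1/Tm)]), T in kelvin (°C + 273.15 exactly),
mixed between linear folded/unfolded baselines. **Tm extraction** smooths the
ratio signal with a local polynomial (Savitzky–Golay, window ≈ 2 °C, order 2),
differentiates by central differences, takes the global derivative maximum
(ties toward lower temperature — single-transition assumption) and refines it
below grid resolution with a least-squares parabola over a ±2.5 °C window
around the peak (≈ a quarter of a typical transition width; a 3-point
parabola is markedly more noise-sensitive).

Two numerical choices deserve note:

* **Derivative space.** The two-state transition is symmetric in reciprocal
  absolute temperature, not in temperature: the peak of dR/dT sits below the
  true midpoint by ≈ R·Tm²·ln-term/ΔH — ~0.3 °C at ΔH 200 kJ/mol, negligible
  at 600. The default extractor therefore locates the peak of dR/d(1/T)
  (= −T²·dR/dT), which is exactly at the midpoint for the model and
  indistinguishable from the plain derivative for sharp transitions;
  `derivative_space="temperature"` reproduces the instrument-style
  convention.
* **Baselines.** With drifting baselines the derivative peak of the *total*
  signal is genuinely displaced (≤ ~0.05 °C at ΔH 400 with the default mild
  slopes); this is a property of the signal, not an extractor artifact. Flat
  baselines (`folded_slope = unfolded_slope = 0`) exist for analytic tests,
  where recovery is exact to well under half a grid step.

A direct sigmoid fit (`fit_tm_sigmoid`) is offered as an alternative Tm
definition; whether a given instrument reports derivative-peak or fitted
midpoint varies, and the derivative peak is the default because it is the
standard readout of scanning fluorimeters.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code and define the package's study
conditions:

* **Alignments** (`gen_alignment`): 15 sequences, 400 columns by default,
  with the library fingerprints planted. The reference is laid out so its
  ungapped numbering *is* the unified numbering (position p at index p−1),
  making the anchor table trivial by construction; shared insertion columns
  (reference gapped) and 2–6 random deletions per sequence (background
  columns only) exercise the mapping. Identity to the reference is
  controlled exactly (a fixed count of background substitutions), either one
  fraction for all sequences or per sequence id; identity between two
  non-reference sequences is emergent, not controlled — controlling all
  pairs simultaneously is over-constrained. Background columns are uniform
  random; there is no phylogenetic structure, substitution-matrix realism, or
  column-wise conservation gradient.
* **Traces** (`gen_trace`): exactly linear signal, slope = activity·factor/60
  (the inverse of the printed formulas), t = 0…10 min every 30 s (21 points),
  additive Gaussian noise (default sd 0.002 AU, a plate-reader-scale choice —
  replicate noise magnitudes are not published, so this is a package
  default, exposed in `SimConfig`). No substrate depletion, lag, or drift.
* **Melting curves** (`gen_melting_curve`): the two-state model above on a
  20–95 °C grid (default step 0.25 °C), additive Gaussian noise on the ratio.
  No aggregation/scattering artifacts, no multi-domain transitions.
* **Inactivation** (`gen_inactivation`): residual(t) = 100·e^(−kt) on an
  8-point schedule over 24 h; the first sample is the reference (exactly
  100%, noise-free); noisy residuals are floored at a small positive value so
  log-linear fitting stays defined. Real courses can show activation phases
  (activity increasing during incubation, as cofactor is taken up) and
  non-first-order decay; those are outside the model, and `fit_inactivation`
  will flag such courses as non-decaying rather than invent a rate.

Passing tests therefore demonstrate that the *analysis operations invert the
generating models at the stated noise levels* — parameter recovery. They do
not validate instrument calibration, real replicate scatter, or biological
conclusions. In particular, measured wet-lab quantities — specific-activity
and substrate-spectrum tables, solvent-tolerance panels, actual melting
points, synthesis conversions — are **not** reproducible at desk scale and
are *not* recomputed by this package; they enter only as planted parameters
whose recovery is checked through the synthetic route above.

## Problem sizes and tolerances

Defaults used by the test suite and the reproduction script: 15 × 400
alignments; 21-point traces, noiseless recovery asserted to <0.1% relative
and unbiasedness over 200 noisy seeds (within 2 standard errors); 301-point
melting grids, noiseless recovery within ±0.25 °C at ΔH 400 kJ/mol with
drifting baselines (≤ half a grid step with flat baselines) and replicate sd
≤ 0.5 °C over 100 seeds at 1%-of-amplitude noise; inactivation fits exact at
zero noise and unbiased over 200 noisy seeds. These sizes keep the full
suite in the tens of seconds while leaving each statistical check
well-powered.

## Known limitations

* The identity engine's default `both_ungapped` convention is a documented
  choice; published identity matrices rarely state their denominator, so
  values computed here may differ from printed ones by convention, not by
  bug. The alternatives are one keyword away.
* Trait rules are position-wise and independent; they do not model epistasis
  between active-site positions, and an undetermined position silently
  removes only the rules that need it.
* The fingerprint library asserts a schema, not a structure: sequences whose
  true structural alignment deviates from the reference anchoring will be
  misread, and no structural validation beyond the anchor-residue check is
  performed.
* No oligomeric-state prediction, no ΔG extraction from melting curves, and
  no sequence-based stability prediction are attempted.
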