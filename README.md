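# atakit

Sequence-based function prediction and biochemical characterization analysis
for **PLP fold-type I amine transaminases (ATAs)** — the enzymes that make
chiral amines by transferring an amino group from a donor amine to a ketone
or keto acid.

The package is for enzyme discoverers and biocatalysis groups who screen
transaminase candidates: it turns a reference-anchored multiple sequence
alignment into **active-site fingerprints** and rule-based activity
predictions, plate-reader traces into **activities**, and stability /
thermal-unfolding data into **inactivation rates and melting temperatures**.
A synthetic-data module generates every input with planted ground truth, so
the full pipeline runs and is testable with no external data.

## The science in brief

**Fingerprints.** Homologous fold-type I transaminases can be compared
residue-by-residue through a unified (structure-based) numbering. The residue
tuple at seven active-site positions — 16, 47, 129, 145, 185, 346, 348 — is
the enzyme's fingerprint; comparing it to characterized references predicts
function before any wet-lab work. Key rules: an arginine at 346 (the
"flipping arginine") enables the dual substrate recognition of typical ATAs;
the β-alanine:pyruvate subfamily (parent fingerprint `MWYRGGN`) uses R145
instead; W/Y at 47 together with A/G at 185 and R346 is the motif of highly
active ATAs (`FWYMARV`, `FWYNARL`), while hydrophilic S/T at 185 or a
non-aromatic residue at 47 marks reduced amine activity; R16 suggests
affinity for substrates with a distal carboxylate.

**Kinetics.** Volumetric activity comes from the blank-corrected
initial-rate slope of a photometric trace: U/mL = slope[ΔAbs/min]·60/5.23
(acetophenone assay, 245 nm) or ·60/12.64 (AlaDH/XTT coupled assay).
Specific activity is 1000·(U/mL)/(mg/mL), flagged ND below the 4 mU/mg
detection floor.

**Stability.** Residual activity relative to the first sample is tracked
under *resting* (storage buffer + PLP) vs *operating* (plus 200 mM
β-alanine / 20 mM cyclohexanone) conditions; first-order inactivation
k and half-life are fitted on the log scale. Melting temperatures are the
first-derivative peak of a two-state van't Hoff unfolding curve
(f(T) = 1/(1+exp[(ΔH/R)(1/T−1/Tm)]), 20–95 °C scan), with sub-grid
parabolic refinement. See `docs/methods.md` for models, assumptions and
numerical choices.

## Worked example

```python
import atakit as ak

# --- alignment -> fingerprint -> prediction -----------------------------
aln = ak.gen_alignment(ak.SimConfig(seed=7, target_identity={"TA-10": 0.391}))
pmap = ak.build_position_map(aln, "TA-3N5M", ak.default_anchors())
fp = ak.extract_fingerprint(aln, pmap, "TA-10")
pred = ak.predict_traits(fp, ak.load_library().subset(["reference"]))
print("fingerprint:", fp)
print("flags:", sorted(pred.flags))
print("identity to TA-3N5M:", ak.pairwise_identity(aln).value("TA-10", "TA-3N5M"))

# --- trace -> activity ---------------------------------------------------
trace = ak.gen_trace(0.6, ak.ACETOPHENONE, noise_sd=0.002, seed=7)
vol = ak.activity_from_slope(ak.fit_slope(trace).slope, ak.ACETOPHENONE)
print(ak.specific_activity(vol, protein_conc_mg_per_mL=0.5).specific_mU_per_mg)

# --- melting curve -> Tm, stability -> RS/OS gap ------------------------
curve = ak.gen_melting_curve(ak.MeltParams(midpoint_C=87.0), noise_sd=0.0016, seed=7)
print("Tm:", ak.compute_tm(curve).tm_C)
resting = ak.gen_inactivation(0.0, condition=ak.ConditionLabel(mode="resting"))
operating = ak.gen_inactivation(0.3, condition=ak.ConditionLabel(mode="operating"))
print(ak.compare_conditions(resting, operating, 8.0))
```

prints

```
fingerprint: MWYFARV
flags: ['flipping_arginine_346', 'high_amine_activity_motif']
identity to TA-3N5M: 39.1
1194.8...            # mU/mg, well above the 4 mU/mg ND floor
Tm: 87.16            # °C, recovered from the planted 87.0 °C midpoint
ConditionComparison(time_h=8.0, resting_pct=100.0, operating_pct=9.07...,
                    difference_pct=90.9...)
```

Reading: the planted `MWYFARV` fingerprint carries the flipping arginine and
the full high-amine-activity motif (W47 + A185 + R346) — the signature of a
highly active amine transaminase — at 39.1% global identity to the subfamily
parent; the 0.6 U/mL planted trace converts to ≈1200 mU/mg at 0.5 mg/mL; the
melting midpoint is recovered to within the scan's grid step; and the
stability comparison quantifies an enzyme that is fully stable in storage
but loses ~91% of its activity after 8 h under turnover conditions.

The same operations are available from a shell:

```bash
atakit simulate alignment --seed 7 --out aln.fasta
atakit fingerprint --aln aln.fasta --ref TA-3N5M
atakit identity --aln aln.fasta --convention both_ungapped
atakit simulate melt --midpoint 87 --out melt.csv && atakit tm --curve melt.csv
```

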