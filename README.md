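# bbbscreen

In-silico screening of small-molecule CNS PET tracer candidates for
blood–brain-barrier (BBB) permeability.

A successful brain PET tracer must cross the BBB, and only a small
fraction of small molecules do. Early, structure-only screens therefore
lean on physicochemical classifiers: rule-of-thumb property filters,
multiparameter-optimization (MPO) desirability scores, and closed-form
logBB regressions. `bbbscreen` implements these classifiers behind one
pipeline, together with the binary-classification statistics used to
compare them on labeled tracer cohorts (successful vs. unsuccessful
tracers) and a synthetic cohort generator so the whole stack is testable
without any external dataset.

## What is implemented

**Rules of thumb** (conjunctions of descriptor thresholds; registry ids in
parentheses): the CNS adaptation of Lipinski's rules — MW ≤ 400 g mol⁻¹,
ClogP ≤ 5, HBA ≤ 7, HBD ≤ 3 (`lipinski_cns`); van de Waterbeemd
(`waterbeemd`); Kelder PSA (`kelder`); Hitchcock–Pennington (`hitchcock`);
Manallack pKa limits (`manallack_pka`); the Ghose 2D guidelines (`ghose`);
and the Norinder–Haeberlein rules N+O ≤ 5 (`norinder_rule1`) and
ClogP − (N+O) > 0 (`norinder_rule2`).

**MPO desirability scores**: each of six descriptors (MW, ClogP,
ClogD₇.₄, TPSA, HBD, most-basic pKa) is mapped through a
piecewise-linear desirability function *T*(x) ∈ [0, 1] — monotonic
decreasing for most descriptors, a hump for TPSA — and summed:

    MPO = Σᵢ Tᵢ(xᵢ)  ∈ [0, 6]

`cns_mpo` classifies CNS+ at a total > 4; `cns_pet_mpo` uses tighter,
tracer-specific ranges and a threshold > 3. A five-descriptor BBB score
(aromatic rings, heavy atoms, MWHBN = HBN/MW^e, TPSA, pKa) is supported
with caller-supplied piecewise coefficients (`bbb_score`).

**logBB / logPS models**: logBB = log₁₀(C_brain/C_blood); the
Renkin–Crone relation PS = −F·ln(1 − K_in/F) with
K_in = (Q_br/C_pf)/T; four linear logBB regressions (`kansy_eq4`,
`clark_eq5`, `vilar_eq6`, `vilar_eq7`), the Vilar pair carrying CNS+/CNS−
semantics; and the composite CNS access score
log(PS·f_u,brain) + logBB with penetrance bands at −3.50 and −3.0
(`cns_access`, from precomputed vendor columns).

**Evaluation**: ACC, ER, Se, Sp, FNR, FPR, PPV, NPV, MCC and CCR from the
2×2 confusion table, with explicit flags instead of silent zeros when a
denominator vanishes — MCC and CCR matter because tracer cohorts are
heavily imbalanced (e.g. 109 successful vs. 20 unsuccessful).

## Worked example

```python
from bbbscreen import compute_profile, score_mpo, CNS_MPO, evaluate_rule

profile = compute_profile("CCN1CCC[C@H]1CNC(=O)c1cc(Cl)cc(Cl)c1OC")  # raclopride
print(evaluate_rule("norinder_rule1", profile).classification)  # Classification.CNS_PLUS
score = score_mpo(profile, CNS_MPO)
print(round(score.total, 2), score.classification)
```

prints `Classification.CNS_PLUS` (raclopride has N+O = 4 ≤ 5) and
`5.12 Classification.CNS_PLUS`: with RDKit descriptors raclopride loses a
little on ClogP/ClogD (≈ 3.2, just past the ≤ 3 desirable cutoff) and on
its single HBD, but stays well above the > 4 cutoff. No basic pKa is
computed by the open backend, so that component is imputed as 1.0 and
flagged in `score.flags`.

The end-to-end analysis lives in `analysis/` (generate cohorts → screen
rules → screen scores → summarize). On the default realistic synthetic
cohort (seed 0, 109/20) it prints, e.g.:

    cns_mpo      Se 1.00  Sp 1.00  MCC 1.00  CCR 1.00
    cns_pet_mpo  Se 0.99  Sp 1.00  MCC 0.97  CCR 1.00
    vilar_eq6    Se 0.04  Sp 0.95  MCC -0.02  CCR 0.49

i.e. the anchored MPO models separate the synthetic classes almost
perfectly (they define the generator's class structure), while the
stricter Vilar model 6 — which predicts logBB ≥ 0.3 — calls almost
everything CNS− at these descriptor means.

A CLI wraps the same pipeline:

```bash
bbbscreen generate --mode realistic --seed 0 --output cohort.csv
bbbscreen screen --input cohort.csv --models cns_mpo,lipinski_cns \
    --output screened.csv --metrics-json metrics.json
bbbscreen describe-models
```

Real descriptor tables (e.g. a published cohort with vendor-calculated
properties and precomputed CNS-access/logBB columns) load through
`load_dataset` with a user-supplied column map; precomputed
score columns are thresholded as-is and never silently recomputed.

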