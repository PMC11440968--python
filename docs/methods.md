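# Methods

## Scope and model

`bbbscreen` treats early BBB-permeability screening as a set of
descriptor-space classifiers applied to one per-compound vector (the
`DescriptorProfile`): molecular weight, computed lipophilicity (ClogP and
the pH 7.4 distribution coefficient ClogD₇.₄), topological polar surface
area, hydrogen-bond donor/acceptor counts, heteroatom counts, and
ionization constants. Three classifier families share this input:

1. **Threshold rules** — conjunctions of printed bounds
   (e.g. MW ≤ 400, N+O ≤ 5). A compound is CNS+ only if every evaluable
   criterion passes. Bounds follow the printed comparators exactly:
   `≤`/`<` as written, ranges like "ClogP 2–5" closed at both ends.
2. **MPO desirability scores** — each descriptor is transformed onto
   [0, 1] by a piecewise-linear desirability function and the six
   components are summed. Only the range endpoints and the function
   *types* (monotonic decreasing vs. hump) are fixed by the published
   models; linear interpolation between the desirable and undesirable
   bounds is adopted as the simplest function consistent with both types.
   Classification is strict (total > 4 for the CNS drug model, > 3 for
   the PET variant); a tie at the threshold is CNS−.
3. **Linear logBB regressions** — four published multiple-linear models
   applied with their central coefficients; the printed ±standard-error
   terms are not propagated, because the models are used as point
   predictors. The two Vilar models encode their own thresholds (output
   > 0 ⇒ logBB ≥ 0.3 and ≥ −1 respectively); the older two return raw
   logBB estimates thresholded explicitly by the caller (default
   logBB > 0 ⇒ CNS+, boundary to the negative class).

Vendor-model outputs (the CNS access composite log(PS·f_u,brain) + logBB
and a commercial logBB predictor) are *ingested*, never recomputed: the
pipeline thresholds precomputed columns (> −3.50 and > 0) and records per
model whether values were recomputed or read from columns. The CNS access
band at exactly −3.50 falls in the non-penetrant/CNS− side, both printed
comparators being strict; weak penetrants (−3.50, −3.0] count as CNS+ in
the binary view.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kelder` PSA cutoff | 70 Å² | the narrowed PSA range is quoted as 60–70 Å² without a single threshold; 70 is the default, 60 reachable via `psa_cutoff` |
| MPO thresholds | 4 (drug), 3 (PET) | strict `>` comparisons |
| `mwhbn_exponent` | 0.5 | MWHBN = HBN / MW^e in the BBB score; the defining publications are ambiguous between e = 1 and a root normalization, so the exponent is config |
| logBB threshold | 0 | CNS+ iff logBB > 0 |
| CNS access bands | −3.50, −3.0 | non/weak/full penetrant |

BBB-score piecewise coefficients are deliberately *not* built in: the
model is defined by stepwise/polynomial piecewise functions whose
coefficients belong to the original publication; `score_bbb` evaluates
whatever piecewise config the caller supplies, and the bundled
`example_bbb_config()` is a clearly-labeled synthetic illustration.

## Descriptor backends

The open backend (RDKit) computes MW, ClogP (Crippen), TPSA, donor and
acceptor counts, heteroatom and ring counts. Two definitional choices:
HBD counts N/O atoms bearing at least one hydrogen (so water has one
donor), and `polar_h` counts hydrogens bonded to N or O. ClogD₇.₄ is
approximated by ClogP (neutral-species assumption): exact for
non-ionizable compounds, optimistic for bases. No open pKa or molar-volume
model is bundled; those fields stay unset and consumers treat them as
absent (rules flag indeterminate criteria; the MPO pKa component imputes
1.0 and flags it, because a compound without a basic center cannot be
less desirable than a weakly basic one under a decreasing transform).
Because commercial calculators produce systematically different ClogP /
ClogD / pKa values, reproducing published screening counts requires
loading the original descriptor table via `load_dataset` rather than
recomputing descriptors; the package keeps those routes explicitly
separate.

## Synthetic cohorts: what they emulate, what they do not

The generator produces descriptor-level profiles only — no chemical
structures — labeled successful/unsuccessful, with a default 109/20 class
imbalance mirroring the size and imbalance of reported PET-tracer
cohorts.

- **clean** mode samples positives strictly inside every desirable range
  of the anchor MPO model and negatives with exactly `n_violations`
  components strictly inside undesirable regions (default 3, which caps a
  six-component total at 3 and guarantees separability under both
  built-in thresholds). This gives exact ground truth for the scoring
  path: Se = Sp = 1 is a correctness property, not a performance claim.
- **boundary** mode places records on and on both sides of every printed
  comparator boundary (integer descriptors use the flanking integers),
  pinning the `≤`/`>` semantics.
- **realistic** mode draws the six anchor descriptors from per-class
  normals truncated to physical ranges. The default means/SDs (positive
  MW 320 ± 40, negative 520 ± 60, etc.) are illustrative synthetic
  constants chosen once to straddle the CNS MPO cutoffs; they are not
  fitted to any measured dataset.

Consequently, passing tests on synthetic cohorts demonstrates that the
classifiers implement their definitions and that the evaluation machinery
is correct; they say nothing about how real tracers distribute in
descriptor space, about correlations between descriptors (the generator
draws them independently), or about the discriminative power of any model
on measured data. The ancillary counts (HBA, N+O, aromatic rings) are
drawn from small discrete ranges and clamped to the profile invariants
(HBN = HBD + HBA, N+O ≥ N).

## Numerical choices

- Desirability transforms are continuous; at a desirable bound the score
  is exactly 1, strictly past an undesirable bound exactly 0, and the
  interpolation formula `(undesirable_min − x)/(undesirable_min −
  desirable_max)` reaches 0 exactly at the undesirable bound.
- Metrics with zero denominators return `None` plus an entry in
  `undefined` rather than 0/NaN; MCC with a zero marginal returns 0.0
  (flagged). This matters on 109/20-style cohorts where a degenerate
  classifier empties a margin.
- The Renkin–Crone relation is evaluated with `log1p` for accuracy near
  zero uptake; its domain 0 ≤ K_in < F is enforced. Tests invert it
  numerically (bisection) and require round-trip recovery of K_in to
  1e−9 relative tolerance.
- Reported percentages round half away from zero to the nearest integer
  percent.
- Determinism: profiles, scores and verdicts are pure functions of their
  inputs; the generator is fully determined by its seed; result CSVs are
  byte-stable.

## Problem sizes

The property suite sweeps 10⁵ random profiles for transform-range checks,
all 2×2 confusion tables with n ≤ 50 (≈ 3·10⁵ tables) against a
chi-square-based phi oracle, 20 seeds of clean-mode recovery, and 200
perfusion round-trips; the analysis scripts and the acceptance script use
the default 109/20 cohorts. These sizes make every check exact or
statistically stable while keeping the whole suite interactive.

## Known limitations

- The open descriptor backend cannot reproduce commercial ClogD/pKa
  values; screening counts computed from recomputed descriptors will
  differ from counts computed from vendor tables (by design, both routes
  are explicit).
- Only 2D descriptors are supported: molecular volume and solvent
  accessible surface area criteria, and conformer-dependent properties,
  are out of scope.
- Efflux-transporter liability (P-gp/BCRP), non-specific binding and PET
  pharmacology parameters (K_d, B_max, binding potential) are not
  modeled; the classifiers address BBB permeability only.
- The Vilar models are published as a joint predictor (model 6 for the
  CNS+ threshold, model 7 for the CNS− threshold); the pipeline exposes
  each model's classification separately and leaves joint use to the
  caller.
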