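# recurra

Gut-microbiota beta-diversity analysis and post-operative Crohn's
disease recurrence prediction from binned UniFrac-distance likelihoods.

## The problem

Crohn's patients undergoing ileocolic resection start from a state of
known mucosal health, yet most see inflammation return at the
neo-terminal ileum; at the first post-operative colonoscopy the
Rutgeerts score grades the mucosa (0–1 remission, 2–4 recurrence).
Could profiling the gut microbiota of the *surgical* specimen predict
that outcome?  This package implements the full analysis chain for that
question on mucosal-biopsy 16S profiles:

* **Diversity.** Weighted UniFrac between communities on a shared
  phylogeny — raw value `Σ_b ℓ(b)·|p_A(b) − p_B(b)|` over branches `b`,
  optionally normalised by the abundance-weighted root-to-leaf depth so
  distances lie in [0, 1] — plus Chao1
  (`S_obs + F₁(F₁−1)/(2(F₂+1))`), Faith PD and rarefaction.
* **Ordination.** Classical PCoA (Gower double-centering,
  eigendecomposition, axes scaled by `√λ`).  Multiple biopsies from one
  patient at one time are pseudo-replicates and are collapsed to their
  per-axis mean (centroid) before any between-patient comparison.
* **Inference.** Permutation (Monte-Carlo) t-tests on distance pools —
  exact by enumeration at small n — and per-taxon Welch tests on
  patient-averaged relative abundances with BH q-values.
* **Prediction.** The binned likelihood model: histogram the remission
  and recurrence distance pools in bins of width 0.1 (each class
  normalised to frequencies), convert to per-bin
  `P(rec|bin) = f_rec/(f_rec+f_rem)`, score a patient by the mean
  probability over their biopsies' distances, and validate
  leave-one-patient-out.  Robustness exercises: random single-biopsy
  resampling and exhaustive one-biopsy-per-patient combinations.
* **Sequencing-error simulation.** Reads drawn from reference
  sequences with per-base substitution errors, dereplicated, filtered,
  and greedily clustered at 97% identity, demonstrating how sequencing
  noise inflates OTU counts at deep coverage.
* **Synthetic cohorts.** No sequence data ship with the package; a
  generator plants the cohort structure of interest (tight control
  cluster, dispersed Crohn's patients, recurrence offset from controls
  and less stable through time) in multinomial counts over a simulated
  phylogeny; every analysis runs end-to-end without any download.

## Worked example

```sh
python analysis/01_simulate_cohort.py     # synthetic cohort -> results/data/
python analysis/02_beta_diversity.py      # UniFrac, PCoA, group tests
python analysis/03_recurrence_prediction.py
```

which prints (seed 17):

```
patients: 3 remission, 3 recurrence, 8 controls
...
crohns_vs_crohns: 0.308 +/- 0.036  vs  control_vs_control: 0.091 +/- 0.004  (permutation p = 0.000999, 1000 reps)
...
leave-one-patient-out: 6/6 correct; mean winning-class probability 100% +/- 0%
single random biopsy per patient (10000 draws): 38% of comparisons significant
all 729 one-biopsy-per-patient combinations: 28% significant
```

Crohn's patients are more dispersed in ordination space than controls
(mean pairwise centroid distance 0.308 vs 0.091); the multi-biopsy
likelihood model recovers every patient's outcome while a single random
biopsy separates the outcome groups in only ~1/3 of draws — combining
biopsies is what makes the signal usable.  Scripts `04`–`06` add the
through-time stability analysis, alpha diversity, and the OTU-inflation
experiment.

## Layout

* `src/recurra/` — the library: `data_model`, `diversity`,
  `ordination`, `group_inference`, `classifier`, `seqsim`, `synth`,
  `pipeline`.
* `analysis/` — numbered narrative drivers writing tables under
  `results/`.
* `docs/methods.md` — models, parameters, numerical choices and
  limitations.
* `tests/` — unit, property and end-to-end acceptance tests.
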