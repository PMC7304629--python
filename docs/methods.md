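# Methods

## The model

`bindmode` treats partner-free binding-mode prediction as a two-stage
problem.

**Stage 1 — window scoring.** A candidate binding region *R* (a window of
5–9 consecutive residues) is described by three differences between the
window and its flanking context (up to 20 residues on each side, pooled):

| feature   | meaning                                   | scale / units                     |
|-----------|-------------------------------------------|-----------------------------------|
| ΔID       | mean disorder score, window − flanks      | disorder probability, [−1, 1]     |
| ΔA        | composition bias, window − flanks         | TOP-IDP propensity units (default)|
| ΔH        | mean hydropathy, window − flanks          | Kyte–Doolittle units, [−9, 9]     |

The linear score S_F(R) = λ1·ΔID + λ2·ΔA + λ3·ΔH + γ maps through the
logistic function to p_DO(R), the probability that the region folds upon
binding. The underlying assumption is that a segment that is locally more
hydrophobic, less disorder-prone and compositionally atypical relative to
its context has a template for ordering when a partner arrives, whereas a
segment indistinguishable from its context can form many alternative,
exchangeable contacts and stays fuzzy.

**Stage 2 — residue aggregation.** For residue A_i, the set
{p_DO(R_i)} over all windows containing it (35 in the interior; down to 5
at the termini, which are kept, not discarded) is summarised two ways:
its median gives p_DO(A_i) (and p_DD = 1 − p_DO), and its histogram over
ten 0.1-wide bins gives binding-mode frequencies whose base-2 Shannon
entropy S_Ai ∈ [0, log₂10] quantifies binding-mode diversity. Ten bins is
a deliberate ceiling: finer modes would require more candidate windows,
i.e. longer interfaces than disordered binding motifs typically form.

**Landscape classification.** Residues are labelled on the (p_DD, S_Ai)
plane using fixed boxes: disorder-to-order (p_DD < 0.25, S < 1.8),
disorder-to-disorder (p_DD > 0.65, S < 1.8), polymorphic (p_DD ≤ 0.25,
S > 2.25), conditionally folding (0.25 < p_DD ≤ 0.45, S > 2.25) and
disordered-binding (0.45 < p_DD ≤ 0.75, S > 2.25). The boxes do not tile
the plane; everything between them — notably the 1.8 ≤ S ≤ 2.25 band — is
labelled `continuum`, reflecting that the landscape is a continuum of
interaction behaviours rather than five discrete categories. Thresholds
are exposed as a JSON-configurable `LandscapeThresholds` object; the
boundary inclusivities above are implemented literally.

## Parametrisation

Coefficients are estimated by plain maximum-likelihood logistic regression
on labelled regions — one example per region, not per residue, with
features computed over the whole annotated region against its 20-residue
flanks. Regions observed ordered in every complex (with an interface
contact) are positives; regions disordered in every structure are
negatives; context-dependent regions are excluded from training.

Numerics: Newton/IRLS from β = 0, convergence when the log-likelihood
changes by < 1e−8, at most 100 iterations; standard errors from the
inverse observed information; Wald 95% intervals. Complete separation
(perfect classification with |β| diverging) is detected and handled by
refitting with a ridge of 1e−4 and an explicit `SeparationWarning` — the
unpenalised MLE does not exist in that case. The fit is cross-checked
against an independent maximum-likelihood implementation in the test
suite.

Because no canonical coefficient set ships with the method, model
parameters are a required input file. The packaged default
(`data/default_model.json`) is fitted on synthetic labelled regions and
its provenance block marks it NON-CANONICAL; it exists so the pipeline
runs out of the box. Every model file records the feature configuration
(window range, flank length, composition statistic, disorder source) and
`score_region` refuses to mix parameters with differently-computed
features.

### Open design points and how they were resolved

* **ΔA statistic.** The exact published composition formula is not
  available; the default is the difference in mean TOP-IDP disorder
  propensity between window and flanks, with an L1
  composition-vector distance selectable in `FeatureConfig`. The choice is
  recorded in the model file so it can never silently diverge from the
  features at prediction time.
* **Disorder source.** Predictions consume any per-residue score in
  [0, 1]. The built-in fallback is a FoldIndex-style unfoldability index
  (u = 2.785·⟨H⟩ − |⟨q⟩| − 1.151 on a 21-residue window, normalised KD
  hydropathy; disorder = 0.5 − u clipped to [0, 1]). It is deterministic
  and uses only quantities the package already needs, but it is a coarse
  stand-in: benchmark-grade runs should inject scores from a trained
  disorder predictor through the score-TSV interface.
* **Median convention.** Even-count window sets use the midpoint of the
  two central order statistics (the standard sample median).
* **Bin edges.** Half-open [0, 0.1), …, [0.8, 0.9), with [0.9, 1.0]
  closed; membership is floor(10·p) on the stored double.
* **Terminal residues.** Residues near the termini have 5–34 windows;
  their reduced sets are used as-is rather than dropped, since terminal
  entropy is not systematically different once the set is non-trivial.
* **Unscorable windows.** Windows touching a nonstandard (X) residue or
  lacking any flanking context are dropped, not imputed; `n_windows`
  records survivors and residues with none are emitted as missing.

## Structure curation

Order/disorder calls come from modelled coordinates only: a residue is
ordered (O) when any non-hydrogen atom is present, missing (M) otherwise
(no electron-density analysis). Disordered regions are maximal M-runs of
≥ 5 residues in the monomer; a resolution filter (reject worse than 3 Å)
is available. Interface residues are those with any heavy atom within
4.5 Å of a different chain, homotypic pairs included; the neighbour search
is non-periodic (crystal-symmetry contacts are out of scope). Region
labels: DOR requires ≥ 5 consecutive ordered residues in *every* complex
plus ≥ 1 interface contact; DDR requires the region missing in monomer
and all complexes; CDR requires an ordered (contacted) form in one complex
and a missing form in another; anything else is `unclassified`, with the
evidence stored so every label is re-derivable. Leading/trailing M-runs
are flagged as potential construct-truncation artefacts and excluded from
DDR/CDR evidence by default (overridable). Sequence mapping is by author
numbering against a declared full-length sequence, falling back to exact
substring alignment of the modelled stretch. Redundancy reduction of input
structure sets is the caller's responsibility; the curator assumes a
pre-clustered list.

## Synthetic data: what it emulates, and what it does not

* `simulate_training_set` draws feature triples from independent normals
  (defaults: sd 0.3 for ΔID and ΔA, 1.5 for ΔH — the scales on which the
  real biases live) and labels them through the true logistic model, with
  generating coefficients (2, −1, 0.5, −0.3) as the reference recovery
  target. A correlation structure can be supplied for robustness checks.
  This validates the estimator, not the biological realism of features.
* `synth_sequence` plants regions with requested hydropathy/disorder
  biases (hydropathy via exponentially tilted composition sampling, target
  hit within ~0.2 KD units; disorder bias exact by construction) in a flat
  background composition. Real proteomes are not compositionally flat and
  real disorder profiles are autocorrelated; passing tests on these
  fixtures demonstrates that the pipeline responds correctly to designed
  local biases, not that real-proteome predictions are accurate.
* `synth_structures` writes minimal PDB files (N/CA/C on an idealised
  extended chain, partner atoms placed 4.2 Å from the designated contact
  residue) that realise O/M plans exactly. They exercise the curation
  logic, including the 4.5 Å rule, without any physical realism.

## Problem sizes and evaluation

The evaluation module computes rank-based AUC (U/(n1·n2), midrank ties),
Mann-Whitney tests (exact two-sided p when n1·n2 ≤ 400 without ties,
normal approximation with tie and continuity correction otherwise), and a
bivariate logistic discriminator on (p_DD, S_Ai) whose AUC approaches the
Bayes optimum on Gaussian test classes. The test suite and the acceptance
script use n = 5000 for single-fit recovery, 100 replicates at n = 1000
for confidence-interval coverage, n = 1000 per class for permutation AUC,
and 50000 draws for prevalence calibration — sizes at which the Monte-Carlo
error of each check is far below its tolerance while the whole suite runs
in seconds.

## Known limitations

* Predictions are only as good as the disorder scores supplied; the
  built-in fallback is deliberately simple and the packaged default
  coefficients are synthetic. Published benchmark figures for this class
  of method (per-class AUCs on curated DOR/CDR/DDR datasets) depend on a
  specific external disorder predictor, a curated supplementary dataset
  and trained coefficients that were never published, so the repository
  ships the evaluation harness but asserts no such numbers.
* The composition statistic is a documented stand-in (see above); models
  trained with one statistic are incompatible with features from another
  by design.
* The method is partner-free by construction: it predicts the spectrum of
  binding modes a residue can sample, not which mode a given partner will
  select.
* Curation infers disorder from missing coordinates, which conflates
  genuine disorder with crystallographic artefacts; the terminal-run flag
  mitigates, but does not eliminate, truncation effects.
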