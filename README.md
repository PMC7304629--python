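# bindmode

Sequence-based prediction of **binding-mode landscapes** for intrinsically
disordered protein regions (IDRs).

Many disordered regions fold into a well-defined structure when they bind a
partner (a *disorder-to-order* transition, DO), while others stay
conformationally heterogeneous in the bound complex (*disorder-to-disorder*,
DD — "fuzzy" binding). A third group switches between modes depending on the
partner or cellular context. `bindmode` predicts, from sequence alone and
without knowing the partner, which of these behaviours each residue prefers
and how context-dependent that preference is. It is aimed at structural
bioinformaticians and IDP researchers triaging disordered regions for
experimental characterisation.

## The model

For every residue *A<sub>i</sub>*, all candidate binding windows *R* of
length 5–9 containing it are enumerated (35 for a residue away from the
termini). Each window is compared against its up-to-20-residue flanks on
three local biases — disorder propensity ΔID, amino-acid composition ΔA and
Kyte–Doolittle hydropathy ΔH — and scored linearly:

```
S_F(R) = λ1·ΔID + λ2·ΔA + λ3·ΔH + γ
p_DO(R) = exp(S_F) / (1 + exp(S_F)),   p_DD(R) = 1 − p_DO(R)
```

The residue-level probability `p_DO(A_i)` is the **median** of the window
set `{p_DO(R_i)}`. Binning the window probabilities into ten 0.1-wide
binding modes gives frequencies whose **Shannon entropy** (bits)

```
S_Ai = − Σ f[p_DO(R)] · log2 f[p_DO(R)]
```

measures how many distinct binding modes the residue can sample (0 =
committed to one mode, log₂10 ≈ 3.32 = maximally context-dependent). Each
residue is then placed on the two-dimensional **(p_DD, S) landscape**:
disorder-to-order (p_DD < 0.25, S < 1.8), disorder-to-disorder
(p_DD > 0.65, S < 1.8), and three fuzzy, context-dependent classes at
S > 2.25 — polymorphic (p_DD ≤ 0.25), conditionally folding
(0.25 < p_DD ≤ 0.45) and disordered-binding (0.45 < p_DD ≤ 0.75) — with the
remainder forming the continuum between them.

The coefficients (λ, γ) are estimated by maximum-likelihood logistic
regression on curated regions that fold upon binding (label 1) versus
regions that stay disordered (label 0); the package also implements the
structure-based curation rules that produce such labels from monomer and
complex coordinate files (missing-density = disordered; DOR / CDR / DDR
assignment with a 4.5 Å interface criterion).

## Worked example

```python
from bindmode import ProteinSequence, BindingModeModel
from bindmode.simulate import SimulationSpec, simulate_training_set

examples = simulate_training_set(SimulationSpec(n=2000, seed=7))
res = BindingModeModel.from_examples(examples).fit()
print(res.summary())
```

```
Binding-mode logistic model
==============================================================
N regions: 2000   folds-on-binding: 851   log-likelihood: -1158.6791
converged: True in 5 iterations
--------------------------------------------------------------
                coef   std err       z      [0.025    0.975]
   lambda1    2.0960    0.1813   11.56      1.7407    2.4512
   lambda2   -0.9525    0.1733   -5.50     -1.2922   -0.6128
   lambda3    0.5466    0.0377   14.51      0.4727    0.6204
     gamma   -0.3676    0.0509   -7.23     -0.4673   -0.2680
==============================================================
composition statistic: topidp   flanks: 20   windows: 5-9
```

The generating coefficients (2, −1, 0.5, −0.3) sit inside every 95%
interval. Profiling a sequence with a hydrophobic island inside a charged,
disordered context:

```python
seq = ProteinSequence("demo",
    "EDSSEDEAKGRSDEKRNSQE" + "ILVFLAVLI" + "EDGSRKQNSEDEKRSGNDSE")
df = res.profile_frame(seq)          # built-in disorder fallback
print(df.iloc[[5, 24, 28, 44]].to_string(index=False))
```

```
sequence_id  position residue  n_windows     p_do     p_dd  entropy_bits      landscape_class
       demo         6       D         29 0.331085 0.668915      0.940144 disorder-to-disorder
       demo        25       L         35 0.872591 0.127409      1.782847    disorder-to-order
       demo        29       I         35 0.643987 0.356013      2.937762  conditional-folding
       demo        45       G         25 0.270928 0.729072      1.319996 disorder-to-disorder
```

The charged flanks are confidently predicted to stay disordered when bound
(p_DD ≈ 0.67–0.73, low entropy), the centre of the hydrophobic island to
fold upon binding (p_DO ≈ 0.87), and the island's edge shows a high
binding-mode entropy (2.94 bits) — a conditionally folding, fuzzy residue
whose behaviour depends on context.

The same pipeline is available from the shell:

```bash
bindmode predict --fasta query.fasta --builtin --out profiles.tsv
bindmode featurize --fasta seqs.fasta --regions regions.tsv --builtin --out feats.tsv
bindmode fit --features feats.tsv --out model.json
bindmode curate --monomer mono.pdb --complexes c1.pdb --complexes c2.pdb \
    --chain A --sequence-fasta full.fasta --out regions.tsv
bindmode evaluate --profiles profiles.tsv --labels labels.tsv --out metrics.json
```

The packaged default model is fitted on synthetic labelled regions (its
provenance block says so) so the tool runs out of the box; for
benchmark-quality predictions, train on curated regions with externally
computed disorder scores and pass that model file.

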