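# Methods

## Scope and data model

The package predicts the binding free-energy change ΔΔG = ΔG_mutant −
ΔG_wild (kcal/mol; positive = weakened binding) of an antigen–antibody
complex under one or more residue substitutions, from chain sequences
alone.  One *mutation record* holds the complex id, the wild-type antibody
and antigen chains, a mutation list, and the measured ΔΔG.  Multi-chain
proteins (e.g. heavy + light antibody chains) are concatenated in table
order into a single sequence per role before featurization, with chain
boundaries retained for reporting; the model consumes exactly one antibody
and one antigen sequence per complex.

Mutation positions are 1-based indices into the named chain's sequence.
Benchmark tables that number residues against author/PDB coordinates must
declare a per-chain offset column (`A:32` means "subtract 32 from table
positions on chain A"); without it sequential numbering is assumed, and a
wild-type mismatch raises with chain, position, expected and found residue
rather than silently mis-indexing.  `X` is accepted in sequences (all-zero
one-hot row) but never as a mutation target.

## Featurization

Each sequence becomes an (n, 40) matrix: a one-hot block and a PSSM block,
both ordered by the fixed alphabet `ACDEFGHIKLMNPQRSTVWY`.  PSI-BLAST
ASCII profiles are parsed and re-ordered from the native
`ARNDCQEGHILKMFPSTWYV` column order at read time, and are used as raw
log-odds (no squashing or standardization; per-matrix z-scaling is
available behind `z_scale=` for experimentation).  Generating profiles
with PSI-BLAST (typically 3 iterations against UniProtKB/Swiss-Prot) is an
external recipe; the package only parses the output.  Whether profiles are
computed per chain or per concatenated role sequence is the caller's
choice — the `Featurizer` keys profiles by exact sequence string, and the
per-concatenated-sequence convention matches the one-matrix-per-protein
data model.

When no profile is supplied — synthetic data in particular — a
deterministic fallback assigns each residue its BLOSUM62 log-odds row.
This carries residue identity and substitution-preference information but
*no positional conservation signal*; conclusions about what PSSMs
contribute on real data cannot be drawn from synthetic runs.

## Network

Widths below refer to `ModelConfig`; defaults are hidden_size 64, kernel
sizes (3, 5, 7), 4 heads, dropout 0.1, head sizes (128, 64, 1).

* **Embedding.**  Three 1-D convolution branches over the (B, N, 40)
  input, one per kernel size, each emitting 2·hidden_size channels split
  into value and gate halves combined as `value ⊙ σ(gate)` (a gated linear
  unit).  Branch outputs are concatenated to d = 3·hidden_size channels
  and layer-normalized over channels; padded positions are zeroed.
* **Self-attention.**  Scaled dot-product attention with d split across
  heads (d_k = d/n_heads), padded key positions excluded from the softmax
  by an additive −1e9 bias, head outputs concatenated and linearly mixed,
  dropout on the mixed context (training only), then a residual
  connection.
* **Mutual attention.**  Same scaled dot-product form, but queries come
  from one protein and keys/values from its partner, computed in both
  directions within each complex variant so each protein's representation
  is partner-aware.  As specified by its defining equation it carries *no*
  residual and *no* dropout (a `mutual_residual` switch exists for
  experimentation, off by default, and off in every reported run).  Head
  outputs are concatenated without an extra mixing matrix.  The
  head-averaged antigen→antibody map — each row a probability distribution
  over antibody positions — is exported for interpretability.
* **Prediction head.**  Mask-aware mean pooling over each protein's true
  length (max pooling available behind `pooling="max"`); the four pooled
  vectors are concatenated wild-pair-first into a 4d vector and passed
  through three affine layers with rectifiers between them, the last layer
  of size 1.  No nonlinearity after the final scalar.
* **Ablation.**  `use_attention=False` routes pooled *embeddings* directly
  to the head.  Because attention maps d → d, the head input width is
  identical with and without the block, so the control isolates the
  attention mechanism rather than parameter count.

Open design points were resolved as follows: attention block depth is 1
(the mutual-attention output does not re-enter self-attention); pooling is
mean rather than max or a learned token (simple and length-robust);
multi-head attention uses the standard subspace-splitting construction.

## Autodiff core and optimization

The network runs on a small reverse-mode automatic-differentiation engine
written for this package (numpy arrays, float64 throughout, ~20
primitives: broadcasting arithmetic, batched matmul, reductions, sigmoid /
relu / exp, a masked softmax with the mask fused as a constant additive
bias, shape ops, and max over an axis).  Gradients accumulate by
topological traversal; every primitive's backward rule is checked against
central finite differences in the test suite, and an end-to-end check
verifies backpropagated parameter gradients of the one-record MSE to
relative error < 1e-3.

Training is mini-batch Adam (β = 0.9/0.999, ε = 1e-8, plain L2 as
`weight_decay`) on the MSE loss, labels in kcal/mol without normalization.
Mini-batches are drawn within complexes — records of one complex share
chain lengths, so per-batch right-padding is near zero; record order
within complexes and batch order are reshuffled each epoch.  One model
seed fixes initialization (Glorot-uniform weights, zero biases); one
training seed fixes shuffling and dropout; runs are bit-reproducible given
both.  A non-finite loss aborts with diagnostics.  With a validation set,
the best-validation-loss parameters are returned and optional
early-stopping patience applies.

## Evaluation protocols

* **K-fold** — records shuffled with a seed and dealt into k folds whose
  sizes differ by at most one.
* **Label-ascending split** — within each complex, records sorted by ΔΔG
  (stable, so ties keep input order) and the top ceil(fraction·size)
  labels held out; every complex then satisfies min(test ΔΔG) ≥ max(train
  ΔΔG).  This probes extrapolation to stronger affinity losses than seen
  in training.  Singleton complexes go to train with a warning.  The
  default test fraction is 0.2.

Metrics: Pearson correlation; R² as the coefficient of determination
1 − SS_res/SS_tot (≤ 1, may be negative; this standard definition is used
deliberately); rank consistency = R² applied to average-rank vectors,
invariant under monotone transforms, for candidate-ranking use cases.
Pooled out-of-fold metrics (all held-out predictions concatenated) are
primary; per-fold values are also reported, NaN where a fold is too small
or degenerate.

## Interpretability transform

Wild and mutant antigen×antibody maps are min-max normalized over the
whole matrix (not per row — the normalization is defined on matrix
entries), subtracted mutant-minus-wild, and the difference renormalized to
[0, 1].  A constant input matrix maps to all zeros by policy so degenerate
cases still render.  The transform is invariant to any common positive
affine rescaling of both inputs.  Heatmap exports write a labelled TSV
(rows = antigen residues such as `K7`, columns = antibody residues) and a
PNG with the antigen sequence on the x-axis.  The
`mutated_column_enrichment` diagnostic reports the mean map value over
mutated antibody columns relative to the global mean (> 1 = the map
highlights mutated sites); it is a reported statistic, not a hard gate,
because head-averaged attention differences are only an indirect probe of
what the model uses.

## Synthetic benchmark

The generator emulates the structure of curated antibody-mutation tables
while planting a known signal.  Per complex: antigen of 60–120 and
antibody of 80–150 residues drawn uniformly from the canonical alphabet
(long enough for the convolution kernels, short enough for minutes-scale
CPU training), and a contiguous 8-residue antibody interface window.  Per
record: 1–5 mutation sites, drawn from the interface with probability 0.8,
and

    ΔΔG = Σ_sites weight(site)·(μ(mt) − μ(wt)) + N(0, noise_sd²)

with weight 1 inside the window and 0 outside, residue pseudo-energies μ
i.i.d. N(0, 0.7²) kcal/mol — so a typical single interface substitution
shifts ΔΔG by about 1 kcal/mol, commensurate with curated tables — and
noise_sd = 0.3 by default.  The pairwise effect table μ(b) − μ(a) is
antisymmetric with zero diagonal by construction, and with zero noise the
emitted labels equal the analytic ground truth exactly.

What this does and does not test: position-dependence (only interface
sites matter) gives the attention block a real signal to find, and
off-interface records have true ΔΔG = 0, so a position-blind model is
measurably handicapped.  But the sequences have no immunoglobulin grammar,
no CDR structure, no epistasis, and the effect model is additive by
construction — passing the benchmark demonstrates that the pipeline can
recover a planted residue- and position-specific signal through noise, not
that it attains any particular accuracy on real antibody data.

## Standard run sizes and numerical choices

The standard benchmark configuration (`benchmark_configs()`) pairs the
default generator (8 complexes × 60 records, 480 total) with a compact
model — hidden_size 16 (d = 48), 2 heads, head sizes (64, 32, 1) — trained
60 epochs, batch 32, Adam lr 1e-3, an 80/20 hold-out split, and fixed
seeds; it reaches held-out PCC ≈ 0.7 in a few minutes on one CPU core.
These sizes are the package's declared study conditions for synthetic
runs; the full-width default model (hidden 64, 4 heads, lr 1e-4) is the
configuration intended for real benchmark tables.

Numerical details: float64 everywhere; masked softmax via additive −1e9
bias (exact zeros after underflow, so padding invariance holds to machine
precision); layer-norm ε = 1e-5; min-max normalization returns zeros on
constant input; metric functions raise on constant vectors rather than
returning NaN; Pearson/rank computations delegate to scipy.  Checkpoints
are a single `.npz` archive with a JSON config header and a format tag.

## Known limitations

* No pretrained protein language model embeddings and no structural
  features; accuracy on real data is bounded by what raw sequences + PSSMs
  carry.
* The BLOSUM62 pseudo-profile is a weak stand-in for alignment-derived
  PSSMs; real-data workflows should supply PSI-BLAST profiles.
* Attention-difference maps are a visualization aid, not a causal
  attribution method.
* The numpy autodiff core targets clarity and CPU-scale problems; it does
  not batch across devices and is not competitive with framework kernels
  on large datasets.
* Antibody-specific numbering schemes (Kabat/IMGT) and PDB renumbering are
  out of scope; tables must be reconcilable to sequential positions via
  the offset mechanism.
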