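# Methods

## Model

Let `Y ∈ {0,1}^{nm×nd}` be the known microbe–disease adjacency. The model
scores every pair in three stages.

**GIP kernels.** The interaction profile of a microbe is its row of `Y`,
of a disease its column. Side-specific similarity is the Gaussian
interaction-profile kernel `K(i,j) = exp(−γ‖IPᵢ − IPⱼ‖²)` with
`γ = γ′ / mean(‖IP‖²)`; for 0/1 profiles the mean squared norm is the mean
degree, so the bandwidth adapts to sparsity and `γ′` (default 1 on both
sides) is scale-free. The kernel is symmetric positive semidefinite with
unit diagonal and entries in (0, 1]. A single all-zero profile (an entity
whose last association was masked during cross-validation) is legal —
distances remain defined; only an all-zero profile *set* is degenerate and
raises an error.

**LapRLS per space.** With `L = D^{−1/2}(D − K)D^{−1/2}` the symmetric
normalized Laplacian of a kernel (`D` = diagonal of row sums), each space
solves

    min_F ‖A_side − F‖²_F + η · tr(Fᵀ L F)

whose unique minimizer is `F = (I + ηL)^{−1} A_side`, identical to the
kernel-form closed expression `K(K + ηLK)^{−1}A_side` whenever `K` is
invertible. The penalty is the graph-smoothness quadratic form
`tr(FᵀLF) = Σ_columns Σ_{i,j} K̃ᵢⱼ (fᵢ/√dᵢ − fⱼ/√dⱼ)²/2`: similar entities
get similar score rows. `η` (default 1 per side) trades data fit against
smoothness; `η = 0` returns the adjacency unchanged, `η → ∞` flattens each
column onto the Laplacian null space (the √degree direction).

**Orientation and fusion.** With `A = Yᵀ` (disease × microbe), the
microbe-space classifier consumes `Aᵀ = Y` and is nm × nd; the
disease-space one consumes `A` and is nd × nm. This is the only reading
under which every product in the closed forms is dimensionally defined.
The fused score matrix is `F* = lw·FM + (1−lw)·FDᵀ` (nm × nd); `lw = 0.5`
— a plain mean — is the default, exposed as a knob. Scores are ranking
quantities, not calibrated probabilities.

## Numerical choices

- The per-space system is solved as the SPD system `(I + ηL)F = A_side`
  (Cholesky via `scipy.linalg.solve(assume_a="pos")`), never an explicit
  inverse. The unreduced system `(K + ηLK)X = A_side` is *singular* in
  practice: entities with identical profiles (e.g. the many degree-1
  microbes attached to the same hub disease) produce duplicate kernel
  rows. The reduced form is the continuous extension — it is the cost
  minimizer for any `K` — and agrees with the kernel form to 1e−10 on
  well-conditioned instances (tested against an explicit-inverse oracle
  and a numeric optimizer).
- If the solve fails or leaves a relative residual above 1e−8, the code
  falls back to a pseudo-inverse solution (relative singular-value cutoff
  1e−10) and logs a warning when the condition number exceeds 1e12.
- Kernels are computed from the Gram matrix with the squared distance
  clipped at 0, then exactly symmetrized with the diagonal pinned to 1.
- AUC uses the midrank Mann–Whitney convention (ties worth ½), which
  coincides with the trapezoidal area under the emitted ROC curve; a
  constant score vector yields exactly 0.5. Candidate ranking breaks score
  ties by index order (stable sort).

## Cross-validation protocols

All protocols mask edges of `Y` and **recompute both GIP kernels on the
masked matrix** before refitting — the similarity is a function of the
labels, so reusing full-data kernels would leak the held-out pairs.

- **Global LOOCV** (deterministic): each known pair is masked in turn and
  its refit score recorded. The negative set — scores of all never-known
  pairs — is taken from the single full-data model, and one pooled ROC is
  computed. The alternative of re-scoring negatives inside every masked
  run is available (`negatives="per-run"`, rank-percentile averaging); on
  the fixtures the two agree to a few hundredths, and the fixed-reference
  variant is the default because it yields one well-defined pooled curve.
- **Local LOOCV** (deterministic): same masking loop, but each held-out
  pair is ranked only against the unknown microbes of its own disease
  column. Raw scores are not comparable across columns, so per-pair rank
  percentiles are pooled; the AUC is their mean (the probability that the
  held-out microbe outscores a random unknown microbe of the same
  disease), and the reported curve sweeps the percentile threshold.
- **Repeated 5-fold CV** (seeded): known pairs are shuffled and split into
  five nearly equal groups — over *pairs*, not entities, without
  stratification; each group is masked simultaneously and its positives
  ranked (percentile) against the masked model's scores at all
  originally-unknown pairs. Percentiles pool across folds into one AUC per
  repeat; the summary is mean ± sd over repeats (default 100), with
  fold-level AUCs and their sd kept in the result detail since either
  spread convention appears in the literature. One `numpy` generator seeded
  by the caller drives all splits.

Runtime: one refit at 292 × 39 is a few milliseconds, so global LOOCV
(~450–500 refits) takes ~3 s and 100×5-fold ~6 s on one CPU.

## Synthetic generators

`random_bipartite` draws i.i.d. Bernoulli edges — the null against which a
predictor should score ≈ 0.5. `planted_block_network` partitions both node
sets into co-clusters with edge probabilities `p_in` within and `p_out`
across; the strong-structure configuration used throughout the tests is
3 blocks, `p_in = 0.6`, `p_out = 0.02` at 60 × 20 (sized so the full test
suite stays fast). `hmdad_like` emulates the statistical profile of a
genus-level curation: 292 × 39, ~450 expected associations, lognormal
disease-popularity weights (log-sd 1.3, giving the hub diseases that
dominate real curations) and 9× within-block contrast. All generators are
seed-deterministic, and empty rows/columns are repaired by adding one
uniform edge per empty line (capped at 100 rounds) so tiny sparse fixtures
remain feasible.

What the fixtures do **not** emulate: taxonomy and name synonymy,
per-study reporting correlations, duplicate curation entries, and the
exact degree sequence of any real database. Passing fixture tests
therefore demonstrates that the machinery is correct and that the model
exploits planted structure; it does not certify performance numbers on any
real curation — the benchmark tests against the real genus-level export
run only when that table is supplied (`data/hmdad_associations.tsv`).

## Data handling

Association tables are TSV/CSV with one (microbe, disease) row; names are
whitespace-normalized but matched exactly and case-preserving — no
taxonomic or synonym resolution, which would silently change the node
counts. Duplicate rows collapse to a single edge; both the raw row count
and the distinct-pair count are reported, and all modeling uses distinct
pairs (the model consumes a binary adjacency). Index order defaults to
first appearance and is recorded; all model outputs are equivariant under
relabeling, which is tested.

## Known limitations

- Entities with no remaining associations after masking receive only
  generic popularity-driven scores; predictions for never-observed
  microbes are out of scope by construction.
- GIP similarity inherits any ascertainment bias of the curation (heavily
  studied diseases look "similar" to everything popular).
- The fusion is a fixed weighted mean; no calibration of scores to
  probabilities is attempted.
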