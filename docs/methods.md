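# Methods

## Topology classes and the induced permutation action

A topology on `n` labelled taxa is identified with its set of nontrivial
splits.  Class indices are fixed conventions of this repository:

- **Quartets** (slots `A,B,C,D`): `I = AB|CD`, `II = AC|BD`, `III = AD|BC`.
- **Quintets** (slots `A..E`): each topology is two cherries plus one
  "middle" taxon on the path between them.  Classes are grouped by the
  middle taxon iterated `E, D, C, B, A`; within each group the remaining
  four taxa, kept in slot order, take the three quartet classes above.
  Classes 1–3 therefore restrict to the quartet classes on `A,B,C,D` with
  `E` in the middle.  Any consistent completion of the order would serve;
  this one is fixed, documented, and versioned in checkpoints
  (`phylosym-v1`), because a trained model's output classes are only
  meaningful relative to it.

Permuting input slots relabels leaves and therefore permutes classes; the
induced map `S_n → S_K` is computed by relabelling each enumerated split
set and looking it up (`topology.induced_action`).  Tests verify it is a
group homomorphism (exhaustively for `n=4`, sampled for `n=5`) and that
every class has an 8-element stabilizer (24/3 and 120/15).

Enumeration beyond `n = 8` is refused; counting uses the closed form
`(2n-5)!!`.  The test suite cross-checks enumeration against an independent
oracle that assembles all sets of `n-3` pairwise-compatible splits.

## Equivariance as an architectural invariant

Descriptors are sums of shared symmetric pair maps, so:

- within-pair and between-pair swaps leave each descriptor bitwise
  unchanged (float addition is commutative);
- an arbitrary slot permutation maps the descriptor *set* onto itself,
  permuted by the induced class action, again bitwise;
- the shared scorer `Ψ` then makes the raw score vector bitwise
  equivariant.

The softmax normalizer sums the `K` exponentials in class order, so
*probabilities* under a permuted input can differ in the last bits
(observed ≈ 1e-16); the documented contract for probabilities is therefore
a 1e-6 tolerance, while tests pin raw scores bitwise.  Identical input
sequences make all descriptors equal, forcing exactly uniform class
probabilities — a useful degenerate-input canary.

Dropout (between LSTM layers) is active only in training mode; every
equivariance statement is about evaluation mode.

## Network defaults

| parameter | quartet | quintet | notes |
|---|---|---|---|
| embedding dim `m` | 80 | 160 | per-site embedding of the 20 letters |
| LSTM hidden | 20 | 40 | scorer `Ψ` |
| LSTM layers | 3 | 6 | |
| dropout | 0.2 | 0.2 | between LSTM layers, training only |
| head hidden width | = LSTM hidden | = LSTM hidden | one ReLU layer before the scalar score |
| `β` depth | 1 residual block | 1 | deeper blocks gave marginal gains |

The head width is not pinned by the published training setups; it defaults
to the LSTM hidden size and is configurable.  `β` is a dense residual block
`x + W2·relu(W1·x + b1) + b2` applied per site; `α` is a plain embedding
table.  Both batched scoring (all `K` descriptors through one recurrent
invocation) and per-descriptor scoring are implemented; a test asserts the
two paths agree numerically.

All arithmetic is float64 NumPy through the in-repo autodiff engine.  This
keeps finite-difference gradient checks meaningful (relative error ≤ 1e-4
on a tiny model) at the cost of raw speed; the desk-scale training runs in
the test suite use reduced models (`m = 8..16`, 1 LSTM layer, `L = 50..200`)
so the whole suite stays in minutes on one CPU.

## Substitution model and simulator

The Dayhoff empirical model is embedded as the classic published integer
exchangeabilities and frequencies (identical to the matrix shipped with
standard phylogenetics software).  `Q_ij = s_ij π_j`, diagonal set to make
rows sum to zero, scaled so `-Σ_i π_i Q_ii = 1`; branch lengths are expected
substitutions per site.  The model's own frequencies are used throughout
(no empirical-data frequencies).  Transition matrices come from a symmetric
eigendecomposition done once per model; tests compare against
`scipy.linalg.expm` and check the semigroup property, detailed balance, and
the `t → ∞` equilibrium limit.

Quartet simulation: one leaf of each cherry carries the long branch
`a = κ1 b` (the choice is randomized per sample and recorded in metadata),
sisters carry `b`, internal branch `c = κ2 b`; the root sits at the midpoint
of the internal branch and root states are drawn from `π` per site.  Under a
stationary reversible chain the root placement on that edge is
distributionally irrelevant; the midpoint is fixed for reproducibility.
A single rate `r ~ U(0.05, 1)` multiplies every branch of an alignment;
sites are i.i.d. given `r` (no site-rate heterogeneity, no indels), so
columns are simulated vectorized.  Quintets draw all seven branch lengths
i.i.d. `U(0, 1)` (externals for slots `A..E` first, then the two internal
edges), keep the same per-alignment rate, and are rooted at the middle
taxon's attachment node — the degenerate "midpoint" of the internal path,
again irrelevant distributionally and fixed only to pin the random stream.

Default length `L = 1550`; default quartet grid `b ∈ {0.1, 0.5, 1}` ×
`κ1 ∈ {2, 10, 40}` × `κ2 ∈ {0.01, 0.1, 1}`.  Datasets draw labels uniformly,
derive one substream per sample from `(seed, scenario, sample)` so any
sample regenerates in isolation, and record 90/9/1
train/test/validation boundaries per scenario.  On-disk datasets are FASTA
plus a TSV label/metadata table and a YAML manifest with checksums.

What the simulator does *not* emulate: alignment error, gaps, site- and
lineage-specific rate variation beyond the single multiplier, model
misspecification.  Tests passing on these data show the pipeline is
correct and calibrated under its own generative model, not that the
classifier transfers to real alignments.

The synthetic "marker" toy set used by training sanity checks is not an
evolutionary simulation at all: background columns are i.i.d. uniform and a
random ~20% of columns share residues within the generating cherries,
making the label decodable from single columns.  Markers are spread across
the whole sequence so the signal survives recurrent scoring of long inputs.

## Maximum-likelihood distances and neighbor joining

The pairwise distance maximizes `Σ_sites log(π_x P_xy(t))` by bounded scalar
minimization on `[0, 10]` with tolerance 1e-6 on `t`.  Saturated pairs — the
likelihood still rising at the boundary — return the cap 10, mirroring the
finite ceilings of standard distance software; identical sequences return 0.
On a fixed simulated pair the estimate agrees with R phangorn's
`dist.ml(model="Dayhoff")` to ~1e-6, and at `L = 10^5` the estimator is
within 0.02 of a true separation of 0.5.

Neighbor joining is the standard Saitou–Nei Q-criterion agglomeration;
ties are broken by joining the lowest-index pair (row-major argmin), making
the output deterministic, including on the fully degenerate all-equal
matrix.  Consistency on exactly additive quartet and quintet matrices is
tested over random branch lengths, and the implementation is cross-checked
against scikit-bio's independent NJ on noisy matrices.

## The LBA comparison

`scripts/acceptance.py` re-simulates the two headline regimes (500
replicates each, `L = 1550`, labels uniform, `b = c = 1`):

- `a = 2`: every distance is well inside the identifiable range; NJ accuracy
  is 100%.
- `a = 40`: with the per-alignment rate `r ~ U(0.05, 1)`, branches of
  `40 r = 2..40` substitutions/site are usually fully saturated; distances
  hit the cap, the two short-branch taxa attract, and NJ is wrong
  essentially always.  The measured accuracy is ~4–6%, not exactly 0: the
  ~6% of draws with `r < 0.1` produce long branches of only ≈ 2–4
  substitutions/site, which are still estimable — phangorn's own
  ML distances recover those same cases, so the residual signal is a
  property of the simulated regime, not of this implementation.  For
  `r > 0.2` the measured accuracy is exactly 0.

## Training loop

Adam (lr 0.001, decayed by 0.9 every 10 epochs), cross-entropy on raw
scores (mean reduction by default; summed reduction available), evaluation
on the test split every 10 epochs (configurable), checkpoint selection by
best test accuracy, and a single final pass over the held-out validation
split.  Splits are asserted disjoint.  Quintet-style training supports
sampling a fixed-size subset of the training split per epoch (without
replacement, from the seeded generator) and evaluating on a random test
subset.  Everything — shuffling, subsampling, dropout — draws from one
generator seeded by the config, so a rerun reproduces the loss trajectory
exactly.  An optional early-stop threshold on test accuracy exists for
bounded sanity runs; published-scale training (300 epochs on the pooled
27-scenario grid, or 1300 epochs for quintets) uses no early stop.

The full published-scale configurations (30 000 quartet samples at
`m = 80`, or 10 000 quintet samples at `m = 160`) are hours of CPU work
with this float64 implementation and are not exercised by the test suite;
the suite's training checks use the reduced problems described above.

## Known limitations

- Protein alphabet only; gaps and ambiguity codes are rejected, matching
  the gap-free simulations.
- Classification stops at 5 taxa (15 classes); the descriptor construction
  generalizes, but the label space grows as `(2n-5)!!`.
- The NumPy implementation favors auditability over speed; it is not a
  GPU training stack.
- NJ accuracy is the only published-scale quantity reproduced end-to-end;
  the neural results at published scale are out of desk reach (see above).
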