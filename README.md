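# phylosym

Symmetry-preserving neural topology classification for 4- and 5-taxon
phylogenies, with an amino-acid sequence simulator for long-branch-attraction
(LBA) studies and a neighbor-joining baseline.

## The problem

Given a gap-free alignment of four (or five) amino-acid sequences
`[s_A, s_B, s_C, s_D]`, infer which unrooted tree topology generated it.
For four taxa there are 3 topologies (`I = AB|CD`, `II = AC|BD`,
`III = AD|BC`); for five taxa there are 15; in general `(2n-5)!!`.  Classical
methods — distance-based (neighbor joining), likelihood, Bayesian — fail
systematically in the *Felsenstein zone*: when two non-sister lineages evolve
fast, their long branches "attract" and the methods confidently return the
wrong topology.  Treating topology inference as classification lets a neural
network learn to see through this bias, but the input order of the sequences
is arbitrary: swapping `A` and `B` must not change the probability of `AB|CD`,
and swapping `B` and `C` must *exchange* the probabilities of `AB|CD` and
`AC|BD`.  This package builds those symmetries into the architecture instead
of augmenting the training data with all `n!` input orderings.

## The model

Following the Deep Sets representation of permutation-invariant functions,
`f(x_1..x_n) = Φ(Σ_i φ(x_i))`, the classifier composes three learned maps,
each applied per site (weight sharing across the `L` columns):

- `α : D → R^m` — embedding of the 20-letter alphabet, `φ(s)[i,:] = α(s_i)`;
- `β : R^m → R^m` — a shallow dense residual block; the symmetric pair map is
  `Φ(φ(s)+φ(s'))[i,:] = β(α(s_i) + α(s'_i))`;
- per-class descriptors, e.g. for quartets

  ```
  D_I   = Φ(φ(s_A)+φ(s_B)) + Φ(φ(s_C)+φ(s_D))
  D_II  = Φ(φ(s_A)+φ(s_C)) + Φ(φ(s_B)+φ(s_D))
  D_III = Φ(φ(s_A)+φ(s_D)) + Φ(φ(s_C)+φ(s_B))
  ```

- `Ψ` — a stacked LSTM reading the `L` descriptor slices in order; its last
  output feeds a one-hidden-layer ReLU head producing one scalar score per
  class, and a softmax over the `K` scores gives `[p_I, p_II, p_III]`.

For five taxa each of the 15 topologies is two cherries plus a "middle"
taxon; its descriptor is the pair-map sum over the two cherries (the middle
sequence drops out), giving 15 descriptors scored by the same `Ψ`.  Because
vector addition commutes, permuting the input slots permutes the raw class
scores **bitwise** according to the induced action of the permutation on
topology classes — the property is architectural and holds at random
initialization, which the test suite verifies exhaustively over all 24
quartet permutations.  Only the `n(n-1)/2` unordered pair maps are ever
evaluated per forward pass, shared across descriptors.

The network is implemented in NumPy on a small in-repo reverse-mode
autodiff engine (`phylosym.autodiff`) with Adam, cross-entropy loss and an
exponential learning-rate schedule; gradients are guarded by
finite-difference tests.

## The simulator and the baseline

`phylosym.simulate` generates labelled training data from a Dayhoff
continuous-time Markov chain (classic published exchangeabilities and
frequencies, rate matrix `Q_ij = s_ij π_j` normalized to one expected
substitution per site per unit branch length).  Quartets follow the LBA
scheme: short external branches `b`, long branches `a = κ1 b` on one leaf of
each cherry, internal branch `c = κ2 b`, all scaled by a per-alignment rate
`r ~ U(0.05, 1)`; the default grid crosses `b ∈ {0.1, 0.5, 1}`,
`κ1 ∈ {2, 10, 40}`, `κ2 ∈ {0.01, 0.1, 1}` at `L = 1550` sites.  Quintets
draw all seven branch lengths i.i.d. from `U(0, 1)`.

`phylosym.baselines` provides the classical comparator: maximum-likelihood
pairwise distances under the same Dayhoff model (bounded scalar
optimization, capped at 10 substitutions/site for saturated pairs) fed to
Saitou–Nei neighbor joining with a deterministic tie-break.

## Worked example

```python
import numpy as np
import phylosym as ps

cfg = ps.BranchConfig(b=1.0, kappa1=40, kappa2=1.0)   # severe LBA regime
sample = ps.simulate_quartet(label=2, cfg=cfg, L=1550,
                             rng=np.random.default_rng(7))
print(sample.label, sample.meta["long_taxa"])          # 2 CD
print(np.round(ps.pairwise_distances(sample.alignment).d, 2))
pred = ps.classify_nj(sample.alignment)
print(pred, ps.write_newick(ps.enumerate_topologies("ABCD")[pred - 1]))
```

prints

```
2 CD
[[ 0.    2.76 10.   10.  ]
 [ 2.76  0.   10.   10.  ]
 [10.   10.    0.   10.  ]
 [10.   10.   10.    0.  ]]
1 ((A,B),(C,D));
```

The true topology is class `II = AC|BD` with fast-evolving `C` and `D`; every
distance touching a long branch saturates to the cap, the two slowly evolving
taxa `A, B` look like sisters, and neighbor joining returns class `I` — the
textbook long-branch-attraction error.  The classifier's symmetry, visible
even untrained:

```python
net = ps.TopologyClassifier(n_taxa=4, seed=0)
net.forward(sample.alignment).probs            # [0.3359 0.3292 0.3349]
# swap the B and C sequences: classes I and II exchange probabilities
net.forward([sample.alignment.sequences[i] for i in (0, 2, 1, 3)]).probs
#                                                [0.3292 0.3359 0.3349]
```

Training is exposed through `phylosym.train.train` (Adam, lr 0.001 decayed
by 0.9 every 10 epochs, best-test-accuracy checkpoint selection, held-out
validation) and the `phylosym` command line (`simulate`, `train`,
`evaluate`, `predict`, `baseline`).

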