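"""Architectural properties of the classifier: equivariance, locality, loss."""

import itertools

import numpy as np
import pytest

from phylosym.model import (
    Hyperparams,
    TopologyClassifier,
    cross_entropy,
    cross_entropy_from_probs,
    quartet_hyperparams,
    quintet_hyperparams,
)
from phylosym.autodiff import Tensor
from phylosym.topology import induced_action

from conftest import random_sequences


def _permute_slots(seqs, perm):
    out = [None] * len(seqs)
    for i, s in enumerate(seqs):
        out[perm[i]] = s
    return out


def _expected_vector(base, action):
    out = np.empty_like(base)
    for k, v in enumerate(base):
        out[action[k] - 1] = v
    return out


def test_default_hyperparameters_match_training_setups():
    q4, q5 = quartet_hyperparams(), quintet_hyperparams()
    assert (q4.m, q4.lstm_hidden, q4.lstm_layers, q4.dropout) == (80, 20, 3, 0.2)
    assert (q5.m, q5.lstm_hidden, q5.lstm_layers) == (160, 40, 6)
    assert q4.head_width == q4.lstm_hidden  # default head width


def test_embedding_locality_and_weight_sharing(tiny_quartet_net, quartet_sequences):
    net = tiny_quartet_net
    s = quartet_sequences[0]
    e = net.embed(s)
    assert e.shape == (len(s), net.hp.m)
    # changing site j leaves other rows untouched
    mutated = s[:5] + ("A" if s[5] != "A" else "C") + s[6:]
    e2 = net.embed(mutated)
    assert np.array_equal(np.delete(e, 5, axis=0), np.delete(e2, 5, axis=0))
    assert not np.array_equal(e[5], e2[5])
    # permuting sites permutes rows identically
    perm = np.random.default_rng(0).permutation(len(s))
    assert np.array_equal(net.embed("".join(s[i] for i in perm)), e[perm])


def test_pair_descriptor_symmetry_and_locality(tiny_quartet_net, quartet_sequences):
    net = tiny_quartet_net
    s, s2 = quartet_sequences[:2]
    assert np.array_equal(net.pair_descriptor(s, s2), net.pair_descriptor(s2, s))
    with pytest.raises(ValueError):
        net.pair_descriptor(s, s2[:-1])
    # self-pair row i equals beta(2 alpha(s_i))
    d_self = net.pair_descriptor(s, s)
    expected = net._beta(Tensor(2.0 * net.embed(s))).data
    assert np.allclose(d_self, expected)


def test_quartet_descriptor_invariances(tiny_quartet_net, quartet_sequences):
    net = tiny_quartet_net
    sA, sB, sC, sD = quartet_sequences
    D = net.descriptors_quartet(sA, sB, sC, sD)
    # D_I invariant under A<->B, C<->D, and clade swap — bitwise
    for reordered in [(sB, sA, sC, sD), (sA, sB, sD, sC), (sC, sD, sA, sB)]:
        assert np.array_equal(net.descriptors_quartet(*reordered)[0], D[0])
    # swap B,C maps (I, II, III) -> (II, I, III)
    D_swapped = net.descriptors_quartet(sA, sC, sB, sD)
    assert np.array_equal(D_swapped[0], D[1])
    assert np.array_equal(D_swapped[1], D[0])
    assert np.array_equal(D_swapped[2], D[2])
    # all equal sequences -> all descriptors equal
    D_same = net.descriptors_quartet(sA, sA, sA, sA)
    assert np.array_equal(D_same[0], D_same[1]) and np.array_equal(D_same[1], D_same[2])


def test_quartet_equivariance_all_24_permutations(tiny_quartet_net, quartet_sequences):
    """Raw scores transform bitwise per the induced action, at random init."""
    net = tiny_quartet_net
    base = net.forward(quartet_sequences)
    for perm in itertools.permutations(range(4)):
        action = induced_action(perm, 4)
        out = net.forward(_permute_slots(quartet_sequences, perm))
        assert np.array_equal(out.scores, _expected_vector(base.scores, action))
        assert np.allclose(out.probs, _expected_vector(base.probs, action),
                           rtol=0, atol=1e-6)


def test_quintet_equivariance_random_permutations(tiny_quintet_net, quintet_sequences):
    net = tiny_quintet_net
    base = net.forward(quintet_sequences)
    rng = np.random.default_rng(2)
    for _ in range(40):
        perm = tuple(rng.permutation(5))
        action = induced_action(perm, 5)
        out = net.forward(_permute_slots(quintet_sequences, perm))
        assert np.array_equal(out.scores, _expected_vector(base.scores, action))
        assert np.allclose(out.probs, _expected_vector(base.probs, action),
                           rtol=0, atol=1e-6)


@pytest.mark.parametrize("n", [4, 5])
def test_identical_inputs_give_uniform_probabilities(n, tiny_quartet_net,
                                                     tiny_quintet_net):
    net = tiny_quartet_net if n == 4 else tiny_quintet_net
    seqs = [random_sequences(1, 8, seed=9)[0]] * n
    probs = net.forward(seqs).probs
    assert np.allclose(probs, 1.0 / net.n_classes, rtol=0, atol=1e-15)


def test_descriptor_site_locality(tiny_quartet_net, quartet_sequences):
    """Masking site i of all inputs changes only row i of every descriptor."""
    net = tiny_quartet_net
    D = net.descriptors_quartet(*quartet_sequences)
    site = 4
    mutated = [s[:site] + ("A" if s[site] != "A" else "W") + s[site + 1:]
               for s in quartet_sequences]
    D2 = net.descriptors_quartet(*mutated)
    for d, d2 in zip(D, D2):
        assert np.array_equal(np.delete(d, site, axis=0), np.delete(d2, site, axis=0))


def test_six_pair_evaluations_per_quartet_forward(tiny_quartet_net, quartet_sequences):
    """All 3 descriptors share the 6 unordered pair maps (one evaluation each)."""
    net = tiny_quartet_net
    before = net.pair_evals
    net.forward(quartet_sequences)
    assert net.pair_evals - before == 6


def test_scoring_paths_agree(tiny_quartet_net, quartet_sequences):
    """Batched scoring of all descriptors equals scoring them one at a time."""
    net = tiny_quartet_net
    batched = net.forward(quartet_sequences).scores
    separate = [net.score(d) for d in net.descriptors_quartet(*quartet_sequences)]
    assert np.allclose(batched, separate, atol=1e-12)
    # repeatability in evaluation mode
    assert np.array_equal(batched, net.forward(quartet_sequences).scores)


def test_score_accepts_single_site_descriptor(tiny_quartet_net):
    d = np.zeros((1, tiny_quartet_net.hp.m))
    assert np.isfinite(tiny_quartet_net.score(d))


def test_forward_input_validation(tiny_quartet_net, quartet_sequences):
    with pytest.raises(ValueError):
        tiny_quartet_net.forward(quartet_sequences[:3])
    with pytest.raises(ValueError):
        tiny_quartet_net.forward(quartet_sequences[:3] + [quartet_sequences[3][:-2]])
    with pytest.raises(ValueError):
        tiny_quartet_net.forward(["X-XZ"] + quartet_sequences[1:])


def test_cross_entropy_closed_forms():
    # uniform scores -> ln K per sample
    for K, B in [(3, 4), (15, 2)]:
        scores = Tensor(np.zeros((B, K)), requires_grad=True)
        labels = np.arange(B) % K + 1
        assert abs(cross_entropy(scores, labels).data - np.log(K)) < 1e-12
        assert abs(cross_entropy(scores, labels, "sum").data - B * np.log(K)) < 1e-12
    # one-hot probabilities on the correct labels -> loss 0
    probs = np.eye(3)[[0, 2]]
    assert cross_entropy_from_probs(probs, np.array([1, 3])) == 0.0
    with pytest.raises(ValueError):
        cross_entropy(Tensor(np.zeros((2, 3))), np.array([0, 1]))


def test_checkpoint_round_trip(tmp_path, tiny_quartet_net, quartet_sequences):
    path = tmp_path / "model.npz"
    tiny_quartet_net.save(path)
    loaded = TopologyClassifier.load(path)
    assert np.array_equal(loaded.forward(quartet_sequences).scores,
                          tiny_quartet_net.forward(quartet_sequences).scores)


def test_gradients_match_finite_differences():
    """Full-model gradient check on a tiny instance, 1e-4 relative error."""
    hp = Hyperparams(m=4, lstm_hidden=3, lstm_layers=2, dropout=0.0)
    net = TopologyClassifier(4, hp, seed=7)
    rng = np.random.default_rng(1)
    idx = rng.integers(0, 20, size=(2, 4, 6))
    labels = np.array([1, 3])

    loss = cross_entropy(net.forward_scores(idx), labels)
    loss.backward()

    def loss_value():
        return float(cross_entropy(net.forward_scores(idx), labels).data)

    eps = 1e-6
    pick = np.random.default_rng(2)
    for name, p in net.params.items():
        grad = p.grad if p.grad is not None else np.zeros_like(p.data)
        flat = p.data.reshape(-1)
        for k in pick.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[k]
            flat[k] = orig + eps
            up = loss_value()
            flat[k] = orig - eps
            down = loss_value()
            flat[k] = orig
            fd = (up - down) / (2 * eps)
            an = grad.reshape(-1)[k]
            assert abs(fd - an) <= 1e-4 * max(1.0, abs(fd) + abs(an)), name
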