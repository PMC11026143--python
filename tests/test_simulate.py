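"""Simulator correctness: determinism, stationarity, divergence closed forms."""

import numpy as np
import pytest
from scipy.stats import chisquare

from phylosym.io import Alignment
from phylosym.simulate import (
    BranchConfig,
    generate_dataset,
    lba_grid,
    load_dataset,
    make_marker_dataset,
    simulate_quartet,
    simulate_quintet,
    _draw_root,
    _evolve,
)
from phylosym.substitution import transition_matrix
from phylosym.topology import enumerate_topologies, quintet_class_structure


def _diff_fraction(s1: str, s2: str) -> float:
    return np.mean([a != b for a, b in zip(s1, s2)])


def test_branch_config_validation():
    with pytest.raises(ValueError):
        BranchConfig(b=-1, kappa1=2, kappa2=1)
    with pytest.raises(ValueError):
        BranchConfig(b=1, kappa1=0.5, kappa2=1)
    cfg = BranchConfig(b=0.5, kappa1=10, kappa2=0.1)
    assert cfg.a == 5.0 and cfg.c == 0.05


def test_quartet_same_seed_is_byte_identical(dayhoff):
    cfg = BranchConfig(b=0.5, kappa1=10, kappa2=0.1)
    s1 = simulate_quartet(2, cfg, L=100, rng=np.random.default_rng(9), model=dayhoff)
    s2 = simulate_quartet(2, cfg, L=100, rng=np.random.default_rng(9), model=dayhoff)
    assert s1.alignment.sequences == s2.alignment.sequences
    assert s1.meta == s2.meta


def test_quartet_degenerate_zero_branches_gives_identical_sequences(dayhoff):
    cfg = BranchConfig(b=1e-12, kappa1=2, kappa2=1)
    s = simulate_quartet(1, cfg, L=200, rng=np.random.default_rng(0), model=dayhoff)
    assert len(set(s.alignment.sequences)) == 1


def test_quartet_invalid_label_rejected(dayhoff):
    with pytest.raises(ValueError):
        simulate_quartet(4, BranchConfig(1, 2, 1), L=10, model=dayhoff)
    with pytest.raises(ValueError):
        simulate_quintet(16, L=10, model=dayhoff)


def test_quartet_divergence_matches_closed_form(dayhoff):
    """Sister short-branch divergence equals 1 - sum_i pi_i P_ii(d r), 3 SE."""
    cfg = BranchConfig(b=1.0, kappa1=2, kappa2=1.0)
    L = 1550
    for seed in (0, 1, 2):
        s = simulate_quartet(1, cfg, L=L, rng=np.random.default_rng(seed), model=dayhoff)
        r = s.meta["r"]
        short = [nm for nm in "ABCD" if nm not in s.meta["long_taxa"]]
        # the two short taxa sit in different cherries: path is b + c + b
        d = (cfg.b + cfg.c + cfg.b) * r
        p_expected = 1.0 - np.dot(dayhoff.pi, np.diag(transition_matrix(dayhoff, d)))
        i, j = "ABCD".index(short[0]), "ABCD".index(short[1])
        p_obs = _diff_fraction(s.alignment.sequences[i], s.alignment.sequences[j])
        se = np.sqrt(p_expected * (1 - p_expected) / L)
        assert abs(p_obs - p_expected) < 3 * se


def test_single_branch_stationarity_chi_square(dayhoff):
    """Child states of a pi-rooted branch stay pi-distributed (alpha=0.01)."""
    rng = np.random.default_rng(5)
    root = _draw_root(dayhoff, 100_000, rng)
    child = _evolve(root, 0.7, dayhoff, rng)
    counts = np.bincount(child, minlength=20)
    _, p = chisquare(counts, f_exp=dayhoff.pi * counts.sum())
    assert p > 0.01


def test_saturation_limit(dayhoff):
    """At t=100 the divergence approaches 1 - sum pi_i^2."""
    rng = np.random.default_rng(6)
    L = 100_000
    root = _draw_root(dayhoff, L, rng)
    child = _evolve(root, 100.0, dayhoff, rng)
    p_obs = np.mean(root != child)
    p_lim = 1.0 - np.dot(dayhoff.pi, dayhoff.pi)
    assert abs(p_obs - p_lim) < 3 * np.sqrt(p_lim * (1 - p_lim) / L)


def test_sister_swap_leaves_pattern_distribution_unchanged(dayhoff):
    """Swapping which cherry leaf is long only relabels the joint pattern law."""
    rng1, rng2 = np.random.default_rng(7), np.random.default_rng(8)
    L = 200_000
    t_long, t_short = 0.8, 0.2
    root1 = _draw_root(dayhoff, L, rng1)
    a1, b1 = _evolve(root1, t_long, dayhoff, rng1), _evolve(root1, t_short, dayhoff, rng1)
    root2 = _draw_root(dayhoff, L, rng2)
    b2, a2 = _evolve(root2, t_short, dayhoff, rng2), _evolve(root2, t_long, dayhoff, rng2)
    n1 = np.zeros((20, 20)); np.add.at(n1, (a1, b1), 1.0)
    n2 = np.zeros((20, 20)); np.add.at(n2, (a2, b2), 1.0)
    tv = 0.5 * np.abs(n1 / L - n2 / L).sum()
    assert tv < 0.05  # sampling noise scale ~ sqrt(400 / 2L) ~ 0.03


def test_quintet_label_round_trip(dayhoff):
    """The generating tree's splits equal the enumerated topology of the label."""
    tops = enumerate_topologies(("A", "B", "C", "D", "E"))
    for label in (1, 4, 8, 15):
        s = simulate_quintet(label, L=10, rng=np.random.default_rng(label), model=dayhoff)
        (pair1, pair2), middle = quintet_class_structure()[label - 1]
        assert s.label == label
        # cherries recorded in the class structure match the enumerated splits
        cherries = {
            frozenset("ABCDE"[x] for x in pair) for pair in (pair1, pair2)
        }
        enumerated_cherries = {
            side for split in tops[label - 1].splits for side in split if len(side) == 2
        }
        assert cherries == enumerated_cherries


def test_quintet_same_seed_determinism(dayhoff):
    s1 = simulate_quintet(7, L=50, rng=np.random.default_rng(3), model=dayhoff)
    s2 = simulate_quintet(7, L=50, rng=np.random.default_rng(3), model=dayhoff)
    assert s1.alignment.sequences == s2.alignment.sequences


def test_quintet_marginal_frequencies_near_equilibrium(dayhoff):
    """Stationarity: one leaf's site frequencies over samples approach pi.

    Counts are taken from a single taxon — sites are independent but the
    taxa of one column are correlated through the tree, so pooling all five
    sequences would invalidate the chi-square.
    """
    counts = np.zeros(20)
    total = 0
    for seed in range(10):
        s = simulate_quintet(1 + seed % 15, L=2000,
                             rng=np.random.default_rng(seed), model=dayhoff)
        idx = dayhoff.encode(s.alignment.sequences[0])
        counts += np.bincount(idx, minlength=20)
        total += len(idx)
    _, p = chisquare(counts, f_exp=dayhoff.pi * total)
    assert p > 0.01


def test_generate_dataset_uniform_labels_and_determinism(dayhoff):
    cfg = BranchConfig(b=0.1, kappa1=2, kappa2=1.0)
    ds = generate_dataset(3000, mode="quartet", scenarios=cfg, L=5, seed=7, model=dayhoff)
    labels = np.array([s.label for s in ds.samples])
    counts = np.bincount(labels, minlength=4)[1:]
    sigma = np.sqrt(3000 * (1 / 3) * (2 / 3))
    assert np.abs(counts - 1000).max() < 3 * sigma
    ds2 = generate_dataset(3000, mode="quartet", scenarios=cfg, L=5, seed=7, model=dayhoff)
    assert [s.label for s in ds2.samples] == labels.tolist()
    # split proportions follow the 90/9/1 scheme
    assert len(ds.train_idx) == 2700 and len(ds.test_idx) == 270 and len(ds.val_idx) == 30
    assert not (set(ds.train_idx) & set(ds.test_idx) | set(ds.train_idx) & set(ds.val_idx))


def test_lba_grid_is_the_full_cross():
    grid = lba_grid()
    assert len(grid) == 27
    assert {(c.b, c.kappa1, c.kappa2) for c in grid} == {
        (b, k1, k2) for b in (0.1, 0.5, 1.0) for k1 in (2, 10, 40)
        for k2 in (0.01, 0.1, 1.0)
    }


def test_dataset_write_load_round_trip(dayhoff, tmp_path):
    cfg = BranchConfig(b=0.1, kappa1=2, kappa2=1.0)
    ds = generate_dataset(12, mode="quartet", scenarios=cfg, L=8, seed=1,
                          out_dir=tmp_path / "ds", model=dayhoff)
    loaded = load_dataset(tmp_path / "ds")
    assert [s.label for s in loaded.samples] == [s.label for s in ds.samples]
    assert loaded.samples[0].alignment == ds.samples[0].alignment
    # checksum validation catches tampering
    victim = next((tmp_path / "ds" / "samples").iterdir())
    victim.write_text(victim.read_text().replace(">", "> ", 1))
    with pytest.raises(ValueError):
        load_dataset(tmp_path / "ds")


def test_marker_dataset_is_separable_by_construction():
    ds = make_marker_dataset(50, L=30, marker_density=0.3, seed=0)
    for s in ds.samples:
        a = [list(seq) for seq in s.alignment.sequences]
        from phylosym.topology import QUARTET_PAIRS
        (i1, j1), (i2, j2) = QUARTET_PAIRS[s.label - 1]
        shared = [
            site for site in range(30)
            if a[i1][site] == a[j1][site] and a[i2][site] == a[j2][site]
            and a[i1][site] != a[i2][site]
        ]
        assert shared  # at least one marker column decodes the label
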