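"""Simulation of labelled amino-acid alignments on quartet and quintet trees.

The long-branch-attraction (Felsenstein-zone) quartet design: each of the two
cherries has one short external branch ``b`` and one long one ``a = kappa1*b``,
and the two cherries are joined by a short internal branch ``c = kappa2*b``.
The two long branches are non-sister, which is exactly the regime where
distance and likelihood methods tend to join them erroneously.  A single
relative rate ``r ~ U(0.05, 1)`` multiplies every branch of an alignment
(rate variation across alignments, not across sites).  Sites are i.i.d.: the
root state of each column is drawn from the model's equilibrium frequencies
and evolved independently down the tree with ``P(t) = expm(Q t)``.

The quartet root sits at the midpoint of the internal branch.  Quintets draw
all seven branch lengths i.i.d. from ``U(0, 1)`` and are rooted at the
attachment node of the middle taxon; under a stationary reversible model the
root placement does not affect the data distribution, the choice only pins
down the random-number stream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import Alignment, write_fasta
from .substitution import SubstitutionModel, dayhoff_model, transition_matrix
from .topology import QUARTET_PAIRS, quintet_class_structure

__all__ = [
    "BranchConfig",
    "LabeledSample",
    "Dataset",
    "lba_grid",
    "simulate_quartet",
    "simulate_quintet",
    "generate_dataset",
    "load_dataset",
    "make_marker_dataset",
]

QUARTET_TAXA = ("A", "B", "C", "D")
QUINTET_TAXA = ("A", "B", "C", "D", "E")

RATE_LOW, RATE_HIGH = 0.05, 1.0  # per-alignment relative rate bounds
DEFAULT_LENGTH = 1550            # default alignment length (sites)


@dataclass(frozen=True)
class BranchConfig:
    """Felsenstein-zone branch-length scheme: b short, a = kappa1*b, c = kappa2*b."""

    b: float
    kappa1: float
    kappa2: float

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.kappa1 < 1:
            raise ValueError("kappa1 must be >= 1 (a is the long branch)")
        if self.kappa2 <= 0:
            raise ValueError("kappa2 must be > 0")

    @property
    def a(self) -> float:
        return self.kappa1 * self.b

    @property
    def c(self) -> float:
        return self.kappa2 * self.b


@dataclass(frozen=True)
class LabeledSample:
    """An alignment with its generating topology class and parameters."""

    alignment: Alignment
    label: int  # 1-based topology class index
    meta: dict = field(default_factory=dict)


@dataclass
class Dataset:
    """A simulated dataset with recorded train/test/validation boundaries."""

    samples: list[LabeledSample]
    train_idx: np.ndarray
    test_idx: np.ndarray
    val_idx: np.ndarray
    manifest: dict


def lba_grid() -> list[BranchConfig]:
    """The 3 x 3 x 3 simulation grid over b, kappa1, kappa2."""
    return [
        BranchConfig(b=b, kappa1=k1, kappa2=k2)
        for b in (0.1, 0.5, 1.0)
        for k1 in (2, 10, 40)
        for k2 in (0.01, 0.1, 1.0)
    ]


def _sample_categorical(cdf_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of a (L, k) array of row-wise CDFs."""
    u = rng.random(cdf_rows.shape[0])
    out = (cdf_rows < u[:, None]).sum(axis=1)
    return np.minimum(out, cdf_rows.shape[1] - 1)


def _draw_root(model: SubstitutionModel, L: int, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(model.pi)
    return _sample_categorical(np.broadcast_to(cdf, (L, len(cdf))), rng)


def _evolve(states: np.ndarray, t: float, model: SubstitutionModel,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve per-site states along a branch of length ``t`` (columns i.i.d.)."""
    P = transition_matrix(model, t)
    cdf = np.cumsum(P, axis=1)
    return _sample_categorical(cdf[states], rng)


def simulate_quartet(label: int, cfg: BranchConfig, L: int = DEFAULT_LENGTH,
                     rng: np.random.Generator | None = None,
                     model: SubstitutionModel | None = None) -> LabeledSample:
    """Simulate one labelled quartet alignment under the LBA branch scheme.

    Which leaf of each cherry carries the long branch is randomized per
    sample and recorded in the metadata (``long_taxa``).
    """
    if label not in (1, 2, 3):
        raise ValueError(f"quartet label must be in 1..3, got {label}")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    model = dayhoff_model() if model is None else model

    (i1, j1), (i2, j2) = QUARTET_PAIRS[label - 1]
    long1 = (i1, j1)[rng.integers(2)]
    long2 = (i2, j2)[rng.integers(2)]
    r = rng.uniform(RATE_LOW, RATE_HIGH)

    ext = {s: cfg.b for s in range(4)}
    ext[long1] = cfg.a
    ext[long2] = cfg.a

    root = _draw_root(model, L, rng)
    v1 = _evolve(root, cfg.c * r / 2.0, model, rng)  # root at internal midpoint
    v2 = _evolve(root, cfg.c * r / 2.0, model, rng)
    states = {}
    for slot in (i1, j1):
        states[slot] = _evolve(v1, ext[slot] * r, model, rng)
    for slot in (i2, j2):
        states[slot] = _evolve(v2, ext[slot] * r, model, rng)

    seqs = tuple(model.decode(states[s]) for s in range(4))
    meta = {
        "b": cfg.b, "kappa1": cfg.kappa1, "kappa2": cfg.kappa2, "r": r,
        "long_taxa": "".join(sorted(QUARTET_TAXA[s] for s in (long1, long2))),
    }
    return LabeledSample(Alignment(QUARTET_TAXA, seqs), label, meta)


def simulate_quintet(label: int, L: int = DEFAULT_LENGTH,
                     rng: np.random.Generator | None = None,
                     model: SubstitutionModel | None = None) -> LabeledSample:
    """Simulate one labelled quintet alignment, branch lengths i.i.d. U(0, 1).

    The seven branches are drawn in a fixed order (externals for slots
    A..E, then the two internal edges), a per-alignment rate
    ``r ~ U(0.05, 1)`` scales all of them, and the root is the middle
    taxon's attachment node.
    """
    if not 1 <= label <= 15:
        raise ValueError(f"quintet label must be in 1..15, got {label}")
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    model = dayhoff_model() if model is None else model

    (pair1, pair2), middle = quintet_class_structure()[label - 1]
    ext = {s: rng.uniform(0.0, 1.0) for s in range(5)}
    int1 = rng.uniform(0.0, 1.0)  # attachment node -> cherry 1 ancestor
    int2 = rng.uniform(0.0, 1.0)  # attachment node -> cherry 2 ancestor
    r = rng.uniform(RATE_LOW, RATE_HIGH)

    root = _draw_root(model, L, rng)
    v1 = _evolve(root, int1 * r, model, rng)
    v2 = _evolve(root, int2 * r, model, rng)
    states = {middle: _evolve(root, ext[middle] * r, model, rng)}
    for slot in pair1:
        states[slot] = _evolve(v1, ext[slot] * r, model, rng)
    for slot in pair2:
        states[slot] = _evolve(v2, ext[slot] * r, model, rng)

    seqs = tuple(model.decode(states[s]) for s in range(5))
    meta = {"r": r, "branch_lengths": {**{QUINTET_TAXA[s]: ext[s] for s in range(5)},
                                       "internal1": int1, "internal2": int2}}
    return LabeledSample(Alignment(QUINTET_TAXA, seqs), label, meta)


def _split_indices(n: int, proportions=(0.90, 0.09, 0.01)) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_train = int(round(proportions[0] * n))
    n_test = int(round(proportions[1] * n))
    idx = np.arange(n)
    return idx[:n_train], idx[n_train : n_train + n_test], idx[n_train + n_test :]


def generate_dataset(n_samples: int, *, mode: str = "quartet",
                     scenarios: BranchConfig | Sequence[BranchConfig] | None = None,
                     L: int = DEFAULT_LENGTH, seed: int = 0,
                     out_dir: str | Path | None = None,
                     model: SubstitutionModel | None = None) -> Dataset:
    """Generate ``n_samples`` labelled alignments per scenario, labels uniform.

    ``mode="quartet"`` uses ``scenarios`` (default: the full 3x3x3 LBA grid);
    ``mode="quintet"`` ignores scenarios.  Each sample gets an independent
    substream seeded by ``(seed, scenario_index, sample_index)`` so any
    single sample can be regenerated in isolation.  The first 90% of each
    scenario are the training split, the next 9% test, the last 1%
    validation.  With ``out_dir`` set, FASTA files, a labels/metadata TSV
    and a YAML manifest are written.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("quartet", "quintet"):
        raise ValueError(f"unknown mode {mode!r}")
    model = dayhoff_model() if model is None else model

    if mode == "quartet":
        if scenarios is None:
            scenario_list = lba_grid()
        elif isinstance(scenarios, BranchConfig):
            scenario_list = [scenarios]
        else:
            scenario_list = list(scenarios)
        n_classes = 3
    else:
        scenario_list = [None]
        n_classes = 15

    samples: list[LabeledSample] = []
    train_parts, test_parts, val_parts = [], [], []
    offset = 0
    for sc_idx, sc in enumerate(scenario_list):
        for smp_idx in range(n_samples):
            rng = np.random.default_rng([seed, sc_idx, smp_idx])
            label = int(rng.integers(1, n_classes + 1))
            if mode == "quartet":
                sample = simulate_quartet(label, sc, L=L, rng=rng, model=model)
            else:
                sample = simulate_quintet(label, L=L, rng=rng, model=model)
            sample.meta.update({"scenario": sc_idx, "sample": smp_idx, "seed": seed})
            samples.append(sample)
        tr, te, va = _split_indices(n_samples)
        train_parts.append(tr + offset)
        test_parts.append(te + offset)
        val_parts.append(va + offset)
        offset += n_samples

    manifest = {
        "mode": mode,
        "n_samples_per_scenario": n_samples,
        "L": L,
        "seed": seed,
        "split_proportions": [0.90, 0.09, 0.01],
        "scenarios": [
            None if sc is None else {"b": sc.b, "kappa1": sc.kappa1, "kappa2": sc.kappa2}
            for sc in scenario_list
        ],
    }
    dataset = Dataset(
        samples=samples,
        train_idx=np.concatenate(train_parts),
        test_idx=np.concatenate(test_parts),
        val_idx=np.concatenate(val_parts),
        manifest=manifest,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(ds: Dataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_dir = out_dir / "samples"
    sample_dir.mkdir(exist_ok=True)
    train, test = set(ds.train_idx.tolist()), set(ds.test_idx.tolist())
    rows = []
    for i, s in enumerate(ds.samples):
        fname = f"sample_{i:06d}.fasta"
        write_fasta(s.alignment, sample_dir / fname)
        digest = hashlib.sha256((sample_dir / fname).read_bytes()).hexdigest()
        split = "train" if i in train else ("test" if i in test else "validation")
        rows.append({
            "sample_id": i, "file": f"samples/{fname}", "label": s.label,
            "split": split, "sha256": digest,
            **{k: v for k, v in s.meta.items() if not isinstance(v, dict)},
        })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    manifest = dict(ds.manifest)
    manifest["labels_sha256"] = hashlib.sha256((out_dir / "labels.tsv").read_bytes()).hexdigest()
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def load_dataset(out_dir: str | Path) -> Dataset:
    """Reload a dataset written by :func:`generate_dataset` (verifies checksums)."""
    from .io import read_alignment

    out_dir = Path(out_dir)
    with open(out_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    labels_digest = hashlib.sha256((out_dir / "labels.tsv").read_bytes()).hexdigest()
    if labels_digest != manifest["labels_sha256"]:
        raise ValueError("labels.tsv does not match the manifest checksum")
    table = pd.read_csv(out_dir / "labels.tsv", sep="\t")
    samples, split_lists = [], {"train": [], "test": [], "validation": []}
    for _, row in table.iterrows():
        path = out_dir / row["file"]
        if hashlib.sha256(path.read_bytes()).hexdigest() != row["sha256"]:
            raise ValueError(f"{row['file']} does not match its recorded checksum")
        meta = {k: row[k] for k in table.columns
                if k not in ("sample_id", "file", "label", "split", "sha256")}
        samples.append(LabeledSample(read_alignment(path), int(row["label"]), meta))
        split_lists[row["split"]].append(int(row["sample_id"]))
    return Dataset(
        samples=samples,
        train_idx=np.array(split_lists["train"], dtype=int),
        test_idx=np.array(split_lists["test"], dtype=int),
        val_idx=np.array(split_lists["validation"], dtype=int),
        manifest=manifest,
    )


def make_marker_dataset(n_samples: int, *, L: int = 50, marker_density: float = 0.2,
                        seed: int = 0) -> Dataset:
    """A synthetic, perfectly separable quartet toy set for training sanity checks.

    Background sites are i.i.d. uniform over the alphabet; each site is a
    marker with probability ``marker_density``, and at marker sites the two
    cherries of the generating class each share one residue (distinct
    between cherries), so the label is decodable from single columns.
    Markers are spread over the whole sequence so the signal survives the
    recurrent scoring of arbitrarily long inputs.  This is *not* an
    evolutionary simulation.
    """
    from .substitution import AMINO_ACIDS

    rng = np.random.default_rng(seed)
    n_aa = len(AMINO_ACIDS)
    samples = []
    for _ in range(n_samples):
        label = int(rng.integers(1, 4))
        cols = rng.integers(n_aa, size=(4, L))
        (i1, j1), (i2, j2) = QUARTET_PAIRS[label - 1]
        for site in np.nonzero(rng.random(L) < marker_density)[0]:
            r1, r2 = rng.choice(n_aa, size=2, replace=False)
            cols[[i1, j1], site] = r1
            cols[[i2, j2], site] = r2
        seqs = tuple("".join(AMINO_ACIDS[c] for c in row) for row in cols)
        samples.append(LabeledSample(Alignment(QUARTET_TAXA, seqs), label, {}))
    tr, te, va = _split_indices(n_samples)
    return Dataset(samples, tr, te, va,
                   {"mode": "marker-toy", "L": L, "seed": seed})
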