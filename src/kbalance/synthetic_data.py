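"""Synthetic labeled DNA datasets with controllable class separation.

Each class is modelled by one or more first-order Markov chains over
{A, C, G, T}. Markov chains are the minimal generator whose k-mer
statistics are non-trivial and class-distinct for every k >= 1, and
their stationary expectations are analytically tractable, which makes
the generator itself testable.

The benchmark presets emulate two properties of real genomic fragments
that matter for this pipeline:

- *compositional separation*: classes target different GC contents
  (0.30 / 0.43 / 0.57 / 0.70), the dominant axis of variation in
  genomic k-mer space;
- *within-class heterogeneity*: each class is a mixture of sub-chains
  whose GC content scatters around the class target (emulating
  isochore-like GC variation along real genomes), and classes differ
  in homopolymer persistence (run-length statistics), so word lengths
  k >= 2 carry signal beyond mononucleotide composition.

The ``blob_imbalanced`` preset additionally gives one class 85% of the
sampling weight, producing the densely-covered-region pathology that
feature-space balancing is designed to correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import LabeledDataset, SeqRecord

__all__ = ["ClassModel", "SyntheticSpec", "gc_chain", "generate", "preset_benchmark", "PRESETS"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOCH_TOL = 1e-12

# preset geometry: class GC targets, homopolymer persistence per class, and
# the sub-chain GC offsets emulating isochore-like within-class variation
_PRESET_LABELS = ("Archaea", "Bacteria", "Eukaryota", "Viruses")
_PRESET_GC = (0.30, 0.43, 0.57, 0.70)
_PRESET_PERSISTENCE = (0.60, 0.45, 0.60, 0.45)
_GC_OFFSETS = (-0.06, -0.03, 0.0, 0.03, 0.06)
_GC_OFFSET_WEIGHTS = (0.1, 0.2, 0.4, 0.2, 0.1)

PRESETS = ("separated4", "blob_imbalanced")


@dataclass(frozen=True)
class ClassModel:
    """One first-order Markov chain emitting sequences for one label."""

    label: str
    transition: np.ndarray  # 4x4 row-stochastic, state order A,C,G,T
    initial: np.ndarray  # length-4 stochastic
    weight: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        init = np.asarray(self.initial, dtype=float)
        if t.shape != (4, 4) or init.shape != (4,):
            raise ValueError("transition must be 4x4 and initial length 4")
        if (t < 0).any() or (init < 0).any():
            raise ValueError("probabilities must be non-negative")
        if np.abs(t.sum(axis=1) - 1.0).max() > _STOCH_TOL:
            raise ValueError("each transition row must sum to 1")
        if abs(init.sum() - 1.0) > _STOCH_TOL:
            raise ValueError("initial distribution must sum to 1")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        object.__setattr__(self, "transition", t)
        object.__setattr__(self, "initial", init)


@dataclass(frozen=True)
class SyntheticSpec:
    classes: tuple[ClassModel, ...]
    n_total: int
    length: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("need at least one class model")
        n_labels = len({m.label for m in self.classes})
        if self.n_total < n_labels:
            raise ValueError(f"n_total must be >= number of classes ({n_labels})")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        object.__setattr__(self, "classes", tuple(self.classes))


def gc_chain(gc: float, persistence: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Markov chain with stationary GC content ``gc``.

    Rows are ``(1 - persistence) * pi + persistence * e_i``: with
    probability ``persistence`` the previous base repeats, otherwise a
    fresh base is drawn from the GC-determined composition ``pi``.
    ``pi`` is stationary for any persistence, so GC content is exactly
    ``gc`` in expectation while higher persistence lengthens
    homopolymer runs (stronger local compositional autocorrelation, as
    in real genomes).
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    if not (0.0 <= persistence < 1.0):
        raise ValueError("persistence must be in [0, 1)")
    at = (1.0 - gc) / 2.0
    pi = np.array([at, gc / 2.0, gc / 2.0, at])
    transition = (1.0 - persistence) * np.tile(pi, (4, 1)) + persistence * np.eye(4)
    return transition, pi


def _sample_chain(model: ClassModel, m: int, length: int,
                  rng: np.random.Generator) -> list[str]:
    """Vectorized sampling of ``m`` sequences from one chain."""
    states = np.empty((m, length), dtype=np.int64)
    states[:, 0] = rng.choice(4, size=m, p=model.initial)
    cum = np.cumsum(model.transition, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    for t in range(1, length):
        u = rng.random(m)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    chars = _BASES[states]
    return [row.tobytes().decode("ascii") for row in chars]


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw ``n_total`` sequences; per-model counts are multinomial in
    the normalized weights, record order is a seeded shuffle."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([m.weight for m in spec.classes], dtype=float)
    weights /= weights.sum()
    counts = rng.multinomial(spec.n_total, weights)

    sequences: list[str] = []
    labels: list[str] = []
    for model, m in zip(spec.classes, counts):
        if m == 0:
            continue
        sequences.extend(_sample_chain(model, int(m), spec.length, rng))
        labels.extend([model.label] * int(m))

    order = rng.permutation(len(sequences))
    width = max(5, len(str(spec.n_total)))
    records = [SeqRecord(id=f"seq{i:0{width}d}", sequence=sequences[j])
               for i, j in enumerate(order)]
    return LabeledDataset(records=records,
                          labels=[labels[j] for j in order],
                          rank="superkingdom")


def _preset_models(class_weights: tuple[float, ...]) -> tuple[ClassModel, ...]:
    models = []
    for label, gc, pers, w_class in zip(_PRESET_LABELS, _PRESET_GC,
                                        _PRESET_PERSISTENCE, class_weights):
        for off, w_sub in zip(_GC_OFFSETS, _GC_OFFSET_WEIGHTS):
            transition, pi = gc_chain(gc + off, pers)
            models.append(ClassModel(label=label, transition=transition,
                                     initial=pi, weight=w_class * w_sub))
    return tuple(models)


def preset_benchmark(name: str, n_total: int, seed: int = 0,
                     length: int = 1500) -> SyntheticSpec:
    """Named benchmark dataset specs.

    ``separated4``: four equally weighted classes at GC targets
    0.30/0.43/0.57/0.70, well separated in 3-mer space.
    ``blob_imbalanced``: the same four classes, but the GC-0.43 class
    carries 85% of the sampling weight, so its neighbourhood of feature
    space is densely covered while the rest stays sparse.
    """
    if name == "separated4":
        class_weights = (0.25, 0.25, 0.25, 0.25)
    elif name == "blob_imbalanced":
        class_weights = (0.05, 0.85, 0.05, 0.05)
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    return SyntheticSpec(classes=_preset_models(class_weights),
                         n_total=n_total, length=length, seed=seed)
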