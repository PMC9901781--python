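"""Missingness structure: profiling real data and amputating dense data.

Two independent axes of sparsity are controlled when generating sparse test
sets from dense ones:

* **quantity** — how many features are deleted per instance, either a fixed
  count k or counts drawn from a source histogram truncated at a cap
  ("mirrored", statistically equivalent to the profiled dataset);
* **distribution** — which features are preferentially deleted, via a
  per-feature weight vector.  Four named distributions are supported:
  ``real_world`` (weights proportional to a profiled dataset's per-feature
  missing rates), ``random`` (uniform), ``terminal`` (3-fold weight on the six
  outermost frequencies) and ``central`` (3-fold weight on the five central
  frequencies).

Feature selection within an instance is by successive weighted draws without
replacement, so for k = 1 the per-feature removal marginal equals the weight
vector exactly; for k > 1 it only approximates weight proportionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AudiogramMatrix, EmptyInputError

DISTRIBUTIONS = ("real_world", "random", "terminal", "central")

#: Outermost six / central five frequencies (Hz) of the standard 11-frequency
#: grid, used by the terminal and central amputation distributions.
TERMINAL_FREQUENCIES = frozenset({125, 250, 500, 4000, 6000, 8000})
CENTRAL_FREQUENCIES = frozenset({750, 1000, 1500, 2000, 3000})

#: Floor applied to zero real-world rates so sampling stays well defined.
WEIGHT_FLOOR = 1e-6


@dataclass(frozen=True)
class SparsityProfile:
    """Empirical missingness structure of a dataset."""

    feature_missing_rate: np.ndarray  # per-feature proportion missing
    count_histogram: np.ndarray       # P(instance has exactly k missing), k=0..p
    n_source: int
    frequencies: tuple[int, ...]

    def __post_init__(self):
        r = np.asarray(self.feature_missing_rate, float)
        h = np.asarray(self.count_histogram, float)
        object.__setattr__(self, "feature_missing_rate", r)
        object.__setattr__(self, "count_histogram", h)
        if np.any((r < 0) | (r > 1)):
            raise ValueError("feature_missing_rate entries must lie in [0, 1]")
        if not np.isclose(h.sum(), 1.0):
            raise ValueError("count_histogram must sum to 1")
        if len(h) != len(r) + 1:
            raise ValueError("count_histogram must cover k = 0..n_features")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(per-feature rates, per-count histogram) as tidy tables."""
        rates = pd.DataFrame({
            "frequency_hz": self.frequencies,
            "missing_rate": self.feature_missing_rate,
        })
        hist = pd.DataFrame({
            "n_missing": np.arange(len(self.count_histogram)),
            "proportion": self.count_histogram,
        })
        return rates, hist


@dataclass(frozen=True)
class FixedQuantity:
    """Delete exactly k features from every instance."""
    k: int


@dataclass(frozen=True)
class MirroredQuantity:
    """Per-instance counts drawn from ``histogram`` truncated at ``cap``.

    The truncated histogram is renormalized and keeps k = 0 with its source
    probability (such instances contribute no scored entries).
    """
    cap: int
    histogram: np.ndarray

    def truncated(self) -> np.ndarray:
        h = np.asarray(self.histogram, float)[: self.cap + 1]
        s = h.sum()
        if s <= 0:
            raise ValueError("histogram has no mass at or below the cap")
        return h / s


@dataclass(frozen=True)
class MaskPolicy:
    """Which entries to delete when amputating a dense matrix."""

    distribution: str
    weights: np.ndarray
    quantity: FixedQuantity | MirroredQuantity

    def __post_init__(self):
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(f"unknown distribution {self.distribution!r}")
        w = np.asarray(self.weights, float)
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        object.__setattr__(self, "weights", w / w.sum())
        p = len(w)
        if isinstance(self.quantity, FixedQuantity):
            if not 1 <= self.quantity.k <= p - 1:
                raise ValueError(f"fixed k must be in [1, {p - 1}]")
        elif isinstance(self.quantity, MirroredQuantity):
            if not 1 <= self.quantity.cap <= p - 1:
                raise ValueError(f"mirrored cap must be in [1, {p - 1}]")
        else:
            raise TypeError("quantity must be FixedQuantity or MirroredQuantity")


@dataclass(frozen=True)
class Mask:
    """Realized deletion pattern; True = entry deleted."""
    removed: np.ndarray

    def to_frame(self, frequencies) -> pd.DataFrame:
        rows, cols = np.nonzero(self.removed)
        return pd.DataFrame({
            "row_index": rows,
            "frequency_hz": [frequencies[c] for c in cols],
        })


def profile_sparsity(m: AudiogramMatrix) -> SparsityProfile:
    """Per-feature missing rates and per-instance missing-count histogram."""
    if m.n_instances == 0:
        raise EmptyInputError("cannot profile an empty matrix")
    miss = m.missing_mask()
    rates = miss.mean(axis=0)
    counts = miss.sum(axis=1)
    hist = np.bincount(counts, minlength=m.n_features + 1) / m.n_instances
    return SparsityProfile(rates, hist, m.n_instances, m.frequencies)


def make_weights(distribution: str,
                 profile: SparsityProfile | None = None,
                 frequencies=None) -> np.ndarray:
    """Normalized per-feature removal weights for a named distribution."""
    if distribution == "real_world":
        if profile is None:
            raise ValueError("real_world weights require a SparsityProfile")
        w = np.maximum(profile.feature_missing_rate, WEIGHT_FLOOR)
        return w / w.sum()
    if frequencies is None:
        if profile is None:
            raise ValueError(f"{distribution} weights require frequencies")
        frequencies = profile.frequencies
    p = len(frequencies)
    if distribution == "random":
        return np.full(p, 1.0 / p)
    if distribution == "terminal":
        w = np.where([f in TERMINAL_FREQUENCIES for f in frequencies], 3.0, 1.0)
    elif distribution == "central":
        w = np.where([f in CENTRAL_FREQUENCIES for f in frequencies], 3.0, 1.0)
    else:
        raise ValueError(f"unknown distribution {distribution!r}")
    return w / w.sum()


def sample_mask(shape: tuple[int, int], policy: MaskPolicy,
                rng: np.random.Generator) -> Mask:
    """Draw a deletion mask for a dense matrix of the given shape.

    Per instance independently: draw the count k (fixed, or from the mirrored
    truncated histogram), then select k distinct features by successive
    weighted draws without replacement.
    """
    n, p = shape
    if len(policy.weights) != p:
        raise ValueError("policy weights do not match matrix width")
    if isinstance(policy.quantity, FixedQuantity):
        if policy.quantity.k >= p:
            raise ValueError("fixed k must be below the number of features")
        ks = np.full(n, policy.quantity.k)
    else:
        trunc = policy.quantity.truncated()
        ks = rng.choice(len(trunc), size=n, p=trunc)
    removed = np.zeros((n, p), dtype=bool)
    for i in range(n):
        k = ks[i]
        if k:
            cols = rng.choice(p, size=k, replace=False, p=policy.weights)
            removed[i, cols] = True
    return Mask(removed)


def apply_mask(m: AudiogramMatrix, mask: Mask,
               ) -> tuple[AudiogramMatrix, pd.DataFrame]:
    """Delete masked entries, returning the sparse copy and the ground truth.

    Truth is a tidy table of (row, feature index, frequency, true value) for
    every deleted entry, used later to score imputations.
    """
    if mask.removed.shape != m.values.shape:
        raise ValueError("mask shape does not match matrix shape")
    if np.any(mask.removed & m.missing_mask()):
        raise ValueError("mask removes an entry that is already missing")
    values = m.values.copy()
    rows, cols = np.nonzero(mask.removed)
    truth = pd.DataFrame({
        "row": rows,
        "feature": cols,
        "frequency_hz": [m.frequencies[c] for c in cols],
        "value": values[rows, cols],
    })
    values[rows, cols] = np.nan
    sparse = AudiogramMatrix(values, m.frequencies,
                             ids=None if m.ids is None else m.ids.copy())
    return sparse, truth
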