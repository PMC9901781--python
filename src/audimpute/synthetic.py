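"""Synthetic audiograms with the statistical structure of pooled CI-candidate
registries.

Thresholds are drawn from a multivariate normal on the log2-frequency axis
with a powered-exponential correlation kernel in octave distance (strong
between adjacent frequencies, falling off sharply with separation), quantized
to the 5-dB steps audiometers report and clipped to [0, 120] dB.  The mean profile
slopes upward with frequency (CI candidates hear high frequencies worst), and
per-feature missingness is concentrated on the inter-octave frequencies, which
clinics test least often.

The mean profile and marginal SD are calibration choices for a synthetic
population, not measured values; the per-feature missing-rate defaults and the
adjacent-frequency correlation target (~0.9 between 125 and 250 Hz) are the
features of real registry data the generator is calibrated to reproduce.
Missingness is independent per entry (MCAR given the rates); count-matched
masking is the sparsity module's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .io import (AudiogramMatrix, DEFAULT_FREQUENCIES, THRESHOLD_MAX,
                 THRESHOLD_MIN)

# Powered-exponential kernel exp(-(d/l)^g) calibrated to two registry
# correlations: 0.92 at one octave (125-250 Hz) and ~0.215 at 4.6 octaves
# (125-3000 Hz) -> g ~= 1.92, l ~= 3.66 octaves.  A single-rate exponential
# cannot hold 0.9 adjacent while decaying to ~0.2 at range, and that sharp
# fall-off is what penalizes deleting runs of adjacent frequencies.
DEFAULT_CORR_LENGTH = 3.66
DEFAULT_CORR_SHAPE = 1.92

DEFAULT_MEAN_PROFILE = (55.0, 58.0, 62.0, 66.0, 70.0, 75.0, 80.0, 88.0,
                        94.0, 100.0, 103.0)

#: Registry-style per-feature missing rates; inter-octave frequencies dominate.
DEFAULT_MISSING_RATES = {
    125: 0.450, 250: 0.05, 500: 0.05, 750: 0.654, 1000: 0.05, 1500: 0.729,
    2000: 0.05, 3000: 0.307, 4000: 0.05, 6000: 0.295, 8000: 0.05,
}


@dataclass
class GeneratorParams:
    """Knobs of the synthetic-audiogram generator."""

    n: int = 1000
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES
    mean_profile: tuple[float, ...] = DEFAULT_MEAN_PROFILE
    marginal_sd: float = 22.0
    corr_length: float = DEFAULT_CORR_LENGTH
    corr_shape: float = DEFAULT_CORR_SHAPE
    missing_rates: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    round_step: float = 5.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.mean_profile) != len(self.frequencies):
            raise ValueError("mean_profile length must match frequencies")
        if self.corr_length <= 0:
            raise ValueError("corr_length must be positive")
        if not 0 < self.corr_shape <= 2:
            raise ValueError("corr_shape must lie in (0, 2] for a valid "
                             "correlation function")
        if self.round_step <= 0 or (THRESHOLD_MAX % self.round_step) != 0:
            raise ValueError("round_step must be positive and divide 120")
        for f, r in self.missing_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {f} Hz outside [0, 1]")

    def rate_vector(self) -> np.ndarray:
        """Per-feature missing rates aligned with ``frequencies`` (default 0.05)."""
        return np.array([self.missing_rates.get(f, 0.05)
                         for f in self.frequencies])

    def correlation(self) -> np.ndarray:
        """rho(i, j) = exp(-(|log2 f_i - log2 f_j| / corr_length)^corr_shape)."""
        x = np.log2(np.asarray(self.frequencies, float))
        d = np.abs(x[:, None] - x[None, :])
        return np.exp(-((d / self.corr_length) ** self.corr_shape))

    def to_json(self) -> str:
        d = {k: getattr(self, k) for k in
             ("n", "frequencies", "mean_profile", "marginal_sd", "corr_length",
              "corr_shape", "round_step", "seed")}
        d["missing_rates"] = {str(k): v for k, v in self.missing_rates.items()}
        return json.dumps(d, indent=2)


def generate_dense(params: GeneratorParams,
                   rng: np.random.Generator | None = None) -> AudiogramMatrix:
    """Draw a fully observed synthetic audiogram matrix."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    corr = params.correlation()
    cov = corr * params.marginal_sd ** 2
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is not positive definite") from e
    z = rng.standard_normal((params.n, len(params.frequencies)))
    v = np.asarray(params.mean_profile) + z @ chol.T
    v = np.clip(v, THRESHOLD_MIN, THRESHOLD_MAX)
    v = np.round(v / params.round_step) * params.round_step
    return AudiogramMatrix(v, params.frequencies)


def generate_sparse(params: GeneratorParams,
                    rng: np.random.Generator | None = None,
                    max_regenerations: int = 1000) -> AudiogramMatrix:
    """Dense draw with entries deleted independently at per-feature rates.

    Rows left with no observed entry are redrawn (a cleaned dataset contains
    no blank instances); pathological rates that keep producing blank rows
    raise after ``max_regenerations`` attempts.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    dense = generate_dense(params, rng)
    rates = params.rate_vector()
    v = dense.values.copy()
    v[rng.random(v.shape) < rates] = np.nan
    for _ in range(max_regenerations):
        blank = np.flatnonzero(np.all(np.isnan(v), axis=1))
        if blank.size == 0:
            return AudiogramMatrix(v, params.frequencies)
        redo = GeneratorParams(**{**params.__dict__,
                                  "missing_rates": dict(params.missing_rates),
                                  "n": blank.size})
        fresh = generate_dense(redo, rng).values
        fresh[rng.random(fresh.shape) < rates] = np.nan
        v[blank] = fresh
    raise ValueError("missing rates too high: blank rows persist after "
                     f"{max_regenerations} regenerations")
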