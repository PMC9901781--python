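"""Reading and cleaning of tabular audiogram data.

An audiogram is a row of pure-tone thresholds in dB HL over an ordered grid of
test frequencies.  Cleaning follows the conventions of pooled clinical
audiometric registries: "no response" entries (the audiometer reached its
maximum output without a response) are recorded as 120 dB, implausible values
are discarded, and everything else is clipped into the 0–120 dB range that
audiometers report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The 11 standard frequencies (Hz) of a full clinical audiogram.
DEFAULT_FREQUENCIES: tuple[int, ...] = (
    125, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000,
)

#: Tokens treated as "no response at maximum output" (case-insensitive).
DEFAULT_NO_RESPONSE_TOKENS: tuple[str, ...] = ("NR", "No response", "NR*", "CNT-NR")

#: Values outside this window are implausible and become missing instead of
#: being clipped; values inside it but outside [0, 120] are clipped.
PLAUSIBILITY_WINDOW: tuple[float, float] = (-20.0, 200.0)

THRESHOLD_MIN = 0.0
THRESHOLD_MAX = 120.0

#: Sentinel for a cell that held unparseable (non-numeric, non-empty) text.
INVALID = np.inf


class EmptyInputError(ValueError):
    """Raised when an input table has no rows."""


class MissingColumnError(ValueError):
    """Raised when a required frequency column is absent from a file."""


@dataclass
class AudiogramMatrix:
    """Instances × frequencies grid of thresholds in dB HL.

    Missing entries are NaN.  Before cleaning, cells that held unparseable
    text are the ``INVALID`` sentinel (+inf), with the original token kept in
    ``raw_text`` so that cleaning can map no-response tokens to 120 dB.
    """

    values: np.ndarray
    frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES
    ids: np.ndarray | None = None
    raw_text: dict[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        self.frequencies = tuple(int(f) for f in self.frequencies)
        if list(self.frequencies) != sorted(set(self.frequencies)):
            raise ValueError("frequencies must be strictly ascending")
        if self.values.shape[1] != len(self.frequencies):
            raise ValueError(
                f"values has {self.values.shape[1]} columns for "
                f"{len(self.frequencies)} frequencies"
            )
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if len(self.ids) != self.values.shape[0]:
                raise ValueError("ids length must match number of rows")

    @property
    def n_instances(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean grid, True where an entry is missing."""
        return np.isnan(self.values)

    def take(self, rows: np.ndarray) -> "AudiogramMatrix":
        """Row subset (order as given), preserving ids."""
        return replace(
            self,
            values=self.values[rows],
            ids=None if self.ids is None else self.ids[rows],
            raw_text={},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(f) for f in self.frequencies])
        if self.ids is not None:
            df.insert(0, "id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   frequencies: tuple[int, ...] = DEFAULT_FREQUENCIES,
                   ) -> "AudiogramMatrix":
        cols = [str(f) for f in frequencies]
        ids = df["id"].to_numpy() if "id" in df.columns else None
        return cls(df[cols].to_numpy(dtype=float), frequencies, ids=ids)


def load_audiograms(path, frequencies=DEFAULT_FREQUENCIES) -> AudiogramMatrix:
    """Read a delimited audiogram table into a raw :class:`AudiogramMatrix`.

    The file must have one column per requested frequency, named by the
    frequency in Hz.  Cells may be numeric, empty (missing) or free text;
    text cells become the ``INVALID`` sentinel with the token retained for
    :func:`clean_thresholds`.  An optional ``id`` column is carried through.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise EmptyInputError(f"no audiograms in {path}")
    cols = [str(int(f)) for f in frequencies]
    for c in cols:
        if c not in df.columns:
            raise MissingColumnError(
                f"required frequency column {c!r} not found in {path}"
            )
    n = df.shape[0]
    values = np.full((n, len(cols)), np.nan)
    raw_text: dict[tuple[int, int], str] = {}
    for j, c in enumerate(cols):
        for i, cell in enumerate(df[c].to_numpy()):
            cell = cell.strip()
            if cell == "":
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                values[i, j] = INVALID
                raw_text[(i, j)] = cell
    ids = df["id"].to_numpy() if "id" in df.columns else None
    return AudiogramMatrix(values, tuple(frequencies), ids=ids, raw_text=raw_text)


def clean_thresholds(raw: AudiogramMatrix,
                     no_response_tokens=DEFAULT_NO_RESPONSE_TOKENS,
                     plausibility_window=PLAUSIBILITY_WINDOW,
                     ) -> AudiogramMatrix:
    """Apply the registry cleaning rules; total (never raises).

    * no-response tokens -> 120 dB (the maximum most audiometers record);
    * other unparseable text -> missing;
    * numeric values outside the plausibility window -> missing (implausible
      extremes are removed, not clipped);
    * remaining values clipped into [0, 120];
    * rows with every feature missing are dropped.
    """
    tokens = {t.strip().lower() for t in no_response_tokens}
    lo, hi = plausibility_window
    v = raw.values.copy()
    for (i, j), text in raw.raw_text.items():
        if text.strip().lower() in tokens:
            v[i, j] = THRESHOLD_MAX
    v[np.isinf(v)] = np.nan  # remaining invalid text
    with np.errstate(invalid="ignore"):
        v[(v < lo) | (v > hi)] = np.nan
    v = np.clip(v, THRESHOLD_MIN, THRESHOLD_MAX)
    keep = ~np.all(np.isnan(v), axis=1)
    ids = None if raw.ids is None else raw.ids[keep]
    return AudiogramMatrix(v[keep], raw.frequencies, ids=ids)


def complete_cases(m: AudiogramMatrix) -> AudiogramMatrix:
    """Rows with no missing feature, order preserved (may be empty)."""
    keep = ~np.any(m.missing_mask(), axis=1)
    return m.take(np.flatnonzero(keep))


def filter_by_missing_count(m: AudiogramMatrix, cap: int) -> AudiogramMatrix:
    """Rows with at most ``cap`` missing features; cap=0 is complete cases."""
    cap = int(cap)
    if cap < 0 or cap > m.n_features:
        raise ValueError(f"cap must be in [0, {m.n_features}], got {cap}")
    keep = m.missing_mask().sum(axis=1) <= cap
    return m.take(np.flatnonzero(keep))
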