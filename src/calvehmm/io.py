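"""Reading and writing activity series and model parameter files.

The on-disk activity format is a plain CSV with a mandatory header
``animal_id,hour_offset,posture_changes``. Hour offsets are negative
integers counting back from calving; ``-1`` is the final hour before the
calf is expelled. Models are stored as a single JSON document holding the
transition matrix ``A``, the emission matrix ``B``, the initial
distribution ``Pi`` and the state/symbol alphabets, so that a fitted model
is human-inspectable and diff-able.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

REQUIRED_COLUMNS = ("animal_id", "hour_offset", "posture_changes")

#: Observation alphabet: low / medium / high activity, in band order.
SYMBOLS = ("L", "M", "H")
#: Hidden states: non-calving and calving.
STATES = ("NC", "C")

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class ActivitySeries:
    """One animal's hourly posture-change counts.

    Parameters
    ----------
    animal_id
        Opaque identifier.
    hours
        Consecutive integer hour offsets ending at ``-1`` (the last hour
        before calving).
    counts
        Non-negative integer posture changes per hour: the number of
        standing bouts plus lying bouts observed in that hour.
    """

    animal_id: str
    hours: tuple[int, ...]
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.hours) != len(self.counts):
            raise ValidationError(
                f"{self.animal_id}: {len(self.hours)} hours but "
                f"{len(self.counts)} counts"
            )
        if len(self.hours) == 0:
            raise ValidationError(f"{self.animal_id}: empty series")
        for prev, cur in zip(self.hours, self.hours[1:]):
            if cur != prev + 1:
                raise ValidationError(
                    f"{self.animal_id}: hour offsets must be consecutive; "
                    f"gap between {prev} and {cur}"
                )
        if self.hours[-1] != -1:
            raise ValidationError(
                f"{self.animal_id}: final hour offset must be -1, "
                f"got {self.hours[-1]}"
            )
        for h, c in zip(self.hours, self.counts):
            if c < 0 or int(c) != c:
                raise ValidationError(
                    f"{self.animal_id}: count at hour {h} must be a "
                    f"non-negative integer, got {c!r}"
                )

    def __len__(self) -> int:
        return len(self.counts)

    def count_at(self, hour: int) -> int:
        """Count at a given hour offset."""
        try:
            return self.counts[self.hours.index(hour)]
        except ValueError:
            raise KeyError(f"hour {hour} not in series") from None


@dataclass(frozen=True)
class HMMParams:
    """Two-state HMM parameters lambda = (A, B, Pi).

    ``A`` is the 2x2 state transition matrix over (NC, C), ``B`` the 2x3
    emission matrix over (L, M, H), ``Pi`` the length-2 initial state
    distribution. Rows are validated to sum to one within 1e-9.
    """

    A: np.ndarray
    B: np.ndarray
    Pi: np.ndarray
    states: tuple[str, ...] = STATES
    symbols: tuple[str, ...] = SYMBOLS

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        Pi = np.asarray(self.Pi, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "Pi", Pi)
        k, m = len(self.states), len(self.symbols)
        if A.shape != (k, k):
            raise ValidationError(f"A must be {k}x{k}, got {A.shape}")
        if B.shape != (k, m):
            raise ValidationError(f"B must be {k}x{m}, got {B.shape}")
        if Pi.shape != (k,):
            raise ValidationError(f"Pi must have length {k}, got {Pi.shape}")
        for name, mat in (("A", A), ("B", B), ("Pi", Pi[None, :])):
            if np.any(mat < -_ROW_TOL) or np.any(mat > 1 + _ROW_TOL):
                raise ValidationError(f"{name} has entries outside [0, 1]")
            bad = np.abs(mat.sum(axis=1) - 1.0) > _ROW_TOL
            if bad.any():
                raise ValidationError(
                    f"rows of {name} must sum to 1 within {_ROW_TOL}; "
                    f"row sums {mat.sum(axis=1).tolist()}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HMMParams):
            return NotImplemented
        return (
            self.states == other.states
            and self.symbols == other.symbols
            and np.array_equal(self.A, other.A)
            and np.array_equal(self.B, other.B)
            and np.array_equal(self.Pi, other.Pi)
        )


def read_activity_csv(path: str | Path) -> list[ActivitySeries]:
    """Read an activity CSV into one :class:`ActivitySeries` per animal.

    Raises
    ------
    FormatError
        If the header is missing required columns.
    ValidationError
        If a count is negative or non-integer, or hour offsets have gaps.
    """
    try:
        frame = pd.read_csv(path, dtype={"animal_id": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    out: list[ActivitySeries] = []
    for animal_id, grp in frame.groupby("animal_id", sort=True):
        grp = grp.sort_values("hour_offset")
        hours_raw = grp["hour_offset"].to_numpy()
        counts_raw = grp["posture_changes"].to_numpy()
        for col, vals in (("hour_offset", hours_raw), ("posture_changes", counts_raw)):
            as_float = np.asarray(vals, dtype=float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                bad = int(np.flatnonzero(as_float != np.round(as_float))[0])
                raise ValidationError(
                    f"{animal_id}: non-integer {col} in row {bad} ({vals[bad]!r})"
                )
        counts = counts_raw.astype(int)
        neg = np.flatnonzero(counts < 0)
        if neg.size:
            raise ValidationError(
                f"{animal_id}: negative posture_changes in row {int(neg[0])} "
                f"({counts[int(neg[0])]})"
            )
        out.append(
            ActivitySeries(
                animal_id=str(animal_id),
                hours=tuple(int(h) for h in hours_raw),
                counts=tuple(int(c) for c in counts),
            )
        )
    return out


def write_activity_csv(series: ActivitySeries | list[ActivitySeries], path: str | Path) -> None:
    """Write one or more activity series to CSV (round-trips exactly)."""
    if isinstance(series, ActivitySeries):
        series = [series]
    rows = [
        {"animal_id": s.animal_id, "hour_offset": h, "posture_changes": c}
        for s in series
        for h, c in zip(s.hours, s.counts)
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def load_example_cow() -> ActivitySeries:
    """Load the packaged 72-hour worked-example series.

    Hourly posture-change counts for a single Holstein heifer over the
    final 72 hours before calving (hours -72..-1), used throughout the
    documentation and tests as the reference input.
    """
    ref = resources.files("calvehmm.data").joinpath("cow1_activity.csv")
    with resources.as_file(ref) as p:
        (series,) = read_activity_csv(p)
    return series


def save_model(params: HMMParams, path: str | Path) -> None:
    """Serialize HMM parameters to a JSON document at full precision."""
    doc = {
        "states": list(params.states),
        "symbols": list(params.symbols),
        "A": params.A.tolist(),
        "B": params.B.tolist(),
        "Pi": params.Pi.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_model(path: str | Path) -> HMMParams:
    """Load HMM parameters from JSON; validates stochasticity on load."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("A", "B", "Pi", "states", "symbols"):
        if key not in doc:
            raise FormatError(f"{path}: missing field {key!r}")
    return HMMParams(
        A=np.asarray(doc["A"], dtype=float),
        B=np.asarray(doc["B"], dtype=float),
        Pi=np.asarray(doc["Pi"], dtype=float),
        states=tuple(doc["states"]),
        symbols=tuple(doc["symbols"]),
    )
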