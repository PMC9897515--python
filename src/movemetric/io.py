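"""Reading, validation and preprocessing of movement recordings and ratings.

A recording is a delimited text table sampled at 100 Hz with one row per
sample and named sensor channels: optical marker position (``p0_*``),
accelerometer (``acc_*``) and gyroscope (``gyr_*``), each with x/y/z
components.  Velocity (``p1_*``) and acceleration (``p2_*``) channels are
derived from position with a Savitzky-Golay filter.  Ratings are relative
similarity judgements in [-1, 1] of which of two performances (A, A') is
closer to a template gesture: -1 means A is closest, +1 means A' is.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

#: canonical channel ordering used throughout the package
SENSOR_TYPES = ("acc", "gyr", "p0", "p1", "p2")
RAW_TYPES = ("acc", "gyr", "p0")
AXES = ("x", "y", "z")
ALL_CHANNELS = tuple(f"{t}_{a}" for t in SENSOR_TYPES for a in AXES)
RAW_CHANNELS = tuple(f"{t}_{a}" for t in RAW_TYPES for a in AXES)

RATER_MEAN = "mean"  # sentinel rater id for rater-averaged records


class SchemaError(ValueError):
    """A table is missing required columns or has a malformed header."""


class DataError(ValueError):
    """A table cell is non-numeric, non-finite or out of range."""


@dataclass
class MovementSeries:
    """A time-indexed K-channel feature matrix for one recording.

    Parameters
    ----------
    samples : (N, K) float array
        One row per 100 Hz sample.
    channel_names : sequence of str
        Ordered channel labels, unique, drawn from :data:`ALL_CHANNELS`.
    participant_id, session_id : identification of the recording.
    sample_rate : sampling frequency in Hz.
    """

    samples: np.ndarray
    channel_names: tuple[str, ...]
    participant_id: str = ""
    session_id: int = 0
    trial_id: int = 0
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (N, K) array")
        n, k = self.samples.shape
        if n < 2:
            raise DataError(f"need at least 2 samples, got {n}")
        if len(self.channel_names) != k:
            raise SchemaError(
                f"{len(self.channel_names)} channel names for {k} columns"
            )
        if len(set(self.channel_names)) != k:
            raise SchemaError("channel names must be unique")
        if not np.isfinite(self.samples).all():
            i, j = np.argwhere(~np.isfinite(self.samples))[0]
            raise DataError(
                f"non-finite value at row {i}, column {self.channel_names[j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]

    def select(self, channels) -> "MovementSeries":
        """Return a copy restricted to ``channels`` (in the given order)."""
        idx = [self.channel_names.index(c) for c in channels]
        return replace(
            self, samples=self.samples[:, idx], channel_names=tuple(channels)
        )

    def key(self) -> tuple[str, int, int]:
        return (self.participant_id, self.session_id, self.trial_id)


@dataclass(frozen=True)
class FeatureSet:
    """A subset of sensor types; each type expands to its x/y/z channels."""

    selected_types: tuple[str, ...]

    def __post_init__(self):
        types = tuple(self.selected_types)
        if not types:
            raise SchemaError("feature set must be non-empty")
        bad = [t for t in types if t not in SENSOR_TYPES]
        if bad:
            raise SchemaError(f"unknown sensor types: {bad}")
        # keep canonical order
        object.__setattr__(
            self, "selected_types", tuple(t for t in SENSOR_TYPES if t in types)
        )

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(f"{t}_{a}" for t in self.selected_types for a in AXES)

    def __str__(self) -> str:
        return "+".join(self.selected_types)


@dataclass(frozen=True)
class RatingRecord:
    """One relative-similarity judgement of a pair (A, A') against a template."""

    pair_id: str
    participant_id: str
    session_a: int
    session_b: int
    rater_id: str
    rating: float

    def __post_init__(self):
        if not -1.0 <= self.rating <= 1.0:
            raise DataError(
                f"rating {self.rating} for pair {self.pair_id} outside [-1, 1]"
            )
        if self.session_a == self.session_b and self.rater_id != RATER_MEAN:
            raise DataError(
                f"pair {self.pair_id}: sessions of A and A' must differ"
            )


# ---------------------------------------------------------------------------
# movement tables
# ---------------------------------------------------------------------------

def read_movement(path, schema: dict | None = None, participant_id: str = "",
                  session_id: int = 0, trial_id: int = 0,
                  sample_rate: float = 100.0) -> MovementSeries:
    """Read a delimited movement table into a validated :class:`MovementSeries`.

    ``schema`` optionally maps file column names to canonical channel names.
    Only recognised channels are retained, in canonical order; the raw sensor
    channels (acc, gyr, p0) must all be present.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in RAW_CHANNELS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    channels = [c for c in ALL_CHANNELS if c in df.columns]
    sub = df[list(channels)]
    values = sub.apply(pd.to_numeric, errors="coerce").to_numpy(np.float64)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            f"{path}: non-numeric or non-finite value at row {i}, "
            f"column {channels[j]}"
        )
    return MovementSeries(values, tuple(channels), participant_id=participant_id,
                          session_id=session_id, trial_id=trial_id,
                          sample_rate=sample_rate)


def write_movement(m: MovementSeries, path) -> None:
    pd.DataFrame(m.samples, columns=list(m.channel_names)).to_csv(
        path, index=False, float_format="%.12g"
    )


def derive_kinematics(m: MovementSeries, window: int = 17,
                      polyorder: int = 3) -> MovementSeries:
    """Append velocity (p1) and acceleration (p2) channels derived from p0.

    Derivatives are estimated with a Savitzky-Golay filter (default window of
    17 samples, cubic fit) and scaled by the sample rate so p1 and p2 are
    per-second quantities.  Edge samples use truncated polynomial fits and are
    less accurate; interior samples are exact for polynomial trajectories up
    to the fit degree.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if m.n_samples < window:
        raise ValueError(
            f"series of length {m.n_samples} shorter than window {window}"
        )
    pos_channels = [f"p0_{a}" for a in AXES]
    missing = [c for c in pos_channels if c not in m.channel_names]
    if missing:
        raise SchemaError(f"cannot derive kinematics: missing {missing}")
    delta = 1.0 / m.sample_rate
    new_cols, new_names = [], []
    for order, prefix in ((1, "p1"), (2, "p2")):
        for a in AXES:
            d = savgol_filter(m.channel(f"p0_{a}"), window, polyorder,
                              deriv=order, delta=delta, mode="interp")
            new_cols.append(d)
            new_names.append(f"{prefix}_{a}")
    keep = [c for c in m.channel_names if c not in new_names]
    samples = np.column_stack([m.select(keep).samples] + new_cols)
    names = tuple(keep) + tuple(new_names)
    # restore canonical ordering
    ordered = tuple(c for c in ALL_CHANNELS if c in names)
    return replace(m, samples=samples, channel_names=names).select(ordered)


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

def standardise(group: list[MovementSeries],
                features: FeatureSet | None = None,
                stats: dict | None = None):
    """Z-score each selected channel, pooling statistics over the whole group.

    Pooling over all recordings (template included) keeps distances
    comparable across pairs; the returned ``{channel: (mean, std)}`` table
    lets held-out data be transformed with the same statistics (pass it back
    via ``stats``).

    Returns ``(standardised series, stats table)``.
    """
    if not group:
        raise ValueError("empty group")
    channels = features.channels if features is not None else group[0].channel_names
    for m in group:
        missing = [c for c in channels if c not in m.channel_names]
        if missing:
            raise SchemaError(f"series {m.key()} missing channels {missing}")
    if stats is None:
        pooled = np.concatenate([m.select(channels).samples for m in group])
        mean = pooled.mean(axis=0)
        std = pooled.std(axis=0)
        zero = np.flatnonzero(std < 1e-12)
        if zero.size:
            raise DataError(
                f"zero-variance channel(s): {[channels[i] for i in zero]}"
            )
        stats = {c: (float(mu), float(sd))
                 for c, mu, sd in zip(channels, mean, std)}
    mu = np.array([stats[c][0] for c in channels])
    sd = np.array([stats[c][1] for c in channels])
    out = [replace(m, samples=(m.select(channels).samples - mu) / sd,
                   channel_names=tuple(channels)) for m in group]
    return out, stats


# ---------------------------------------------------------------------------
# ratings tables
# ---------------------------------------------------------------------------

RATING_COLUMNS = ("pair_id", "participant_id", "session_a", "session_b",
                  "rater_id", "rating")


def read_ratings(path) -> list[RatingRecord]:
    """Read and validate a ratings table (one row per pair x rater)."""
    df = pd.read_csv(path)
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: ratings table missing columns {missing}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.pair_id, row.rater_id)
        if key in seen:
            raise DataError(f"duplicate rating for pair {key[0]} by rater {key[1]}")
        seen.add(key)
        records.append(RatingRecord(
            pair_id=str(row.pair_id), participant_id=str(row.participant_id),
            session_a=int(row.session_a), session_b=int(row.session_b),
            rater_id=str(row.rater_id), rating=float(row.rating)))
    return records


def write_ratings(records: list[RatingRecord], path) -> None:
    pd.DataFrame([
        {c: getattr(r, c) for c in RATING_COLUMNS} for r in records
    ]).to_csv(path, index=False)


def average_ratings(records: list[RatingRecord]) -> list[RatingRecord]:
    """Collapse multi-rater records to one mean rating per pair."""
    out = []
    key = lambda r: r.pair_id
    for pair_id, grp in itertools.groupby(sorted(records, key=key), key=key):
        grp = list(grp)
        out.append(replace(
            grp[0], rater_id=RATER_MEAN,
            rating=float(np.mean([r.rating for r in grp])),
        ))
    return out
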