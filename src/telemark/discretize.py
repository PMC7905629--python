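"""Weekly occasion grid and per-fish observation sequences.

Detections are binned into discrete detection occasions (one week by
default).  A fish is scored *present* at an array in an occasion when at
least one of its detections there, within that occasion, belongs to a
qualifying cluster: two or more detections at the array whose
consecutive gaps are at most 24 hours.  Each fish then receives one
observation code per active occasion — 1 when absent from every array,
otherwise the code of the array it occupied.  When a fish qualifies at
two arrays in the same week, the array whose last qualifying detection
is latest wins: the final position best carries the direction of travel
into the following week.

The observation window of fish *i* runs from the occasion after its
release occasion ``c_i`` through ``c_i + l_i`` (transmitter life in
occasions, floored — a partly covered week cannot guarantee an active
transmitter), truncated at the final study occasion ``f``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import pair_is_possible
from .tables import ReceiverRegistry, TagDeployment, detections_frame, _to_utc

#: observation code of an array, keyed by (role, entrance_id)
ARRAY_CODES = {
    ("spawn", None): 2,
    ("interior", None): 3,
    ("entrance", "hinchinbrook"): 4,
    ("entrance", "strait"): 5,
    ("entrance", "passages"): 6,
}

#: array key per observation code (2..6)
CODE_ARRAYS = {v: k for k, v in ARRAY_CODES.items()}


class GridConfigError(ValueError):
    pass


@dataclass(frozen=True)
class OccasionGrid:
    """Contiguous half-open detection occasions with seasonal bins.

    Occasion ``j`` (1-based) covers ``[origin + (j-1)*L, origin + j*L)``
    where ``L`` is the occasion length.  Each occasion belongs to the
    season whose boundary date most recently precedes (or equals) the
    occasion's start instant.
    """

    origin: pd.Timestamp
    occasion_days: int
    n_occasions: int
    season_labels: tuple[str, ...]
    season_of_occasion: np.ndarray  # (n_occasions + 1,), 0-based season index

    @property
    def f(self) -> int:
        """Final possible detection occasion."""
        return self.n_occasions

    @property
    def n_seasons(self) -> int:
        return len(self.season_labels)

    def occasion_of(self, instant) -> int:
        """1-based occasion index containing ``instant`` (may fall outside 1..f)."""
        ts = _to_utc(instant)
        delta = (ts - self.origin) / pd.Timedelta(days=self.occasion_days)
        return int(math.floor(delta)) + 1

    def interval(self, j: int) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = self.origin + pd.Timedelta(days=self.occasion_days * (j - 1))
        return start, start + pd.Timedelta(days=self.occasion_days)

    def season_of(self, j: int) -> int:
        """0-based season index of occasion ``j`` (clamped into 0..f)."""
        return int(self.season_of_occasion[min(max(j, 0), self.n_occasions)])

    def season_bins(self) -> list[tuple[str, int, int]]:
        """(label, first occasion, last occasion) per season."""
        bins = []
        s = self.season_of_occasion[1:]
        for k, label in enumerate(self.season_labels):
            occ = np.nonzero(s == k)[0] + 1
            if len(occ):
                bins.append((label, int(occ[0]), int(occ[-1])))
            else:
                bins.append((label, 0, 0))
        return bins


#: study defaults: a 24-month window with two spring/summer (April-August)
#: and two fall/winter (September-March) seasons
DEFAULT_START = "2017-04-01"
DEFAULT_END = "2019-03-31"
DEFAULT_SEASON_STARTS = [
    ("B1", "2017-04-01"),
    ("B2", "2017-09-01"),
    ("B3", "2018-04-01"),
    ("B4", "2018-09-01"),
]


def build_grid(
    start=DEFAULT_START,
    end=DEFAULT_END,
    occasion_days: int = 7,
    season_starts=None,
) -> OccasionGrid:
    """Enumerate occasions covering [start, end] and bin them into seasons.

    ``season_starts`` is an ordered list of ``(label, first date)`` pairs;
    the first must coincide with ``start``.  Every occasion is assigned to
    the season of the calendar date of its start instant.
    """
    origin = _to_utc(start)
    end_ts = _to_utc(end)
    if not end_ts > origin:
        raise GridConfigError("end date must be after start date")
    if occasion_days <= 0:
        raise GridConfigError("occasion length must be positive")
    if season_starts is None:
        season_starts = [(label, d) for label, d in DEFAULT_SEASON_STARTS]
        # preserve defaults only when they fit in the window; else one bin
        season_starts = [(l, d) for l, d in season_starts if origin <= _to_utc(d) <= end_ts]
        if not season_starts or _to_utc(season_starts[0][1]) != origin:
            season_starts = [("B1", start)] + season_starts

    labels = tuple(label for label, _ in season_starts)
    bounds = [_to_utc(d) for _, d in season_starts]
    if bounds[0] != origin:
        raise GridConfigError("first season must start at the grid start date")
    for a, b in zip(bounds, bounds[1:]):
        if not b > a:
            raise GridConfigError("season boundaries must be strictly increasing")
    if bounds[-1] > end_ts:
        raise GridConfigError("season boundaries must lie within [start, end]")

    n = int(math.floor((end_ts - origin) / pd.Timedelta(days=occasion_days))) + 1
    season_of = np.zeros(n + 1, dtype=np.int64)
    for j in range(1, n + 1):
        occ_start = origin + pd.Timedelta(days=occasion_days * (j - 1))
        k = 0
        for idx, b in enumerate(bounds):
            if occ_start >= b:
                k = idx
        season_of[j] = k
    season_of[0] = season_of[1]
    return OccasionGrid(
        origin=origin,
        occasion_days=occasion_days,
        n_occasions=n,
        season_labels=labels,
        season_of_occasion=season_of,
    )


def transmitter_life_occasions(l_days: float, occasion_days: int = 7) -> int:
    """Transmitter life in whole occasions (floor; conservative censoring)."""
    if l_days <= 0:
        raise ValueError("transmitter life must be positive")
    return int(math.floor(l_days / occasion_days))


# ---------------------------------------------------------------------------
# presence

def assign_presence(
    detections,
    registry: ReceiverRegistry,
    grid: OccasionGrid,
    window_hours: float = 24.0,
) -> dict[str, dict[int, dict[int, pd.Timestamp]]]:
    """Per-fish, per-occasion array presence.

    Returns ``{tag: {occasion: {array code: last qualifying detection}}}``.
    Detections at one array (pooled across its receivers) are segmented
    into maximal clusters with consecutive gaps <= ``window_hours``;
    clusters with >= 2 detections qualify, and presence is marked in
    every occasion that contains at least one of the cluster's
    detections.  Adding detections can only add presence, never remove it.
    """
    df = detections if isinstance(detections, pd.DataFrame) else detections_frame(detections)
    if len(df) == 0:
        return {}
    unknown = sorted(set(df["receiver_id"]) - set(registry))
    if unknown:
        raise KeyError(f"unknown receiver id(s): {unknown}")
    code_of = {
        rid: ARRAY_CODES[(registry[rid].role, registry[rid].entrance_id)] for rid in set(df["receiver_id"])
    }
    df = df.assign(code=df["receiver_id"].map(code_of))
    gap = pd.Timedelta(hours=window_hours)

    presence: dict[str, dict[int, dict[int, pd.Timestamp]]] = {}
    for (tag, code), sub in df.groupby(["tag_id", "code"], sort=False):
        times = (
            sub["timestamp"].sort_values().dt.tz_convert("UTC").dt.tz_localize(None).to_numpy()
        )
        # maximal runs with inter-detection gaps <= window
        breaks = np.nonzero(np.diff(times) > gap.to_numpy())[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(times) - 1]))
        for a, b in zip(starts, ends):
            if b == a:  # singleton cluster does not qualify
                continue
            cluster = times[a : b + 1]
            for t in cluster:
                j = grid.occasion_of(pd.Timestamp(t))
                if not (1 <= j <= grid.f):
                    continue
                by_occ = presence.setdefault(tag, {}).setdefault(j, {})
                ts = pd.Timestamp(t)
                if code not in by_occ or ts > by_occ[code]:
                    by_occ[code] = ts
    return presence


# ---------------------------------------------------------------------------
# observation matrix

@dataclass
class ObservationMatrix:
    """Weekly observation codes on the occasion grid.

    ``codes[i, j]`` is the observation of fish ``i`` at occasion ``j``
    (column 0 unused); 0 marks occasions outside the fish's active
    window ``{c_i+1, ..., min(c_i + l_i, f)}``.
    """

    tag_ids: list[str]
    codes: np.ndarray          # (n_fish, f + 1) int8
    release_occasion: np.ndarray  # c_i, (n_fish,)
    last_occasion: np.ndarray     # min(c_i + l_i, f), (n_fish,)
    f: int
    excluded: list[str] = field(default_factory=list)

    @property
    def n_fish(self) -> int:
        return len(self.tag_ids)

    def active_occasions(self, i: int) -> range:
        return range(int(self.release_occasion[i]) + 1, int(self.last_occasion[i]) + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes[:, 1:], columns=[str(j) for j in range(1, self.f + 1)])
        df.insert(0, "tag_id", self.tag_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, release_occasion, last_occasion
    ) -> "ObservationMatrix":
        tags = list(df["tag_id"])
        f = df.shape[1] - 1
        codes = np.zeros((len(tags), f + 1), dtype=np.int8)
        codes[:, 1:] = df.drop(columns="tag_id").to_numpy(dtype=np.int8)
        return cls(
            tag_ids=tags,
            codes=codes,
            release_occasion=np.asarray(release_occasion, dtype=np.int64),
            last_occasion=np.asarray(last_occasion, dtype=np.int64),
            f=f,
        )


def build_observation_matrix(
    presences: dict,
    deployments: list[TagDeployment],
    grid: OccasionGrid,
) -> ObservationMatrix:
    """Assemble per-fish observation sequences from presence sets.

    Fish released after the grid end are excluded (with their ids
    recorded on the result).  Multi-array weeks are resolved by the
    latest-qualifying-detection tie-break.
    """
    tags, c_list, last_list, excluded = [], [], [], []
    rows = []
    for d in deployments:
        c = grid.occasion_of(d.release_time)
        if c > grid.f:
            excluded.append(d.tag_id)
            continue
        l_occ = transmitter_life_occasions(d.transmitter_life_days, grid.occasion_days)
        last = min(c + l_occ, grid.f)
        tags.append(d.tag_id)
        c_list.append(max(c, 0))
        last_list.append(last)
        row = np.zeros(grid.f + 1, dtype=np.int8)
        by_occ = presences.get(d.tag_id, {})
        for j in range(max(c, 0) + 1, last + 1):
            arrays = by_occ.get(j)
            if not arrays:
                row[j] = 1
            else:
                # latest last-qualifying detection wins
                row[j] = max(arrays, key=lambda code: arrays[code])
        rows.append(row)
    codes = np.array(rows, dtype=np.int8) if rows else np.zeros((0, grid.f + 1), dtype=np.int8)
    return ObservationMatrix(
        tag_ids=tags,
        codes=codes,
        release_occasion=np.array(c_list, dtype=np.int64),
        last_occasion=np.array(last_list, dtype=np.int64),
        f=grid.f,
        excluded=excluded,
    )


class ObservationConflictError(ValueError):
    def __init__(self, violations):
        self.violations = violations
        msgs = ", ".join(
            f"{tag}: occasions {j}->{j + 1} codes {x1}->{x2}" for tag, j, x1, x2 in violations[:10]
        )
        super().__init__(f"impossible consecutive observations: {msgs}")


def validate_observations(
    obs: ObservationMatrix, strict: bool = True, repair: bool = False
) -> list[tuple[str, int, int, int]]:
    """Find consecutive observation pairs impossible under the move graph.

    In strict mode any violation raises; with ``repair=True`` the earlier
    member of each impossible pair is recoded to 1 (undetected) and the
    violation list returned for logging.
    """
    violations = []
    for i in range(obs.n_fish):
        for j in obs.active_occasions(i):
            if j + 1 > obs.last_occasion[i]:
                break
            x1, x2 = int(obs.codes[i, j]), int(obs.codes[i, j + 1])
            if x1 == 0 or x2 == 0:
                continue
            if not pair_is_possible(x1, x2):
                violations.append((obs.tag_ids[i], j, x1, x2))
    if violations:
        if repair:
            index = {t: i for i, t in enumerate(obs.tag_ids)}
            for tag, j, _, _ in violations:
                obs.codes[index[tag], j] = 1
        elif strict:
            raise ObservationConflictError(violations)
    return violations
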