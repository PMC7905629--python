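"""Passage-direction inference at two-line entrance arrays.

Each entrance between the sound and the gulf carries an inner (sound
side) and an outer (gulf side) line of receivers.  A fish's detections
at one entrance are segmented into *visits* — maximal runs whose
consecutive gaps do not exceed 24 hours (a fish is deemed to have left
after a full undetected day).  A visit is a sound-to-gulf passage when
its first detection(s) fall exclusively on the inner line and its last
detection(s) exclusively on the outer line; the reverse pattern is a
gulf-to-sound passage.  No direction is assigned when the first or last
detections coincide across the two lines (within a configurable
tolerance, default: the same second), when the visit touches an inner
receiver with no complementary outer line, or when first and last lines
agree.

The assigned passages are tabulated per entrance r, fish class y and
season k into the directional counts ``d^{r4}_{yk}`` (gulf-to-sound) and
``d^{r8}_{yk}`` (sound-to-gulf) that feed the informative movement
priors, together with the stay/leave ratio ``q_r`` estimated from weekly
presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discretize import OccasionGrid
from .states import ENTRANCE_STATE_BY_ID
from .tables import CovariateClassing, ReceiverRegistry, detections_frame

SOUND_TO_GULF = "sound_to_gulf"
GULF_TO_SOUND = "gulf_to_sound"
UNASSIGNED = "unassigned"


@dataclass
class ArrayVisit:
    """One uninterrupted stay of one fish at one entrance array."""

    tag_id: str
    entrance_id: str
    detections: pd.DataFrame  # time-ordered: receiver_id, timestamp

    @property
    def entry_time(self) -> pd.Timestamp:
        return self.detections["timestamp"].iloc[0]

    @property
    def exit_time(self) -> pd.Timestamp:
        return self.detections["timestamp"].iloc[-1]


@dataclass(frozen=True)
class PassageEvent:
    tag_id: str
    entrance_id: str
    exit_time: pd.Timestamp
    season: int           # 0-based season index
    fish_class: int       # y
    direction: str


def segment_visits(detections, tag_id=None, entrance_id=None, gap_hours: float = 24.0) -> list[ArrayVisit]:
    """Split one fish's time-sorted entrance detections into visits.

    A gap of exactly ``gap_hours`` stays within the visit; only a strict
    exceedance closes it.
    """
    df = detections if isinstance(detections, pd.DataFrame) else detections_frame(detections)
    if len(df) == 0:
        return []
    if tag_id is None:
        tag_id = df["tag_id"].iloc[0]
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    gap = pd.Timedelta(hours=gap_hours)
    visits = []
    start = 0
    times = df["timestamp"]
    for i in range(1, len(df)):
        if times.iloc[i] - times.iloc[i - 1] > gap:
            visits.append(ArrayVisit(tag_id, entrance_id, df.iloc[start:i].reset_index(drop=True)))
            start = i
    visits.append(ArrayVisit(tag_id, entrance_id, df.iloc[start:].reset_index(drop=True)))
    return visits


def assign_direction(
    visit: ArrayVisit, registry: ReceiverRegistry, coincidence_tolerance_s: float = 0.0
) -> str:
    """Direction of travel of one visit, or ``unassigned``.

    Robust to duplicated detection rows: only the set of (receiver,
    timestamp) pairs matters.
    """
    df = visit.detections.drop_duplicates(["receiver_id", "timestamp"])
    recs = {rid: registry[rid] for rid in df["receiver_id"].unique()}
    for rid, rec in recs.items():
        if rec.role != "entrance" or (
            visit.entrance_id is not None and rec.entrance_id != visit.entrance_id
        ):
            raise ValueError(
                f"receiver {rid} does not belong to entrance {visit.entrance_id!r}"
            )
    # a visit touching an inner receiver with no complementary outer line
    # cannot be oriented
    if any(not rec.has_complement for rec in recs.values()):
        return UNASSIGNED

    tol = pd.Timedelta(seconds=coincidence_tolerance_s)
    t = df["timestamp"]
    first_lines = {recs[r].line for r, ts in zip(df["receiver_id"], t) if ts - t.min() <= tol}
    last_lines = {recs[r].line for r, ts in zip(df["receiver_id"], t) if t.max() - ts <= tol}
    if len(first_lines) > 1 or len(last_lines) > 1:
        return UNASSIGNED  # first or last detections coincide across lines
    (first,) = first_lines
    (last,) = last_lines
    if first == "inner" and last == "outer":
        return SOUND_TO_GULF
    if first == "outer" and last == "inner":
        return GULF_TO_SOUND
    return UNASSIGNED


def extract_passages(
    detections,
    registry: ReceiverRegistry,
    grid: OccasionGrid,
    classing: CovariateClassing,
    gap_hours: float = 24.0,
    coincidence_tolerance_s: float = 0.0,
) -> list[PassageEvent]:
    """Segment, orient and season-stamp every entrance visit in a log.

    A passage is one visit (a fish crossing twice contributes twice);
    its season is that of the occasion containing the exit time.
    """
    df = detections if isinstance(detections, pd.DataFrame) else detections_frame(detections)
    if len(df) == 0:
        return []
    entrance_of = {
        rid: registry[rid].entrance_id for rid in df["receiver_id"].unique() if rid in registry
    }
    unknown = sorted(set(df["receiver_id"]) - set(entrance_of))
    if unknown:
        raise KeyError(f"unknown receiver id(s): {unknown}")
    df = df.assign(entrance=df["receiver_id"].map(entrance_of))
    df = df[df["entrance"].notna()]
    passages = []
    for (tag, entrance), sub in df.groupby(["tag_id", "entrance"], sort=False):
        for visit in segment_visits(sub, tag_id=tag, entrance_id=entrance, gap_hours=gap_hours):
            direction = assign_direction(visit, registry, coincidence_tolerance_s)
            passages.append(
                PassageEvent(
                    tag_id=tag,
                    entrance_id=entrance,
                    exit_time=visit.exit_time,
                    season=grid.season_of(grid.occasion_of(visit.exit_time)),
                    fish_class=int(classing.y.get(tag, 0)),
                    direction=direction,
                )
            )
    passages.sort(key=lambda p: (p.tag_id, p.exit_time))
    return passages


@dataclass
class DirectionalCounts:
    """Directional passage counts and stay/leave ratios per entrance.

    ``d4[(r, y, k)]`` counts gulf-to-sound passages and ``d8[(r, y, k)]``
    sound-to-gulf passages at entrance state r for class y in season k;
    ``q[r]`` is the pooled stay/leave ratio, and the stay pseudo-count is
    ``d^{rr}_{yk} = q_r (d^{r4}_{yk} + d^{r8}_{yk})`` (kept fractional).
    """

    n_classes: int
    n_seasons: int
    d4: dict
    d8: dict
    q: dict

    def drr(self, r: int, y: int, k: int) -> float:
        return stay_pseudocount(self.d4[(r, y, k)], self.d8[(r, y, k)], self.q[r])

    def to_dict(self) -> dict:
        from .states import ENTRANCE_ID_BY_STATE

        out = {"q": {ENTRANCE_ID_BY_STATE[r]: self.q[r] for r in self.q}, "counts": {}}
        for r in ENTRANCE_STATE_BY_ID.values():
            name = {v: k for k, v in ENTRANCE_STATE_BY_ID.items()}[r]
            out["counts"][name] = {
                str(y): {
                    str(k): {
                        "d4": self.d4[(r, y, k)],
                        "d8": self.d8[(r, y, k)],
                        "drr": self.drr(r, y, k),
                    }
                    for k in range(self.n_seasons)
                }
                for y in range(self.n_classes)
            }
        return out


def tabulate_counts(
    passages: list[PassageEvent], n_classes: int, n_seasons: int, q: dict
) -> DirectionalCounts:
    """Count assigned passages per (entrance, class, season); unassigned
    passages contribute nothing."""
    d4 = {(r, y, k): 0 for r in ENTRANCE_STATE_BY_ID.values() for y in range(n_classes) for k in range(n_seasons)}
    d8 = {key: 0 for key in d4}
    for p in passages:
        r = ENTRANCE_STATE_BY_ID[p.entrance_id]
        key = (r, p.fish_class, p.season)
        if p.direction == GULF_TO_SOUND:
            d4[key] += 1
        elif p.direction == SOUND_TO_GULF:
            d8[key] += 1
    return DirectionalCounts(n_classes=n_classes, n_seasons=n_seasons, d4=d4, d8=d8, q=dict(q))


class ZeroLeaveError(ZeroDivisionError):
    pass


def estimate_q(presences: dict, grid: OccasionGrid, fallback: dict | None = None) -> dict[int, float]:
    """Stay/leave ratio per entrance from weekly presence.

    ``q_r`` = (fish-occasion pairs present at entrance r in occasions j
    and j+1) / (pairs present at j but absent at j+1), pooled over fish,
    occasions, classes and seasons.  A zero denominator raises unless a
    ``fallback`` value is configured for that entrance.
    """
    from .discretize import ARRAY_CODES

    code_of = {r: ARRAY_CODES[("entrance", name)] for name, r in ENTRANCE_STATE_BY_ID.items()}
    q = {}
    for name, r in ENTRANCE_STATE_BY_ID.items():
        code = code_of[r]
        stays = leaves = 0
        for tag, by_occ in presences.items():
            occs = {j for j, arrays in by_occ.items() if code in arrays}
            for j in occs:
                if j + 1 > grid.f:
                    continue
                if j + 1 in occs:
                    stays += 1
                else:
                    leaves += 1
        if leaves == 0:
            if fallback is not None and r in fallback:
                q[r] = float(fallback[r])
            else:
                raise ZeroLeaveError(
                    f"no departures observed at entrance {name!r}; supply a "
                    f"fallback q value in the run configuration"
                )
        else:
            q[r] = stays / leaves
    return q


def stay_pseudocount(d4: float, d8: float, q: float) -> float:
    """Stay pseudo-count d^{rr} = q (d^{r4} + d^{r8}); fractional values kept."""
    if q < 0:
        raise ValueError("stay/leave ratio must be non-negative")
    return q * (d4 + d8)


def passages_frame(passages: list[PassageEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.tag_id, p.entrance_id, p.exit_time, p.season, p.fish_class, p.direction)
            for p in passages
        ],
        columns=["tag_id", "entrance", "exit_time", "season", "class", "direction"],
    )
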