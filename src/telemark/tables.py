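"""Tabular inputs: detection logs, receiver registries, tag deployments.

Three plain CSV dialects are used throughout:

* ``detections.csv`` — ``tag_id,receiver_id,timestamp`` (ISO-8601);
* ``receivers.csv`` — ``receiver_id,array_name,role,entrance_id,line,has_complement``;
* ``deployments.csv`` — ``tag_id,release_time,transmitter_life_days,weight_g,length_mm,sex,tag_weight_g``.

Timestamps are normalised to UTC on read so that 24-hour window
arithmetic is unambiguous.  Derived per-fish covariates (body condition
``weight / length**3`` and tag burden ``tag_weight / weight``) are
computed once at read time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """A structural problem with an input table (missing columns, bad rows)."""


ROLES = ("spawn", "interior", "entrance")
LINES = ("inner", "outer", "none")
ENTRANCE_IDS = ("hinchinbrook", "strait", "passages")
SEXES = ("F", "M", "unknown")


def _to_utc(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        return ts.tz_localize("UTC")
    return ts.tz_convert("UTC")


@dataclass(frozen=True)
class DetectionEvent:
    tag_id: str
    receiver_id: str
    timestamp: pd.Timestamp


@dataclass(frozen=True)
class ReceiverRecord:
    receiver_id: str
    array_name: str
    role: str
    entrance_id: str | None = None
    line: str = "none"
    has_complement: bool = True

    def __post_init__(self):
        if self.role not in ROLES:
            raise TableFormatError(f"receiver {self.receiver_id}: unknown role {self.role!r}")
        if self.line not in LINES:
            raise TableFormatError(f"receiver {self.receiver_id}: unknown line {self.line!r}")
        if self.role == "entrance":
            if self.entrance_id not in ENTRANCE_IDS:
                raise TableFormatError(
                    f"receiver {self.receiver_id}: entrance receiver needs an "
                    f"entrance_id among {ENTRANCE_IDS}, got {self.entrance_id!r}"
                )
            if self.line not in ("inner", "outer"):
                raise TableFormatError(
                    f"receiver {self.receiver_id}: entrance receiver must sit on "
                    f"the inner or outer line, got {self.line!r}"
                )
        else:
            if self.entrance_id is not None:
                raise TableFormatError(
                    f"receiver {self.receiver_id}: non-entrance receiver cannot "
                    f"carry entrance_id {self.entrance_id!r}"
                )
            if self.line != "none":
                raise TableFormatError(
                    f"receiver {self.receiver_id}: non-entrance receiver cannot "
                    f"sit on a line ({self.line!r})"
                )


@dataclass(frozen=True)
class TagDeployment:
    tag_id: str
    release_time: pd.Timestamp
    transmitter_life_days: int
    weight_g: float
    length_mm: float
    sex: str = "unknown"
    tag_weight_g: float = 0.0

    def __post_init__(self):
        if not self.weight_g > 0:
            raise TableFormatError(f"tag {self.tag_id}: weight must be positive")
        if not self.length_mm > 0:
            raise TableFormatError(f"tag {self.tag_id}: length must be positive")
        if self.tag_weight_g < 0:
            raise TableFormatError(f"tag {self.tag_id}: tag weight must be >= 0")
        if self.transmitter_life_days <= 0:
            raise TableFormatError(f"tag {self.tag_id}: transmitter life must be positive")
        if self.sex not in SEXES:
            raise TableFormatError(f"tag {self.tag_id}: sex must be one of {SEXES}")

    @property
    def condition(self) -> float:
        """Body condition, weight x length^-3 (g mm^-3)."""
        return self.weight_g / self.length_mm**3

    @property
    def tag_burden(self) -> float:
        """Transmitter weight relative to body weight."""
        return self.tag_weight_g / self.weight_g


class ReceiverRegistry(Mapping):
    """Receiver records indexed by receiver id."""

    def __init__(self, records: Iterable[ReceiverRecord]):
        self._by_id: dict[str, ReceiverRecord] = {}
        for rec in records:
            if rec.receiver_id in self._by_id:
                raise TableFormatError(f"duplicate receiver_id {rec.receiver_id!r}")
            self._by_id[rec.receiver_id] = rec

    def __getitem__(self, receiver_id: str) -> ReceiverRecord:
        return self._by_id[receiver_id]

    def __iter__(self):
        return iter(self._by_id)

    def __len__(self):
        return len(self._by_id)

    @property
    def records(self) -> list[ReceiverRecord]:
        return list(self._by_id.values())

    def entrance_receivers(self, entrance_id: str) -> list[ReceiverRecord]:
        return [r for r in self._by_id.values() if r.entrance_id == entrance_id]


# ---------------------------------------------------------------------------
# readers / writers

_DETECTION_COLS = ["tag_id", "receiver_id", "timestamp"]
_RECEIVER_COLS = ["receiver_id", "array_name", "role", "entrance_id", "line", "has_complement"]
_DEPLOYMENT_COLS = [
    "tag_id", "release_time", "transmitter_life_days",
    "weight_g", "length_mm", "sex", "tag_weight_g",
]


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")


def read_detections(path) -> list[DetectionEvent]:
    """Read a detection log; malformed timestamps are reported with line numbers."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _DETECTION_COLS, path)
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
    bad = df.index[parsed.isna()]
    if len(bad):
        # +2: one for the header row, one for 1-based numbering
        lines = ", ".join(str(i + 2) for i in bad[:20])
        raise TableFormatError(f"{path}: unparseable timestamp on line(s) {lines}")
    return [
        DetectionEvent(tag_id=t, receiver_id=r, timestamp=ts)
        for t, r, ts in zip(df["tag_id"], df["receiver_id"], parsed)
    ]


def write_detections(events: Iterable[DetectionEvent], path) -> None:
    detections_frame(events).assign(
        timestamp=lambda d: d["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    ).to_csv(path, index=False)


def detections_frame(events: Iterable[DetectionEvent]) -> pd.DataFrame:
    """Detection events as a DataFrame sorted by (tag, time)."""
    rows = [(e.tag_id, e.receiver_id, e.timestamp) for e in events]
    df = pd.DataFrame(rows, columns=_DETECTION_COLS)
    if len(df):
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        df = df.sort_values(["tag_id", "timestamp"], kind="stable").reset_index(drop=True)
    else:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df


def read_receivers(path) -> ReceiverRegistry:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _RECEIVER_COLS, path)
    records = []
    for _, row in df.iterrows():
        entrance = row["entrance_id"]
        entrance = None if pd.isna(entrance) or entrance == "" else entrance
        line = row["line"]
        line = "none" if pd.isna(line) or line == "" else line
        records.append(
            ReceiverRecord(
                receiver_id=row["receiver_id"],
                array_name=row["array_name"],
                role=row["role"],
                entrance_id=entrance,
                line=line,
                has_complement=str(row["has_complement"]).strip().lower()
                in ("true", "1", "yes"),
            )
        )
    return ReceiverRegistry(records)


def write_receivers(registry: ReceiverRegistry, path) -> None:
    rows = [
        (r.receiver_id, r.array_name, r.role, r.entrance_id or "", r.line, r.has_complement)
        for r in registry.records
    ]
    pd.DataFrame(rows, columns=_RECEIVER_COLS).to_csv(path, index=False)


def read_deployments(path) -> list[TagDeployment]:
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _DEPLOYMENT_COLS, path)
    deployments, errors = [], []
    for i, row in df.iterrows():
        try:
            deployments.append(
                TagDeployment(
                    tag_id=row["tag_id"],
                    release_time=_to_utc(row["release_time"]),
                    transmitter_life_days=int(float(row["transmitter_life_days"])),
                    weight_g=float(row["weight_g"]),
                    length_mm=float(row["length_mm"]),
                    sex=row["sex"],
                    tag_weight_g=float(row["tag_weight_g"]),
                )
            )
        except (TableFormatError, ValueError) as exc:
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise TableFormatError(f"{path}: " + "; ".join(errors[:20]))
    return deployments


def write_deployments(deployments: Iterable[TagDeployment], path) -> None:
    rows = [
        (
            d.tag_id,
            d.release_time.strftime("%Y-%m-%dT%H:%M:%SZ"),
            d.transmitter_life_days,
            d.weight_g,
            d.length_mm,
            d.sex,
            d.tag_weight_g,
        )
        for d in deployments
    ]
    pd.DataFrame(rows, columns=_DEPLOYMENT_COLS).to_csv(path, index=False)


def releases_by_year(deployments: Iterable[TagDeployment]) -> dict[int, int]:
    """Number of tagged fish released per calendar year."""
    counts: dict[int, int] = {}
    for d in deployments:
        counts[d.release_time.year] = counts.get(d.release_time.year, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# covariate classing

CLASSING_VARIABLES = ("length", "weight", "condition", "sex", "tag_burden", "none")


@dataclass(frozen=True)
class CovariateClassing:
    """A binary split of the tagged fish on one covariate.

    Numeric covariates are split at the median over the tagged fish
    (class 0: value <= median); sex is used as its own two levels
    (F -> 0, M -> 1); ``variable="none"`` places every fish in class 0,
    giving the unconstrained (single class) model.
    """

    variable: str
    breakpoint: float | None
    y: Mapping[str, int] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return 2 if self.variable != "none" else 1

    def labels(self, tag_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.y.get(t, 0) for t in tag_ids], dtype=np.int64)


def median_classing(
    deployments: Iterable[TagDeployment], variable: str = "none"
) -> CovariateClassing:
    """Build the median-split classing for one covariate."""
    if variable not in CLASSING_VARIABLES:
        raise ValueError(f"variable must be one of {CLASSING_VARIABLES}, got {variable!r}")
    deployments = list(deployments)
    if variable == "none":
        return CovariateClassing("none", None, {d.tag_id: 0 for d in deployments})
    if variable == "sex":
        y = {d.tag_id: (1 if d.sex == "M" else 0) for d in deployments}
        return CovariateClassing("sex", None, y)
    getter = {
        "length": lambda d: d.length_mm,
        "weight": lambda d: d.weight_g,
        "condition": lambda d: d.condition,
        "tag_burden": lambda d: d.tag_burden,
    }[variable]
    values = np.array([getter(d) for d in deployments], dtype=float)
    breakpoint = float(np.median(values))
    y = {d.tag_id: int(getter(d) > breakpoint) for d in deployments}
    return CovariateClassing(variable, breakpoint, y)
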